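"""Allele-specific (ARMS) and locus-specific PCR primer design.

The design problem: in a family of highly similar alleles, place a
primer whose 3′-terminal base sits on a position where the target
allele differs from every other allele in the database, so polymerase
extension fails on non-targets. Candidate pairs must additionally meet
length, melting-temperature and amplicon-size constraints and show no
predicted product on any non-target allele (in-silico PCR screen).

Locus-specific long-range design is the complementary problem: anchor
both primers in regions conserved across all alleles of one locus and
absent from the other loci, with the amplicon spanning every exon–exon
junction so splice variants would be visible as shorter products.

Coordinates in primer names follow the "+1 = A of ATG" convention; the
printed fragment length of a pair equals reverse label − forward label
(plain subtraction). Half-open sequence indices are authoritative
internally; labels are presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import yaml

from .allele_db import (
    AlleleDatabase,
    AlleleRecord,
    coord_to_index,
    discriminating_positions,
    index_to_coord,
)
from .thermo import reverse_complement, tm_nearest_neighbor

__all__ = [
    "DesignConstraints",
    "Primer",
    "PrimerPair",
    "PredictedProduct",
    "SpliceCheckResult",
    "DesignResult",
    "LocusDesignResult",
    "amplicon_length_from_labels",
    "find_binding_sites",
    "in_silico_pcr",
    "cross_reactivity",
    "design_allele_specific",
    "design_locus_specific",
    "validate_pair",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Constraint set for assay design.

    Defaults follow the published allele-specific HLA class I protocol:
    21-mer primers (17–25 accepted, matching the spread of validated
    assays), Tm 66 ± 2 °C, 70–120 bp amplicons, a single 3′-terminal
    discriminating base, and no predicted cross-reactive product.
    """

    primer_len: int = 21
    len_range: tuple[int, int] = (17, 25)
    tm_target: float = 66.0
    tm_tol: float = 2.0
    amp_min: int = 70
    amp_max: int = 120
    three_prime_k: int = 1
    max_internal_mismatches: int = 2
    product_window: tuple[int, int] = (50, 2000)
    na_mM: float = 50.0
    primer_nM: float = 500.0
    max_pairs: int = 10

    def __post_init__(self) -> None:
        if self.amp_min >= self.amp_max:
            raise ValueError("amp_min must be < amp_max")
        if not (self.len_range[0] <= self.primer_len <= self.len_range[1]):
            raise ValueError("primer_len must lie within len_range")
        if self.three_prime_k < 1:
            raise ValueError("three_prime_k must be >= 1")
        if self.max_internal_mismatches < 0:
            raise ValueError("max_internal_mismatches must be >= 0")

    @classmethod
    def long_range(cls, **overrides) -> "DesignConstraints":
        """Constraints for locus-specific long-range assays (~1000–1200 bp)."""
        base = cls(amp_min=1000, amp_max=1200, product_window=(50, 3000))
        return replace(base, **overrides) if overrides else base

    @classmethod
    def from_dict(cls, data: dict) -> "DesignConstraints":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown design constraint keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("len_range", "product_window"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, text: str) -> "DesignConstraints":
        return cls.from_dict(yaml.safe_load(text) or {})

    def tm(self, sequence: str) -> float:
        return tm_nearest_neighbor(sequence, na_mM=self.na_mM, primer_nM=self.primer_nM)


@dataclass(frozen=True)
class Primer:
    sequence: str
    orientation: str  # "forward" | "reverse"
    label_coord: int
    tm: float

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def name_suffix(self) -> str:
        return f"{self.label_coord}{'F' if self.orientation == 'forward' else 'R'}"


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    target: str
    amplicon_len: int

    @property
    def label_len(self) -> int:
        """Fragment length implied by the coordinate labels (plain subtraction)."""
        return self.reverse.label_coord - self.forward.label_coord


@dataclass(frozen=True)
class PredictedProduct:
    start: int
    end: int  # half-open
    size: int


@dataclass(frozen=True)
class SpliceCheckResult:
    junctions_covered: tuple[int, ...]  # sequence indices of covered exon-exon junctions
    full_length_size: int
    skip_variant_sizes: dict[int, int]  # 1-based exon number -> product size if skipped


@dataclass
class DesignResult:
    status: str  # "ok" | "undesignable" | "no_pairs"
    pairs: list[PrimerPair] = field(default_factory=list)
    failure_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class LocusDesignResult:
    status: str  # "ok" | "no_conserved_window" | "no_pairs"
    pair: PrimerPair | None = None
    splice: SpliceCheckResult | None = None
    failure_counts: dict[str, int] = field(default_factory=dict)


def amplicon_length_from_labels(f_label: int, r_label: int) -> int:
    """Fragment length from the ATG-anchored labels in a pair's primer names.

    The published convention is plain subtraction: reverse label minus
    forward label, for positive as well as ATG-straddling coordinates.
    """
    if f_label == 0 or r_label == 0:
        raise ValueError("ATG-anchored labels cannot be zero")
    if r_label <= f_label:
        raise ValueError(f"reverse label {r_label} must exceed forward label {f_label}")
    return r_label - f_label


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_binding_sites(
    primer_seq: str,
    template: str,
    constraints: DesignConstraints,
    strand: str,
) -> list[tuple[int, int]]:
    """Offsets where a primer is predicted to bind and be extensible.

    A site requires zero mismatches in the 3′-terminal ``three_prime_k``
    window and at most ``max_internal_mismatches`` elsewhere. ``strand``
    is "plus" for forward primers (primer matches the template as
    written) and "minus" for reverse primers (the reverse complement of
    the primer matches the template). Returns ``(offset, mismatches)``
    tuples, offsets ascending.
    """
    m = len(primer_seq)
    if m > len(template):
        return []
    probe = primer_seq if strand == "plus" else reverse_complement(primer_seq)
    tarr = _encode(template)
    parr = _encode(probe)
    windows = np.lib.stride_tricks.sliding_window_view(tarr, m)
    mism = windows != parr
    k = constraints.three_prime_k
    # the primer's 3' end maps to the window's last column on the plus
    # strand and to its first column on the minus strand
    if strand == "plus":
        three_prime = mism[:, m - k :]
        internal = mism[:, : m - k]
    elif strand == "minus":
        three_prime = mism[:, :k]
        internal = mism[:, k:]
    else:
        raise ValueError(f"bad strand {strand!r}")
    ok = (three_prime.sum(axis=1) == 0) & (
        internal.sum(axis=1) <= constraints.max_internal_mismatches
    )
    counts = mism.sum(axis=1)
    return [(int(i), int(counts[i])) for i in np.nonzero(ok)[0]]


def in_silico_pcr(
    forward: "Primer | str",
    reverse: "Primer | str",
    template: str,
    constraints: DesignConstraints | None = None,
) -> list[PredictedProduct]:
    """Predict PCR products of a primer pair on one template.

    Emits a product for every convergent forward/reverse binding-site
    combination whose size lies inside ``product_window``. An empty list
    means no predicted amplification.
    """
    constraints = constraints or DesignConstraints()
    fseq = forward.sequence if isinstance(forward, Primer) else forward
    rseq = reverse.sequence if isinstance(reverse, Primer) else reverse
    template = template.replace("-", "")
    lo, hi = constraints.product_window
    products = []
    fwd_sites = find_binding_sites(fseq, template, constraints, "plus")
    if not fwd_sites:
        return []
    rev_sites = find_binding_sites(rseq, template, constraints, "minus")
    for f0, _ in fwd_sites:
        for r0, _ in rev_sites:
            if r0 < f0:
                continue
            end = r0 + len(rseq)
            size = end - f0
            if lo <= size <= hi:
                products.append(PredictedProduct(start=f0, end=end, size=size))
    products.sort(key=lambda p: (p.start, p.end))
    return products


def cross_reactivity(
    pair: PrimerPair,
    db: AlleleDatabase,
    constraints: DesignConstraints | None = None,
) -> list[str]:
    """Non-target alleles on which the pair is predicted to amplify.

    An empty list means the pair is allele-specific within the database.
    """
    constraints = constraints or DesignConstraints()
    hits = []
    for name, rec in db.records.items():
        if name == pair.target:
            continue
        if in_silico_pcr(pair.forward, pair.reverse, rec.cdna, constraints):
            hits.append(name)
    return hits


def _mk_pair(
    rec: AlleleRecord,
    target: str,
    fwd_start: int,
    fwd_seq: str,
    rev_seq: str,
    amp: int,
    tm_f: float,
    tm_r: float,
) -> PrimerPair:
    f_label = index_to_coord(rec, fwd_start)
    r_label = f_label + amp  # label convention: printed length = r_label - f_label
    return PrimerPair(
        forward=Primer(fwd_seq, "forward", f_label, tm_f),
        reverse=Primer(rev_seq, "reverse", r_label, tm_r),
        target=target,
        amplicon_len=amp,
    )


def _rank_key(pair: PrimerPair, constraints: DesignConstraints):
    mid = (constraints.amp_min + constraints.amp_max) / 2
    return (
        abs(pair.forward.tm - constraints.tm_target) + abs(pair.reverse.tm - constraints.tm_target),
        abs(pair.amplicon_len - mid),
        pair.forward.sequence,
        pair.reverse.sequence,
    )


def design_allele_specific(
    db: AlleleDatabase,
    target: str,
    constraints: DesignConstraints | None = None,
    within_locus: bool = False,
) -> DesignResult:
    """Enumerate allele-specific primer pairs for one target allele.

    Every emitted pair has at least one primer whose 3′-terminal base
    sits on a position discriminating the target from all other
    alleles, both primers inside the length and Tm windows, amplicon
    inside [amp_min, amp_max], and an empty cross-reactivity screen.
    Pairs are returned ranked (closest Tm to target first, then most
    central amplicon, then lexicographic sequences) and truncated to
    ``max_pairs``; the ranking is deterministic.
    """
    constraints = constraints or DesignConstraints()
    rec = db[target]
    seq = rec.cdna
    disc = discriminating_positions(db, target, within_locus=within_locus)
    if not disc:
        return DesignResult(status="undesignable")

    lo, hi = constraints.len_range
    fails: dict[str, int] = {"tm_forward": 0, "tm_reverse": 0, "amplicon": 0, "cross_reactivity": 0}
    tm_cache: dict[str, float] = {}

    def tm_of(s: str) -> float:
        if s not in tm_cache:
            tm_cache[s] = constraints.tm(s)
        return tm_cache[s]

    def tm_ok(t: float) -> bool:
        return abs(t - constraints.tm_target) <= constraints.tm_tol

    candidates: list[PrimerPair] = []
    for coord in disc:
        d = coord_to_index(rec, coord)
        # allele-specific FORWARD primer: 3' end on the discriminating base
        for lf in range(lo, hi + 1):
            s = d - lf + 1
            if s < 0:
                continue
            fseq = seq[s : d + 1]
            if "-" in fseq:
                continue
            tm_f = tm_of(fseq)
            if not tm_ok(tm_f):
                fails["tm_forward"] += 1
                continue
            for amp in range(constraints.amp_min, constraints.amp_max + 1):
                e = s + amp
                if e > len(seq):
                    fails["amplicon"] += 1
                    break
                for lr in range(lo, hi + 1):
                    r0 = e - lr
                    if r0 <= d:  # keep the partner clear of the discriminating base
                        continue
                    region = seq[r0:e]
                    if "-" in region:
                        continue
                    rseq = reverse_complement(region)
                    tm_r = tm_of(rseq)
                    if not tm_ok(tm_r):
                        fails["tm_reverse"] += 1
                        continue
                    candidates.append(_mk_pair(rec, target, s, fseq, rseq, amp, tm_f, tm_r))
        # allele-specific REVERSE primer: 3' end opposite the discriminating base
        for lr in range(lo, hi + 1):
            e_r = d + lr
            if e_r > len(seq):
                continue
            region = seq[d:e_r]
            if "-" in region:
                continue
            rseq = reverse_complement(region)
            tm_r = tm_of(rseq)
            if not tm_ok(tm_r):
                fails["tm_reverse"] += 1
                continue
            for amp in range(constraints.amp_min, constraints.amp_max + 1):
                s = e_r - amp
                if s < 0:
                    fails["amplicon"] += 1
                    break
                for lf in range(lo, hi + 1):
                    fend = s + lf
                    if fend > d:  # forward primer must not reach the discriminating base
                        continue
                    fseq = seq[s:fend]
                    if "-" in fseq:
                        continue
                    tm_f = tm_of(fseq)
                    if not tm_ok(tm_f):
                        fails["tm_forward"] += 1
                        continue
                    candidates.append(_mk_pair(rec, target, s, fseq, rseq, amp, tm_f, tm_r))

    # dedupe (same sequences can arise from different enumeration paths)
    unique: dict[tuple, PrimerPair] = {}
    for pair in candidates:
        key = (pair.forward.sequence, pair.reverse.sequence, pair.forward.label_coord)
        unique.setdefault(key, pair)

    passing = []
    for pair in sorted(unique.values(), key=lambda p: _rank_key(p, constraints)):
        if cross_reactivity(pair, db, constraints):
            fails["cross_reactivity"] += 1
            continue
        passing.append(pair)
        if len(passing) >= constraints.max_pairs:
            break

    if not passing:
        return DesignResult(status="no_pairs", failure_counts=fails)
    return DesignResult(status="ok", pairs=passing, failure_counts=fails)


def _conserved_mask(alleles: list[AlleleRecord]) -> np.ndarray:
    arrs = [_encode(a.cdna) for a in alleles]
    lengths = {len(a) for a in arrs}
    if len(lengths) > 1:
        raise ValueError("locus alleles differ in length; align them first")
    stack = np.vstack(arrs)
    mask = (stack == stack[0]).all(axis=0)
    mask &= stack[0] != ord("-")
    return mask


def splice_check(
    rec: AlleleRecord, fwd_start: int, amp_end: int, fwd_len: int, rev_len: int
) -> SpliceCheckResult:
    """Which exon–exon junctions an amplicon covers, and skip-variant sizes.

    Skip sizes are reported for exons lying entirely between the two
    primer footprints (skipping an exon that carries a primer site
    would abolish the product rather than shorten it).
    """
    if not rec.exons:
        raise ValueError(f"allele {rec.name} has no exon model")
    junctions = tuple(e for _, e in rec.exons[:-1])
    covered = tuple(j for j in junctions if fwd_start < j < amp_end)
    full = amp_end - fwd_start
    skip = {}
    for number, (s, e) in enumerate(rec.exons, start=1):
        if s >= fwd_start + fwd_len and e <= amp_end - rev_len:
            skip[number] = full - (e - s)
    return SpliceCheckResult(junctions_covered=covered, full_length_size=full, skip_variant_sizes=skip)


def design_locus_specific(
    db: AlleleDatabase,
    locus: str,
    constraints: DesignConstraints | None = None,
) -> LocusDesignResult:
    """Design a long-range locus-specific pair spanning all exon junctions.

    Primers are anchored in windows identical across every allele of the
    locus (so the assay amplifies them all) and screened against every
    allele of the other loci by in-silico PCR. The amplicon must cover
    every exon–exon junction of the locus's exon model, which makes
    exon-skipping splice variants detectable as shorter products.
    """
    constraints = constraints or DesignConstraints.long_range()
    alleles = sorted(db.alleles_of_locus(locus), key=lambda r: r.name)
    if not alleles:
        raise KeyError(f"no alleles for locus {locus!r}")
    rec = next((a for a in alleles if a.exons), None)
    if rec is None:
        raise ValueError(f"locus {locus!r} has no allele with an exon model")
    seq = rec.cdna
    mask = _conserved_mask(alleles)
    if not mask.any():
        return LocusDesignResult(status="no_conserved_window")
    junctions = [e for _, e in rec.exons[:-1]]
    first_j, last_j = junctions[0], junctions[-1]
    lo, hi = constraints.len_range
    others = [r for r in db.records.values() if r.locus != locus]

    def conserved_window(start: int, length: int) -> bool:
        return bool(mask[start : start + length].all())

    fails = {"tm_forward": 0, "tm_reverse": 0, "amplicon": 0, "cross_reactivity": 0}
    tm_cache: dict[str, float] = {}

    def tm_of(s: str) -> float:
        if s not in tm_cache:
            tm_cache[s] = constraints.tm(s)
        return tm_cache[s]

    fwd_cands = []  # (start, length, seq, tm)
    for length in range(lo, hi + 1):
        for start in range(0, first_j - length):
            if not conserved_window(start, length):
                continue
            fseq = seq[start : start + length]
            t = tm_of(fseq)
            if abs(t - constraints.tm_target) <= constraints.tm_tol:
                fwd_cands.append((start, length, fseq, t))
            else:
                fails["tm_forward"] += 1
    rev_cands = []  # (region_start, length, seq, tm); amplicon ends at region_start+length
    for length in range(lo, hi + 1):
        for start in range(last_j + 1, len(seq) - length + 1):
            if not conserved_window(start, length):
                continue
            rseq = reverse_complement(seq[start : start + length])
            t = tm_of(rseq)
            if abs(t - constraints.tm_target) <= constraints.tm_tol:
                rev_cands.append((start, length, rseq, t))
            else:
                fails["tm_reverse"] += 1

    candidates = []
    for fs, fl, fseq, tf in fwd_cands:
        for rs, rl, rseq, tr in rev_cands:
            amp = rs + rl - fs
            if not (constraints.amp_min <= amp <= constraints.amp_max):
                fails["amplicon"] += 1
                continue
            candidates.append((_mk_pair(rec, locus, fs, fseq, rseq, amp, tf, tr), fs, fl, rl))
    if not candidates:
        return LocusDesignResult(status="no_pairs", failure_counts=fails)

    candidates.sort(key=lambda c: _rank_key(c[0], constraints))
    for pair, fs, fl, rl in candidates:
        if any(in_silico_pcr(pair.forward, pair.reverse, o.cdna, constraints) for o in others):
            fails["cross_reactivity"] += 1
            continue
        # conserved anchoring guarantees within-locus universality; verify anyway
        if not all(
            in_silico_pcr(pair.forward, pair.reverse, a.cdna, constraints) for a in alleles
        ):
            continue
        amp_end = fs + pair.amplicon_len
        return LocusDesignResult(
            status="ok",
            pair=pair,
            splice=splice_check(rec, fs, amp_end, fl, rl),
            failure_counts=fails,
        )
    return LocusDesignResult(status="no_pairs", failure_counts=fails)


# ---------------------------------------------------------------------------
# Independent validator. Deliberately re-implements every check with plain
# Python scans so it shares no code path with the enumerator above.
# ---------------------------------------------------------------------------

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _brute_rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def _brute_sites(probe: str, template: str, k: int, max_internal: int, strand: str) -> list[int]:
    m = len(probe)
    match = probe if strand == "plus" else _brute_rc(probe)
    three_prime = range(m - k, m) if strand == "plus" else range(0, k)
    sites = []
    for off in range(len(template) - m + 1):
        internal = 0
        ok = True
        for j in range(m):
            if template[off + j] != match[j]:
                if j in three_prime:
                    ok = False
                    break
                internal += 1
                if internal > max_internal:
                    ok = False
                    break
        if ok:
            sites.append(off)
    return sites


def validate_pair(
    pair: PrimerPair,
    constraints: DesignConstraints | None = None,
    db: AlleleDatabase | None = None,
) -> dict[str, dict]:
    """Re-evaluate every design constraint for a pair, from scratch.

    Returns a report mapping constraint name to ``{"passed": bool,
    "detail": str}``. With a database, the amplicon is re-derived by
    exact-match search on the target, 3′ discrimination is re-checked by
    a brute-force column scan, and cross-reactivity by a brute-force
    binding scan; none of these reuse the designer's code.
    """
    constraints = constraints or DesignConstraints()
    report: dict[str, dict] = {}
    lo, hi = constraints.len_range

    for which, primer in (("forward", pair.forward), ("reverse", pair.reverse)):
        n = len(primer.sequence)
        report[f"{which}_length"] = {
            "passed": lo <= n <= hi,
            "detail": f"{n} nt vs allowed {lo}-{hi}",
        }
        t = constraints.tm(primer.sequence)
        report[f"{which}_tm"] = {
            "passed": abs(t - constraints.tm_target) <= constraints.tm_tol,
            "detail": f"{t:.2f} °C vs {constraints.tm_target} ± {constraints.tm_tol}",
        }

    report["amplicon"] = {
        "passed": constraints.amp_min <= pair.amplicon_len <= constraints.amp_max,
        "detail": f"{pair.amplicon_len} bp vs {constraints.amp_min}-{constraints.amp_max}",
    }
    report["labels"] = {
        "passed": pair.label_len == pair.amplicon_len,
        "detail": f"label arithmetic gives {pair.label_len} bp vs amplicon {pair.amplicon_len} bp",
    }

    if db is not None and pair.target in db.records:
        rec = db[pair.target]
        template = rec.cdna.replace("-", "")
        fpos = template.find(pair.forward.sequence)
        rpos = template.find(_brute_rc(pair.reverse.sequence))
        if fpos < 0 or rpos < 0:
            report["target_binding"] = {
                "passed": False,
                "detail": "a primer has no exact match on the target",
            }
        else:
            amp = rpos + len(pair.reverse.sequence) - fpos
            report["target_binding"] = {
                "passed": amp == pair.amplicon_len,
                "detail": f"exact-match product {amp} bp vs declared {pair.amplicon_len} bp",
            }
            # 3' discrimination: the terminal base of at least one primer
            # must fall on a column where the target differs from all others
            others = [r.cdna for n, r in db.records.items() if n != pair.target]
            f3 = fpos + len(pair.forward.sequence) - 1
            r3 = rpos
            disc = []
            for idx in (f3, r3):
                base = template[idx]
                disc.append(
                    bool(others) and all(o[idx] != base for o in others if len(o) > idx)
                )
            report["three_prime_discrimination"] = {
                "passed": any(disc),
                "detail": f"forward 3' at index {f3}: {disc[0]}; reverse 3' at index {r3}: {disc[1]}",
            }
        hits = []
        k = constraints.three_prime_k
        mi = constraints.max_internal_mismatches
        p_lo, p_hi = constraints.product_window
        for name, other in db.records.items():
            if name == pair.target:
                continue
            tpl = other.cdna.replace("-", "")
            fsites = _brute_sites(pair.forward.sequence, tpl, k, mi, "plus")
            if not fsites:
                continue
            rsites = _brute_sites(pair.reverse.sequence, tpl, k, mi, "minus")
            for f0 in fsites:
                for r0 in rsites:
                    size = r0 + len(pair.reverse.sequence) - f0
                    if r0 >= f0 and p_lo <= size <= p_hi:
                        hits.append(name)
                        break
                else:
                    continue
                break
        report["cross_reactivity"] = {
            "passed": not hits,
            "detail": f"predicted products on {hits}" if hits else "no non-target products",
        }
    return report
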