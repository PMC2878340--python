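"""Polymorphic allele sequence database with ATG-anchored coordinates.

Models an IMGT/HLA-style collection of cDNA sequences for a polymorphic
gene family (e.g. HLA-A/-B/-C). Each record carries the position of the
start codon so primer positions can be expressed in the conventional
"+1 = A of ATG" coordinate system, which has no zero: −1 immediately
precedes +1.

Sequences are assumed pre-aligned or equal-length ungapped cDNAs; gap
characters ('-') are tolerated and the columns they occupy are excluded
from discrimination analysis.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlleleRecord",
    "AlleleDatabase",
    "parse_allele_fasta",
    "write_allele_fasta",
    "coord_to_index",
    "index_to_coord",
    "discriminating_positions",
    "discriminating_positions_table",
]

_NAME_RE = re.compile(r"^(?P<locus>[A-Za-z0-9\-]+)\*(?P<fields>\d+(?::\d+)*)$")


@dataclass(frozen=True)
class AlleleRecord:
    """One allele: cDNA sequence, start-codon index and exon model.

    ``exons`` is an ordered list of half-open ``(start, end)`` index
    intervals partitioning the coding portion of ``cdna``.
    """

    name: str
    cdna: str
    atg_index: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        m = _NAME_RE.match(self.name)
        if m is None:
            raise ValueError(f"allele name {self.name!r} is not LOCUS*ff[:ff...]")
        if self.cdna[self.atg_index : self.atg_index + 3] != "ATG":
            raise ValueError(
                f"allele {self.name}: no ATG at declared start-codon index {self.atg_index}"
            )
        prev_end = None
        for start, end in self.exons:
            if not (0 <= start < end <= len(self.cdna)):
                raise ValueError(f"allele {self.name}: exon ({start},{end}) out of bounds")
            if prev_end is not None and start != prev_end:
                raise ValueError(f"allele {self.name}: exons not contiguous at {start}")
            prev_end = end

    @property
    def locus(self) -> str:
        return self.name.split("*", 1)[0]

    @property
    def fields(self) -> tuple[int, ...]:
        return tuple(int(f) for f in self.name.split("*", 1)[1].split(":"))


@dataclass
class AlleleDatabase:
    """Collection of alleles indexed by name and by locus."""

    records: dict[str, AlleleRecord] = field(default_factory=dict)

    def add(self, record: AlleleRecord) -> None:
        if record.name in self.records:
            raise ValueError(f"duplicate allele name {record.name!r}")
        self.records[record.name] = record

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __getitem__(self, name: str) -> AlleleRecord:
        try:
            return self.records[name]
        except KeyError:
            raise KeyError(f"allele {name!r} not in database") from None

    @property
    def locus_index(self) -> dict[str, list[str]]:
        index: dict[str, list[str]] = {}
        for name, rec in self.records.items():
            index.setdefault(rec.locus, []).append(name)
        return index

    def loci(self) -> list[str]:
        return sorted(self.locus_index)

    def alleles_of_locus(self, locus: str) -> list[AlleleRecord]:
        return [self.records[n] for n in self.locus_index.get(locus, [])]


def _clean_sequence(raw: str, name: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - set("ACGT-")
    if bad:
        raise ValueError(f"record {name!r}: non-ACGT symbols {sorted(bad)}")
    if not seq:
        raise ValueError(f"record {name!r}: empty sequence")
    return seq


def parse_allele_fasta(text: str) -> AlleleDatabase:
    """Parse a multi-record FASTA into an :class:`AlleleDatabase`.

    Headers must contain an allele-name token ``LOCUS*ff:ff...`` and may
    carry ``atg=<0-based index>`` and ``exons=<s1-e1,s2-e2,...>``
    annotations. Without an ``atg=`` annotation the first ATG in the
    sequence is taken as the start codon.
    """
    db = AlleleDatabase()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        header = f"{rec.id} {rec.description}"
        name = None
        for token in header.split():
            if _NAME_RE.match(token):
                name = token
                break
        if name is None:
            raise ValueError(f"no allele-name token in FASTA header {header!r}")
        seq = _clean_sequence(str(rec.seq), name)

        m = re.search(r"\batg=(\d+)", header)
        if m:
            atg = int(m.group(1))
        else:
            atg = seq.find("ATG")
            if atg < 0:
                raise ValueError(f"record {name!r}: sequence contains no ATG start codon")
        if seq[atg : atg + 3] != "ATG":
            raise ValueError(f"record {name!r}: no ATG at annotated index {atg}")

        exons: tuple[tuple[int, int], ...] = ()
        m = re.search(r"\bexons=([\d,\-]+)", header)
        if m:
            exons = tuple(
                (int(a), int(b)) for a, b in (span.split("-") for span in m.group(1).split(","))
            )
        db.add(AlleleRecord(name=name, cdna=seq, atg_index=atg, exons=exons))
    if not db.records:
        raise ValueError("FASTA input contains no records")
    return db


def write_allele_fasta(db: AlleleDatabase) -> str:
    """Serialize a database back to the FASTA header dialect of this module."""
    out: list[SeqRecord] = []
    for name, rec in db.records.items():
        ann = f"{len(rec.cdna)} bp atg={rec.atg_index}"
        if rec.exons:
            ann += " exons=" + ",".join(f"{s}-{e}" for s, e in rec.exons)
        out.append(SeqRecord(Seq(rec.cdna), id=name, description=ann))
    buf = io.StringIO()
    SeqIO.write(out, buf, "fasta")
    return buf.getvalue()


def coord_to_index(record: AlleleRecord, coord: int) -> int:
    """ATG-anchored coordinate → 0-based sequence index.

    +1 is the A of the start codon; −1 the base immediately before it;
    there is no coordinate 0.
    """
    if coord == 0:
        raise ValueError("ATG-anchored coordinates have no zero")
    index = record.atg_index + coord - 1 if coord >= 1 else record.atg_index + coord
    if not (0 <= index < len(record.cdna)):
        raise ValueError(
            f"coordinate {coord:+d} maps outside {record.name} (length {len(record.cdna)})"
        )
    return index


def index_to_coord(record: AlleleRecord, index: int) -> int:
    """Inverse of :func:`coord_to_index`."""
    if not (0 <= index < len(record.cdna)):
        raise ValueError(f"index {index} outside {record.name}")
    offset = index - record.atg_index
    return offset + 1 if offset >= 0 else offset


def discriminating_positions(
    db: AlleleDatabase, target: str, within_locus: bool = False
) -> list[int]:
    """Aligned positions where the target differs from EVERY other allele.

    These are the candidate sites for a 3′-terminal allele-specific
    (ARMS) primer base. Comparison defaults to the whole database —
    HLA-A/-B/-C are cross-similar enough that locus-restricted screening
    is unsafe — and can be restricted with ``within_locus``. Positions
    are returned as ATG-anchored coordinates of the target, ascending.
    Columns containing a gap in any compared sequence are skipped.
    """
    rec = db[target]
    others = [
        r
        for n, r in db.records.items()
        if n != target and (not within_locus or r.locus == rec.locus)
    ]
    if not others:
        warnings.warn(
            f"database holds no comparison alleles for {target}; no discrimination possible",
            stacklevel=2,
        )
        return []
    lengths = {len(r.cdna) for r in others} | {len(rec.cdna)}
    if len(lengths) > 1:
        raise ValueError(
            "sequences differ in length; provide a gapped alignment or equal-length cDNAs"
        )
    positions = []
    for i, base in enumerate(rec.cdna):
        if base == "-":
            continue
        column = [r.cdna[i] for r in others]
        if "-" in column:
            continue
        if all(base != other for other in column):
            positions.append(index_to_coord(rec, i))
    return positions


def discriminating_positions_table(db: AlleleDatabase, within_locus: bool = False) -> pd.DataFrame:
    """Discriminating sites for every allele, as a tidy table.

    Columns: allele, coord, target_base, other_bases (comma-joined set).
    """
    rows = []
    for name, rec in db.records.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = discriminating_positions(db, name, within_locus=within_locus)
        for coord in coords:
            i = coord_to_index(rec, coord)
            others = sorted(
                {
                    r.cdna[i]
                    for n, r in db.records.items()
                    if n != name and (not within_locus or r.locus == rec.locus)
                }
            )
            rows.append(
                {
                    "allele": name,
                    "coord": coord,
                    "target_base": rec.cdna[i],
                    "other_bases": ",".join(others),
                }
            )
    return pd.DataFrame(rows, columns=["allele", "coord", "target_base", "other_bases"])
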