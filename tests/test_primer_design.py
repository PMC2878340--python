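"""Primer design: label arithmetic, in-silico PCR, ARMS design, validator."""

import numpy as np
import pytest

from allelequant.allele_db import AlleleDatabase, AlleleRecord, coord_to_index
from allelequant.primer_design import (
    DesignConstraints,
    Primer,
    PrimerPair,
    amplicon_length_from_labels,
    cross_reactivity,
    design_allele_specific,
    design_locus_specific,
    in_silico_pcr,
    splice_check,
    validate_pair,
)
from allelequant.synthetic_data import gen_allele_family
from allelequant.thermo import reverse_complement, tm_nearest_neighbor

from conftest import SYNTH_CONSTRAINTS


def _pair(fwd, rev, target="A*01:01", f_label=1, amp=None):
    ftm = tm_nearest_neighbor(fwd) if len(fwd) >= 8 else 0.0
    rtm = tm_nearest_neighbor(rev) if len(rev) >= 8 else 0.0
    amp = amp if amp is not None else 100
    return PrimerPair(
        forward=Primer(fwd, "forward", f_label, ftm),
        reverse=Primer(rev, "reverse", f_label + amp, rtm),
        target=target,
        amplicon_len=amp,
    )


class TestLabelArithmetic:
    @pytest.mark.parametrize(
        ("f_label", "r_label", "expected"),
        [(272, 383, 111), (522, 621, 99), (-2, 1063, 1065), (143, 251, 108)],
    )
    def test_published_fragment_lengths(self, f_label, r_label, expected):
        assert amplicon_length_from_labels(f_label, r_label) == expected

    def test_zero_label_rejected(self):
        with pytest.raises(ValueError):
            amplicon_length_from_labels(0, 100)

    def test_inverted_labels_rejected(self):
        with pytest.raises(ValueError):
            amplicon_length_from_labels(300, 200)


def _brute_force_pcr(fwd, rev, template, c):
    """Independent oracle: check every offset pair with plain loops."""
    rc = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rev_rc = "".join(rc[b] for b in reversed(rev))

    def sites(probe, three_prime_idx):
        out = []
        for off in range(len(template) - len(probe) + 1):
            mism = [j for j in range(len(probe)) if template[off + j] != probe[j]]
            if any(j in three_prime_idx for j in mism):
                continue
            if len([j for j in mism if j not in three_prime_idx]) <= c.max_internal_mismatches:
                out.append(off)
        return out

    k = c.three_prime_k
    fsites = sites(fwd, set(range(len(fwd) - k, len(fwd))))
    rsites = sites(rev_rc, set(range(k)))
    products = []
    for f0 in fsites:
        for r0 in rsites:
            size = r0 + len(rev) - f0
            if r0 >= f0 and c.product_window[0] <= size <= c.product_window[1]:
                products.append((f0, r0 + len(rev), size))
    return sorted(products)


class TestInSilicoPcr:
    template = "ATGCAAAACCGGTTACGTACGATCGGCTAGCTAGGATCCTTAAGGCCGGAATTCCGGTAA"

    def test_perfect_match_ends_give_one_product(self):
        fwd = self.template[:8]
        rev = reverse_complement(self.template[-8:])
        products = in_silico_pcr(fwd, rev, self.template)
        assert [(p.start, p.end, p.size) for p in products] == [(0, 60, 60)]

    def test_three_prime_mismatch_blocks_extension(self):
        fwd = self.template[:8]
        rev = reverse_complement(self.template[-8:])
        mutated = self.template[:7] + ("G" if self.template[7] != "G" else "C") + self.template[8:]
        assert in_silico_pcr(fwd, rev, mutated) == []

    def test_internal_mismatches_tolerated_up_to_limit(self):
        fwd = self.template[:12]
        rev = reverse_complement(self.template[-12:])
        mutated = list(self.template)
        for i in (2, 5):  # internal to the forward primer
            mutated[i] = "T" if mutated[i] != "T" else "A"
        assert len(in_silico_pcr(fwd, rev, "".join(mutated))) == 1
        mutated[8] = "T" if mutated[8] != "T" else "A"  # third internal mismatch
        assert in_silico_pcr(fwd, rev, "".join(mutated)) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_oracle_on_random_templates(self, seed):
        rng = np.random.default_rng(seed)
        template = "".join(rng.choice(list("ACGT"), size=500))
        c = DesignConstraints()
        f0, flen = int(rng.integers(0, 400)), int(rng.integers(17, 25))
        r_end = int(rng.integers(f0 + flen + 30, min(f0 + flen + 200, 500)))
        fwd = template[f0 : f0 + flen]
        rev = reverse_complement(template[r_end - 20 : r_end])
        got = [(p.start, p.end, p.size) for p in in_silico_pcr(fwd, rev, template, c)]
        assert got == _brute_force_pcr(fwd, rev, template, c)


class TestCrossReactivity:
    def test_single_allele_database_is_clean(self):
        db = AlleleDatabase()
        seq = "ATG" + "ACGT" * 30
        db.add(AlleleRecord(name="A*01:01", cdna=seq, atg_index=0))
        pair = _pair(seq[:18], reverse_complement(seq[-18:]), amp=len(seq))
        assert cross_reactivity(pair, db) == []

    def test_conserved_primers_hit_every_other_allele(self, clean_family):
        db, truth = clean_family
        rec = db["A*01:01"]
        # primers on invariant stretches away from every engineered site
        engineered = {i for info in truth["alleles"].values() for i in info["engineered_indices"]}
        start = next(s for s in range(0, 200) if not (set(range(s, s + 120)) & engineered))
        fwd = rec.cdna[start : start + 20]
        rev = reverse_complement(rec.cdna[start + 80 : start + 100])
        pair = _pair(fwd, rev, target="A*01:01", amp=100)
        hits = cross_reactivity(pair, db)
        assert set(hits) >= {n for n in db.locus_index["A"] if n != "A*01:01"}


class TestAlleleSpecificDesign:
    def test_top_pair_discriminates_on_engineered_snp(self, clean_family, synth_constraints):
        db, truth = clean_family
        target = "A*01:01"
        result = design_allele_specific(db, target, synth_constraints)
        assert result.status == "ok"
        (site,) = truth["alleles"][target]["engineered_indices"]
        rec = db[target]
        for pair in result.pairs:
            fpos = rec.cdna.find(pair.forward.sequence)
            f3 = fpos + len(pair.forward.sequence) - 1
            rpos = rec.cdna.find(reverse_complement(pair.reverse.sequence))
            assert site in (f3, rpos)

    def test_identical_twin_is_undesignable(self):
        db, _ = gen_allele_family(3, n_loci=1, n_alleles=2, snp_rate=0.0, engineered_per_allele=0)
        result = design_allele_specific(db, "A*01:01", DesignConstraints(**SYNTH_CONSTRAINTS))
        assert result.status == "undesignable"
        assert result.pairs == []

    def test_impossible_amplicon_reports_failure_counts(self):
        db, _ = gen_allele_family(5, n_loci=2, n_alleles=2, length=300, exon_count=4, snp_rate=0.0)
        constraints = DesignConstraints(
            amp_min=290, amp_max=299, product_window=(50, 2000), **SYNTH_CONSTRAINTS
        )
        result = design_allele_specific(db, "A*01:01", constraints)
        assert result.status == "no_pairs"
        assert result.failure_counts["amplicon"] > 0

    def test_ranking_is_deterministic(self, clean_family, synth_constraints):
        db, _ = clean_family
        a = design_allele_specific(db, "B*02:01", synth_constraints)
        b = design_allele_specific(db, "B*02:01", synth_constraints)
        assert a.pairs == b.pairs

    def test_emitted_pairs_have_consistent_labels(self, clean_family, synth_constraints):
        db, _ = clean_family
        result = design_allele_specific(db, "C*03:01", synth_constraints)
        assert result.status == "ok"
        for pair in result.pairs:
            assert pair.label_len == pair.amplicon_len


@pytest.fixture(scope="module")
def locus_result(clean_family):
    db, _ = clean_family
    constraints = DesignConstraints.long_range(**SYNTH_CONSTRAINTS)
    return db, design_locus_specific(db, "A", constraints)


class TestLocusSpecificDesign:
    def test_all_junctions_covered(self, locus_result):
        db, result = locus_result
        assert result.status == "ok"
        n_exons = len(db["A*01:01"].exons)
        assert len(result.splice.junctions_covered) == n_exons - 1

    def test_amplifies_every_locus_allele_and_no_other_locus(self, locus_result):
        db, result = locus_result
        c = DesignConstraints.long_range(**SYNTH_CONSTRAINTS)
        for name, rec in db.records.items():
            products = in_silico_pcr(result.pair.forward, result.pair.reverse, rec.cdna, c)
            if rec.locus == "A":
                assert products, f"no product on locus allele {name}"
            else:
                assert products == [], f"cross-locus product on {name}"

    def test_skip_variant_sizes_are_full_minus_exon(self, locus_result):
        db, result = locus_result
        exons = db["A*01:01"].exons
        for exon_number, size in result.splice.skip_variant_sizes.items():
            s, e = exons[exon_number - 1]
            assert size == result.splice.full_length_size - (e - s)
        assert all(s < result.splice.full_length_size for s in result.splice.skip_variant_sizes.values())

    def test_junction_count_arithmetic(self):
        rec = AlleleRecord(
            name="A*01:01",
            cdna="ATG" + "C" * 797,
            atg_index=0,
            exons=tuple((i * 100, (i + 1) * 100) for i in range(8)),
        )
        res = splice_check(rec, fwd_start=10, amp_end=790, fwd_len=20, rev_len=20)
        assert len(res.junctions_covered) == 7


class TestValidator:
    def test_published_a0301_assay_violates_amplicon_bound(self):
        pair = _pair("AAGTGGGAGGCGGCCCATGA", "ATGTGTCTTGGGGGGGTCCGT", f_label=508, amp=128)
        report = validate_pair(pair, DesignConstraints())
        assert not report["amplicon"]["passed"]
        assert "128" in report["amplicon"]["detail"]

    def test_short_primer_fails_length(self):
        pair = _pair("ACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT", amp=100)  # 16 nt forward
        report = validate_pair(pair, DesignConstraints())
        assert not report["forward_length"]["passed"]

    def test_designed_pairs_all_pass(self, clean_family, synth_constraints):
        db, _ = clean_family
        result = design_allele_specific(db, "B*01:01", synth_constraints)
        assert result.status == "ok"
        for pair in result.pairs:
            report = validate_pair(pair, synth_constraints, db)
            failed = [k for k, v in report.items() if not v["passed"]]
            assert failed == []
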