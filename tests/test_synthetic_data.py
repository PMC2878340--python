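"""Generator determinism, truth-record guarantees, stream independence."""

import json

import numpy as np
import pytest

from allelequant.allele_db import discriminating_positions, write_allele_fasta
from allelequant.synthetic_data import (
    gen_allele_family,
    gen_bead_panel,
    gen_cdc_counts,
    gen_cell_mfi,
    gen_qpcr_run,
    simulate_scenario,
)


class TestAlleleFamily:
    def test_default_shape(self, family):
        db, truth = family
        assert len(db) == 12
        assert db.loci() == ["A", "B", "C"]
        assert all(len(info["engineered_coords"]) == 1 for info in truth["alleles"].values())

    def test_engineered_sites_discriminate(self, family):
        db, truth = family
        for name, info in truth["alleles"].items():
            assert set(info["engineered_coords"]) <= set(discriminating_positions(db, name))

    def test_negative_coordinates_exercised(self, family):
        db, _ = family
        rec = db["A*01:01"]
        assert rec.atg_index >= 40  # 5'UTR long enough for minus-coordinate primers

    def test_cross_locus_exceeds_within_locus_divergence(self, family):
        db, _ = family
        a1, a2 = db["A*01:01"].cdna, db["A*02:01"].cdna
        b1 = db["B*01:01"].cdna
        within = sum(x != y for x, y in zip(a1, a2)) / len(a1)
        across = sum(x != y for x, y in zip(a1, b1)) / len(a1)
        assert across > 10 * within

    def test_zero_snp_rate_without_engineering_gives_identical_alleles(self):
        db, _ = gen_allele_family(2, snp_rate=0.0, engineered_per_allele=0)
        for locus in db.loci():
            seqs = {r.cdna for r in db.alleles_of_locus(locus)}
            assert len(seqs) == 1

    def test_same_seed_same_bytes(self):
        fa1 = write_allele_fasta(gen_allele_family(4)[0])
        fa2 = write_allele_fasta(gen_allele_family(4)[0])
        assert fa1 == fa2

    def test_exon_model_partitions_coding_region(self, family):
        db, truth = family
        for locus, exons in truth["exons"].items():
            rec = db.alleles_of_locus(locus)[0]
            assert exons[0][0] == rec.atg_index
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                assert e1 == s2

    def test_infeasible_engineering_rejected(self):
        with pytest.raises(ValueError, match="engineered sites"):
            gen_allele_family(1, length=300, exon_count=4, n_alleles=60, engineered_per_allele=4)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="300"):
            gen_allele_family(1, length=200)


class TestForwardModels:
    def test_qpcr_noise_free_matches_fit_model_exactly(self):
        wells, truth = gen_qpcr_run(6, noise_sd_ct=0.0, n_experiments=1)
        std = wells[(wells.role == "standard") & (wells.target == "FBXL12")]
        from allelequant.qpcr_quant import conc_to_copies

        curve = truth["curves"]["exp1:FBXL12"]
        for row in std.itertuples():
            copies = conc_to_copies(row.conc_ng_ul, truth["volume_ul"], truth["plasmid_bp"])
            expected = curve["intercept"] + curve["slope"] * np.log10(copies)
            assert row.ct == pytest.approx(expected, abs=1e-3)  # TSV rounds to 4 decimals

    def test_cdc_counts_are_plausible_binomials(self):
        counts, truth = gen_cdc_counts(9, p_kill={"s": 0.3}, n_cells=500, n_wells=20)
        phat = counts.red.sum() / (500 * 20)
        assert phat == pytest.approx(0.3, abs=0.05)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            gen_qpcr_run(1, noise_sd_ct=-0.1)

    def test_stream_independence(self):
        # the bead draw must not depend on whether the qPCR generator ran first
        b1, _ = gen_bead_panel(5)
        gen_qpcr_run(5)
        b2, _ = gen_bead_panel(5)
        assert b1.equals(b2)

    def test_cell_mfi_inverts_calibration_in_expectation(self):
        _, bead_truth = gen_bead_panel(5)
        samples, truth = gen_cell_mfi(5, bead_truth, cv=0.0)
        spec = samples[samples.stain == "specific"].iloc[0]
        a, b = bead_truth["intercept"], bead_truth["slope"]
        back = 10.0 ** (a + b * np.log10(spec.mfi))
        assert back == pytest.approx(truth["abc"][spec["sample"]][spec.timepoint_h], rel=1e-3)


class TestScenario:
    def test_files_and_truth_written(self, tmp_path):
        truth = simulate_scenario(3, tmp_path)
        for fname in ("alleles.fasta", "wells.tsv", "beads.tsv", "samples.tsv", "cdc.tsv", "truth.json"):
            assert (tmp_path / fname).exists(), fname
        on_disk = json.loads((tmp_path / "truth.json").read_text())
        assert on_disk["seed"] == 3
        assert set(on_disk["qpcr"]["targets"]) == {
            "A*01:01", "A*02:01", "B*01:01", "B*02:01", "C*01:01", "C*02:01",
        }

    def test_regeneration_is_byte_identical(self, tmp_path):
        simulate_scenario(3, tmp_path / "a")
        simulate_scenario(3, tmp_path / "b")
        for fname in ("alleles.fasta", "wells.tsv", "truth.json", "cdc.tsv"):
            assert (tmp_path / "a" / fname).read_bytes() == (tmp_path / "b" / fname).read_bytes()

    def test_unknown_scenario_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="scenario"):
            simulate_scenario(1, tmp_path, scenario="exotic")
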