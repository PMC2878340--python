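"""Standard curves, Pfaffl efficiency, absolute copies, ratios and folds."""

import math

import numpy as np
import pytest

from allelequant.qpcr_quant import (
    DilutionPoint,
    StandardCurve,
    analyze_qpcr_wells,
    conc_to_copies,
    copies_from_ct,
    efficiency_pfaffl,
    fit_standard_curve,
    fold_change,
    gmean,
    normalized_ratio,
)
from allelequant.synthetic_data import gen_qpcr_run

PERFECT_SLOPE = -1 / math.log10(2)  # -3.321928...: exact doubling per cycle


class TestCopiesConversion:
    def test_formula(self):
        # 1 ng in a 3000 bp plasmid: 1e-9 * 6.022e23 / (3000 * 650)
        assert conc_to_copies(1.0, 1.0, 3000) == pytest.approx(3.088e8, rel=1e-3)

    def test_doubling_size_halves_copies(self):
        assert conc_to_copies(1, 1, 8000) == pytest.approx(conc_to_copies(1, 1, 4000) / 2)

    def test_dilution_series_endpoint(self):
        # 2e-2 ng/uL x 5 uL in a 4031 bp plasmid, checked by hand:
        # 1e-10 g * 6.022e23 / (4031*650) = 2.2983e7
        assert conc_to_copies(2e-2, 5.0, 4031) == pytest.approx(2.2983e7, rel=1e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            conc_to_copies(0, 1, 3000)


class TestStandardCurve:
    def _noise_free_points(self):
        return [
            DilutionPoint(concentration=10.0**-k, copies=10.0 ** (7 - k), ct=40 + PERFECT_SLOPE * (7 - k))
            for k in range(6)
        ]

    def test_noise_free_fit_is_exact(self):
        curve = fit_standard_curve(self._noise_free_points())
        assert curve.slope == pytest.approx(PERFECT_SLOPE, abs=1e-9)
        assert curve.intercept == pytest.approx(40.0, abs=1e-9)
        assert curve.r2 == pytest.approx(1.0, abs=1e-12)
        assert curve.efficiency == pytest.approx(2.0, abs=1e-9)

    def test_three_levels_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_standard_curve(self._noise_free_points()[:3])

    def test_noisy_slope_recovered(self):
        rng = np.random.default_rng(11)
        pts = []
        for k in range(6):
            copies = 10.0 ** (7 - k)
            for rep in range(3):
                ct = 39.0 - 3.35 * math.log10(copies) + rng.normal(0, 0.1)
                pts.append(DilutionPoint(concentration=1.0, copies=copies, ct=ct, replicate=rep))
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(-3.35, abs=0.05)

    def test_summary_mentions_efficiency_qc(self):
        curve = fit_standard_curve(self._noise_free_points())
        assert "efficiency" in curve.summary()
        assert "QC: pass" in curve.summary()


class TestPfaffl:
    def test_perfect_doubling(self):
        assert efficiency_pfaffl(PERFECT_SLOPE) == pytest.approx(2.0, abs=1e-6)

    def test_direct_evaluations(self):
        assert efficiency_pfaffl(-3.45) == pytest.approx(10 ** (1 / 3.45), abs=1e-9)
        assert efficiency_pfaffl(-3.45) == pytest.approx(1.949, abs=5e-4)

    def test_low_efficiency_fails_qc(self):
        e = efficiency_pfaffl(-3.60)
        assert e == pytest.approx(1.896, abs=5e-4)
        curve = StandardCurve(slope=-3.60, intercept=40, r2=0.999)
        assert curve.qc == "fail"

    def test_warning_band(self):
        assert StandardCurve(slope=-3.45, intercept=40, r2=1.0).qc == "warn"  # E ~ 1.949

    def test_strictly_decreasing_in_slope_magnitude(self):
        slopes = np.linspace(-4.0, -3.0, 30)
        effs = [efficiency_pfaffl(s) for s in slopes]
        assert all(a < b for a, b in zip(effs, effs[1:]))

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            efficiency_pfaffl(3.3)


class TestQuantification:
    def test_round_trip_inversion(self):
        curve = StandardCurve(slope=PERFECT_SLOPE, intercept=40.0, r2=1.0)
        ct = 40.0 + PERFECT_SLOPE * 5
        assert copies_from_ct(ct, curve) == pytest.approx(1e5, rel=1e-9)

    def test_ct_at_intercept_is_one_copy(self):
        curve = StandardCurve(slope=-3.4, intercept=38.0, r2=1.0)
        assert copies_from_ct(38.0, curve) == pytest.approx(1.0)

    def test_gmean_closed_form(self):
        assert gmean([4, 9]) == pytest.approx(6.0)

    def test_gmean_permutation_and_constant(self):
        assert gmean([2, 8, 5]) == pytest.approx(gmean([5, 2, 8]))
        assert gmean([3.3, 3.3, 3.3]) == pytest.approx(3.3)

    def test_fold_change_identity(self):
        assert fold_change(2.5, 2.5) == 1.0

    def test_zero_ratio_rejected(self):
        with pytest.raises(ValueError):
            normalized_ratio(0, 100)
        with pytest.raises(ValueError):
            gmean([1.0, 0.0])


class TestRunAnalysis:
    def test_recovers_folds_within_ten_percent(self):
        wells, truth = gen_qpcr_run(21)
        report = analyze_qpcr_wells(wells, plasmid_bp=truth["plasmid_bp"])
        folds = {
            f["target"]: f["fold_vs_0h"] for f in report["fold_changes"] if f["timepoint_h"] == 72
        }
        for target, spec in truth["targets"].items():
            assert folds[target] == pytest.approx(spec["fold_72h"], rel=0.10)

    def test_noise_free_run_recovers_curves_exactly(self):
        wells, truth = gen_qpcr_run(5, noise_sd_ct=0.0)
        report = analyze_qpcr_wells(wells, plasmid_bp=truth["plasmid_bp"])
        for key, curve in report["curves"].items():
            assert curve["slope"] == pytest.approx(truth["curves"][key]["slope"], abs=1e-6)
            assert curve["r2"] == pytest.approx(1.0, abs=1e-9)

    def test_missing_columns_rejected(self):
        wells, _ = gen_qpcr_run(5)
        with pytest.raises(ValueError, match="lacks columns"):
            analyze_qpcr_wells(wells.drop(columns=["role"]), plasmid_bp=4031)
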