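import json

import numpy as np
import pytest

from chirosense.errors import CalibrationError, DataError
from chirosense.pipelines import PipelineConfig
from chirosense.report import (
    COMPLEMENTARY_WAVELENGTHS,
    bin_error,
    chirality_results,
    derive_chirality,
    evaluate_campaign,
    univariate_calibrate,
    univariate_predict_er,
)
from chirosense.spectra_io import default_grid
from chirosense.synthetic import (
    MixtureComposition,
    NoiseModel,
    make_preset_basis,
    simulate_design,
    simulate_mixture,
)


class TestDeriveChirality:
    def test_quaternary_test_sample_values(self):
        # 11.25 + 3.75 mM -> total 15.00, er 75.0:25.0, major R
        entry = derive_chirality(11.25, 3.75, analyte="PMP")
        assert entry.total_mM == pytest.approx(15.0)
        assert entry.er == (75.0, 25.0)
        assert entry.major == "R"
        assert entry.ee == pytest.approx(0.5)

    def test_racemate(self):
        entry = derive_chirality(2.0, 2.0)
        assert entry.er == (50.0, 50.0)
        assert entry.major == "rac"

    def test_single_enantiomer(self):
        entry = derive_chirality(5.0, 0.0)
        assert entry.er == (100.0, 0.0)
        assert entry.ee == pytest.approx(1.0)
        assert entry.major == "R"

    def test_er_pair_sums_to_100(self, rng):
        for _ in range(50):
            c_r, c_s = rng.uniform(0.01, 10, 2)
            entry = derive_chirality(c_r, c_s)
            assert entry.er[0] + entry.er[1] == pytest.approx(100.0, abs=0.05)

    def test_mirror_swaps_labels(self):
        a = derive_chirality(7.0, 3.0)
        b = derive_chirality(3.0, 7.0)
        assert a.er == b.er and a.total_mM == b.total_mM
        assert a.major == "R" and b.major == "S"

    def test_nonpositive_total_flagged(self):
        entry = derive_chirality(-1.0, 0.5)
        assert not entry.er_defined
        assert entry.major == "undefined"
        assert entry.total_mM == pytest.approx(-0.5)

    def test_clip(self):
        entry = derive_chirality(-1.0, 4.0, clip=True)
        assert entry.total_mM == pytest.approx(4.0)
        assert entry.er == (100.0, 0.0)

    def test_ppa_diastereomer_labels(self):
        entry = derive_chirality(1.0, 3.0, analyte="PPA")
        assert entry.major == "1S,2R"

    def test_results_matrix(self):
        res = chirality_results(
            np.array([[1.0, 3.0, 2.0, 2.0]]),
            [("PEA", "R"), ("PEA", "S"), ("PMP", "R"), ("PMP", "S")],
        )
        assert res[0][0].major == "S" and res[0][1].major == "rac"


def _calibration_points(noise=None, total=5.0, n=10, seed=7):
    grid = default_grid()
    bases = [make_preset_basis("PEA"), make_preset_basis("PMP")]
    pts = {"PEA": [], "PMP": []}
    for i, ee in enumerate(np.linspace(-1, 1, n)):
        comp = MixtureComposition(
            {
                "PEA": (total * (1 + ee) / 2, total * (1 - ee) / 2),
                "PMP": (total * (1 + ee) / 2, total * (1 - ee) / 2),
            }
        )
        cd, _ = simulate_mixture(bases, comp, "DCE", noise=noise, sample_id=f"cal{i}")
        pts["PEA"].append((cd.value_at(340.0), comp.diff("PEA")))
        pts["PMP"].append((cd.value_at(400.0), comp.diff("PMP")))
    return pts


class TestUnivariate:
    def test_noiseless_er_recovery(self):
        pts = _calibration_points()
        cal = univariate_calibrate(pts["PMP"], "PMP", 400.0)
        bases = [make_preset_basis("PEA"), make_preset_basis("PMP")]
        comp = MixtureComposition({"PEA": (2.0, 3.0), "PMP": (4.2, 0.8)})
        cd, _ = simulate_mixture(bases, comp, "DCE")
        entry = univariate_predict_er(cal, cd.value_at(400.0), 5.0)
        assert entry.er[0] == pytest.approx(84.0, abs=1e-6)
        assert entry.major == "R"

    def test_all_racemic_calibration_rejected(self):
        pts = [(0.0, 0.0)] * 5
        with pytest.raises(CalibrationError):
            univariate_calibrate(pts, "PEA", 340.0)

    def test_too_few_points(self):
        with pytest.raises(CalibrationError):
            univariate_calibrate([(0.0, 1.0), (1.0, 2.0)], "PEA", 340.0)

    def test_negating_composition_negates_slope(self):
        pts = _calibration_points()["PEA"]
        cal = univariate_calibrate(pts, "PEA", 340.0)
        neg = [(cd, -x) for cd, x in pts]
        cal_neg = univariate_calibrate(neg, "PEA", 340.0)
        assert cal_neg.slope == pytest.approx(-cal.slope)
        assert cal_neg.intercept == pytest.approx(cal.intercept, abs=1e-9)

    def test_cd_at_intercept_gives_racemate(self):
        cal = univariate_calibrate(_calibration_points()["PEA"], "PEA", 340.0)
        entry = univariate_predict_er(cal, cal.intercept, 4.0)
        assert entry.er == (50.0, 50.0)

    def test_out_of_range_clipped_with_warning(self):
        cal = univariate_calibrate(_calibration_points()["PEA"], "PEA", 340.0)
        big_cd = cal.intercept + cal.slope * 100.0
        with pytest.warns(UserWarning):
            entry = univariate_predict_er(cal, big_cd, 5.0)
        assert entry.er == (100.0, 0.0)

    def test_other_analyte_invisible_at_readout(self):
        # varying PMP composition does not move the PEA readout at 340 nm... the
        # converse holds exactly by construction: PEA is silent at 400 nm.
        bases = [make_preset_basis("PEA"), make_preset_basis("PMP")]
        cal = univariate_calibrate(_calibration_points()["PMP"], "PMP", 400.0)
        ers = []
        for pea_ee in (-1.0, 0.0, 1.0):
            comp = MixtureComposition(
                {"PEA": (2.5 * (1 + pea_ee), 2.5 * (1 - pea_ee)), "PMP": (4.0, 1.0)}
            )
            cd, _ = simulate_mixture(bases, comp, "DCE")
            ers.append(univariate_predict_er(cal, cd.value_at(400.0), 5.0).er[0])
        assert max(ers) - min(ers) < 0.1

    def test_noisy_campaign_within_4_points(self):
        # mirrors the <4 percentage-point margin on a seeded noisy campaign
        noise = NoiseModel(multiplicative_sd=0.01, additive_sd_fraction=0.0, seed=7)
        pts = _calibration_points(noise=noise)
        cal_pea = univariate_calibrate(pts["PEA"], "PEA", 340.0)
        cal_pmp = univariate_calibrate(pts["PMP"], "PMP", 400.0)
        bases = [make_preset_basis("PEA"), make_preset_basis("PMP")]
        rng = np.random.default_rng(11)
        worst = 0.0
        for i in range(6):
            ee_pea, ee_pmp = rng.uniform(-1, 1, 2)
            comp = MixtureComposition(
                {
                    "PEA": (2.5 * (1 + ee_pea), 2.5 * (1 - ee_pea)),
                    "PMP": (2.5 * (1 + ee_pmp), 2.5 * (1 - ee_pmp)),
                }
            )
            cd, _ = simulate_mixture(bases, comp, "DCE", noise=noise, sample_id=f"t{i}")
            for cal, ee in ((cal_pea, ee_pea), (cal_pmp, ee_pmp)):
                pred = univariate_predict_er(cal, cd.value_at(cal.wavelength_nm), 5.0)
                worst = max(worst, abs(pred.er[0] - 50 * (1 + abs(ee))))
        assert worst <= 4.0

    def test_default_wavelengths(self):
        assert COMPLEMENTARY_WAVELENGTHS == {"PEA": 340.0, "PMP": 400.0}


class TestEvaluateCampaign:
    def test_bins_boundaries(self):
        assert bin_error(0.49) == "green"
        assert bin_error(0.5) == "yellow"  # left-closed
        assert bin_error(1.49) == "yellow"
        assert bin_error(1.5) == "red"

    def test_noiseless_campaign_all_green(self):
        ds = simulate_design("quaternary", 10, 3, seed=31)
        report = evaluate_campaign(ds, PipelineConfig("pcr", "uv", 4))
        assert report.test_rmse < 1e-6
        assert all(b == "green" for row in report.bins for b in row)

    def test_deterministic_report(self):
        a = evaluate_campaign(
            simulate_design("quaternary", 10, 3, seed=33, noise=NoiseModel(seed=33)),
            PipelineConfig("pcr", "uv", 4),
        )
        b = evaluate_campaign(
            simulate_design("quaternary", 10, 3, seed=33, noise=NoiseModel(seed=33)),
            PipelineConfig("pcr", "uv", 4),
        )
        assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(b.to_dict(), sort_keys=True)

    def test_requires_test_samples(self):
        ds = simulate_design("quaternary", 8, 0, seed=35)
        with pytest.raises(DataError):
            evaluate_campaign(ds, PipelineConfig("pcr", "uv", 4))

    def test_frame_columns(self):
        ds = simulate_design("quaternary", 8, 2, seed=37)
        report = evaluate_campaign(ds, PipelineConfig("pcr", "uv", 4))
        df = report.to_frame()
        assert set(df.columns) >= {"sample_id", "analyte", "enantiomer", "abs_error_mM", "bin"}
        assert len(df) == 2 * 4
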