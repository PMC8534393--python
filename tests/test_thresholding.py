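"""ROC-optimal thresholds, the ROI protocol, regressions and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clotseg import (
    Centerline,
    PUBLISHED_ARTERY_MODEL,
    PUBLISHED_PARENCHYMA_MODEL,
    ROISpec,
    Volume,
    VoxelSampleSet,
    assemble_samples,
    compare_models,
    correlation_report,
    equidistant_centerline_rois,
    fit_threshold_model,
    generate_cohort,
    predict_threshold,
    roc_optimal_threshold,
)


def brute_force_optimum(thrombus, non, lo=0, hi=100):
    """Independent oracle: exhaustive scan + the declared tie rule."""
    thrombus = np.asarray(thrombus, dtype=float)
    non = np.asarray(non, dtype=float)
    best_j = -np.inf
    js = []
    for t in range(lo, hi + 1):
        sens = np.mean(thrombus >= t)
        spec = np.mean(non < t)
        js.append(sens + spec - 1.0)
    js = np.array(js)
    best_j = js.max()
    opt = [t for t, j in zip(range(lo, hi + 1), js) if abs(j - best_j) <= 1e-12]
    runs = []
    start = prev = opt[0]
    for t in opt[1:]:
        if t == prev + 1:
            prev = t
        else:
            runs.append((start, prev))
            start = prev = t
    runs.append((start, prev))
    a, b = max(runs, key=lambda r: r[1] - r[0] + 1)
    return int(np.floor((a + b) / 2)), best_j


class TestROC:
    def test_perfect_separation_tie_rule(self):
        samples = VoxelSampleSet([60.0] * 36, [40.0] * 36, [40.0] * 100)
        res = roc_optimal_threshold(samples)
        assert res.optimal_threshold == 50  # J = 1 on 41..60, midpoint rounded down
        assert res.sensitivity_at_optimum == 1.0
        assert res.specificity_at_optimum == 1.0

    def test_small_example_midpoint_rounds_down(self):
        samples = VoxelSampleSet([52, 54, 56, 58], [40, 42], [44, 50])
        res = roc_optimal_threshold(samples)
        assert res.optimal_threshold == 51  # J = 1 run {51, 52}, midpoint 51.5 -> 51
        assert res.sensitivity_at_optimum == 1.0
        assert res.specificity_at_optimum == 1.0

    def test_overlapping_classes_match_brute_force(self):
        samples = VoxelSampleSet([48, 50, 52, 54], [44, 46], [48, 50])
        res = roc_optimal_threshold(samples)
        t_star, j = brute_force_optimum(samples.thrombus, samples.non_thrombus)
        assert res.optimal_threshold == t_star
        assert res.youden.max() == pytest.approx(j)

    def test_matches_brute_force_on_random_samples(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n_t = rng.integers(2, 20)
            n_v = rng.integers(2, 20)
            thrombus = np.round(rng.normal(55, 6, n_t), rng.integers(0, 2))
            non = np.round(rng.normal(40, 6, n_v), rng.integers(0, 2))
            samples = VoxelSampleSet(thrombus, non[:1], non[1:])
            res = roc_optimal_threshold(samples)
            t_star, j = brute_force_optimum(samples.thrombus, samples.non_thrombus)
            assert res.optimal_threshold == t_star
            assert res.youden.max() == pytest.approx(j, abs=1e-12)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        thrombus=st.lists(st.integers(20, 80), min_size=1, max_size=40),
        non=st.lists(st.integers(20, 80), min_size=2, max_size=40),
    )
    def test_property_matches_brute_force(self, thrombus, non):
        if len(set(thrombus) | set(non)) == 1:
            return  # inseparable inputs are rejected, covered elsewhere
        samples = VoxelSampleSet(thrombus, non[:1], non[1:])
        res = roc_optimal_threshold(samples)
        t_star, j = brute_force_optimum(thrombus, np.asarray(non, dtype=float))
        assert res.optimal_threshold == t_star
        assert res.youden.max() == pytest.approx(j, abs=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(7)
        thrombus = np.round(rng.normal(55, 4, 36))
        non = np.round(rng.normal(38, 4, 136))
        base = roc_optimal_threshold(VoxelSampleSet(thrombus, non[:36], non[36:]))
        for c in (-5, 3, 10):
            shifted = roc_optimal_threshold(
                VoxelSampleSet(thrombus + c, non[:36] + c, non[36:] + c)
            )
            assert shifted.optimal_threshold == base.optimal_threshold + c

    def test_monotone_sensitivity_specificity(self):
        rng = np.random.default_rng(8)
        samples = VoxelSampleSet(rng.normal(55, 5, 36), rng.normal(40, 5, 36), rng.normal(36, 4, 100))
        res = roc_optimal_threshold(samples)
        assert np.all(np.diff(res.sensitivity) <= 1e-12)
        assert np.all(np.diff(res.specificity) >= -1e-12)

    def test_separated_gaussians_give_usable_operating_point(self):
        rng = np.random.default_rng(9)
        samples = VoxelSampleSet(
            rng.normal(55, 3, 36), rng.normal(42, 3, 36), rng.normal(36, 3, 100)
        )
        res = roc_optimal_threshold(samples)
        assert res.sensitivity_at_optimum >= 0.5
        assert res.specificity_at_optimum >= 0.5

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            roc_optimal_threshold(VoxelSampleSet([], [40.0], [40.0]))
        with pytest.raises(ValueError, match="inseparable"):
            roc_optimal_threshold(VoxelSampleSet([40.0] * 5, [40.0] * 3, [40.0] * 4))


class TestProtocol:
    def make_volume(self):
        return Volume(np.random.default_rng(0).normal(40, 5, (64, 64, 16)))

    def rois(self, n=4):
        thrombus = [ROISpec((10 + 6 * i, 10, 5), 3, "thrombus") for i in range(n)]
        vessel = [ROISpec((10 + 6 * i, 40, 5), 3, "contralateral_vessel") for i in range(4)]
        parenchyma = ROISpec((40, 40, 5), 10, "parenchyma")
        return thrombus, vessel, parenchyma

    def test_counts_36_36_100(self):
        vol = self.make_volume()
        t, v, p = self.rois()
        samples = assemble_samples(vol, t, v, p)
        assert len(samples.thrombus) == 36
        assert len(samples.vessel) == 36
        assert len(samples.parenchyma) == 100
        assert len(samples.non_thrombus) == 136

    def test_wrong_roi_count_rejected(self):
        vol = self.make_volume()
        t, v, p = self.rois(n=3)
        with pytest.raises(ValueError, match="requires 4"):
            assemble_samples(vol, t, v, p)

    def test_wrong_roi_size_rejected(self):
        vol = self.make_volume()
        t, v, p = self.rois()
        p_small = ROISpec((40, 40, 5), 3, "parenchyma")
        with pytest.raises(ValueError, match="10x10"):
            assemble_samples(vol, t, v, p_small)

    def test_wrong_class_rejected(self):
        vol = self.make_volume()
        t, v, p = self.rois()
        bad = [ROISpec(r.center, 3, "thrombus") for r in v]
        with pytest.raises(ValueError, match="contralateral_vessel"):
            assemble_samples(vol, t, bad, p)


class TestEquidistantROIs:
    def test_quarter_positions_on_straight_centerline(self):
        vol = Volume(np.zeros((64, 64, 16)), spacing=(0.625, 0.625, 0.625))
        cl = Centerline([[10, 10, 5], [22, 10, 5]])  # 12 mm along x
        rois = equidistant_centerline_rois(cl, vol, k=4)
        centers_mm = np.array([vol.index_to_physical(r.center) for r in rois])
        expected_x = 10 + np.array([1.5, 4.5, 7.5, 10.5])
        np.testing.assert_allclose(centers_mm[:, 0], expected_x, atol=0.3125)  # half voxel

    def test_k1_midpoint(self):
        vol = Volume(np.zeros((32, 32, 8)))
        cl = Centerline([[5, 5, 3], [15, 5, 3]])
        (roi,) = equidistant_centerline_rois(cl, vol, k=1)
        assert roi.center == (10, 5, 3)

    def test_centerline_exiting_volume_raises(self):
        vol = Volume(np.zeros((16, 16, 8)))
        cl = Centerline([[0, 5, 3], [40, 5, 3]])
        with pytest.raises(ValueError, match="exits"):
            equidistant_centerline_rois(cl, vol, k=4)


class TestThresholdModels:
    def test_exact_linear_table_recovers_published_coefficients(self):
        x = np.linspace(28, 40, 20)
        table = pd.DataFrame(
            {"parenchyma_hu": x, "artery_hu": x, "optimal_threshold_hu": 0.62 * x + 30.0}
        )
        fit = fit_threshold_model(table, "parenchyma")
        assert fit.slope == pytest.approx(0.62, abs=1e-9)
        assert fit.intercept == pytest.approx(30.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_line_through_two_artery_points(self):
        table = pd.DataFrame(
            {"artery_hu": [0.0, 10.0, 20.0], "optimal_threshold_hu": [31.0, 35.5, 40.0]}
        )
        fit = fit_threshold_model(table, "artery")
        assert fit.slope == pytest.approx(0.45, abs=1e-12)
        assert fit.intercept == pytest.approx(31.0, abs=1e-12)

    def test_constant_predictor_rejected(self):
        table = pd.DataFrame({"artery_hu": [44.0] * 5, "optimal_threshold_hu": range(5)})
        with pytest.raises(ValueError, match="zero variance"):
            fit_threshold_model(table, "artery")

    def test_predict_published_models(self):
        assert predict_threshold(PUBLISHED_PARENCHYMA_MODEL, 50.0) == pytest.approx(61.0)
        assert predict_threshold(PUBLISHED_PARENCHYMA_MODEL, 0.0) == pytest.approx(30.0)
        assert predict_threshold(PUBLISHED_ARTERY_MODEL, 40.0) == pytest.approx(49.0)

    def test_ols_bias_shrinks_with_n(self):
        errs = []
        for n in (20, 70, 500):
            slopes = [
                fit_threshold_model(
                    generate_cohort(n, "parenchyma", noise_sd=3.0, seed=s), "parenchyma"
                ).slope
                for s in range(40)
            ]
            errs.append(abs(np.mean(slopes) - 0.62))
        assert errs[2] < errs[0] + 0.02  # MC mean error shrinks (allow MC slack)
        assert errs[2] < 0.03


class TestModelComparison:
    def test_identical_models_identical_criteria(self):
        table = generate_cohort(70, "parenchyma", noise_sd=3.0, seed=5)
        m = fit_threshold_model(table, "parenchyma")
        comp = compare_models(m, m, table).records
        assert comp.loc["m1", "aic"] == comp.loc["m2", "aic"]
        assert comp.loc["m1", "bic"] == comp.loc["m2", "bic"]

    def test_generating_model_beats_intercept_only(self):
        import statsmodels.api as sm

        table = generate_cohort(70, "parenchyma", noise_sd=3.0, seed=6)
        m2 = fit_threshold_model(table, "parenchyma")
        null = sm.OLS(table["optimal_threshold_hu"], np.ones(len(table))).fit()
        assert m2.aic < null.aic

    def test_noiseless_prediction_correlation_is_one(self):
        table = generate_cohort(30, "parenchyma", noise_sd=0.0, seed=7)
        m = fit_threshold_model(table, "parenchyma")
        comp = compare_models(m, m, table).records
        assert comp.loc["m1", "pearson_r"] == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_table_rejected(self):
        table = generate_cohort(30, "parenchyma", seed=8)
        m = fit_threshold_model(table, "parenchyma")
        with pytest.raises(ValueError, match="mismatched"):
            compare_models(m, m, table.head(10))


class TestCorrelationReport:
    def test_diagonal_and_symmetry(self):
        table = generate_cohort(70, seed=10)
        rep = correlation_report(table)
        mat = rep.coefficients
        np.testing.assert_allclose(np.diag(mat), 1.0)
        np.testing.assert_allclose(mat.values, mat.values.T, atol=1e-12)
        assert np.nanmax(np.abs(mat.values)) <= 1.0 + 1e-12

    def test_perfect_anticorrelation(self):
        table = pd.DataFrame(
            {"parenchyma_hu": np.linspace(30, 40, 20), "artery_hu": -np.linspace(30, 40, 20)}
        )
        rep = correlation_report(table, columns=["parenchyma_hu", "artery_hu"])
        assert rep.coefficients.loc["parenchyma_hu", "artery_hu"] == pytest.approx(-1.0)

    def test_constant_column_undefined(self):
        table = pd.DataFrame(
            {"parenchyma_hu": np.linspace(30, 40, 10), "artery_hu": np.full(10, 44.0)}
        )
        rep = correlation_report(table, columns=["parenchyma_hu", "artery_hu"])
        assert np.isnan(rep.coefficients.loc["parenchyma_hu", "artery_hu"])
        assert rep.methods.loc["parenchyma_hu", "artery_hu"] == "undefined"

    def test_hematocrit_artery_coupling_recovered(self):
        # generator couples hematocrit to artery HU at r = 0.43
        rs = []
        for s in range(60):
            table = generate_cohort(70, seed=s)
            rs.append(np.corrcoef(table["hematocrit"], table["artery_hu"])[0, 1])
        assert abs(np.mean(rs) - 0.43) < 0.05
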