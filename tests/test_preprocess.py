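"""Centering/scaling strategy algebra, fit/apply contract, estimators.

Brute-force loop implementations of every location/scale vector serve
as independent oracles for the vectorized strategy code.
"""

import statistics

import numpy as np
import pytest

from msflow.datamodel import concatenate, replicate_sample
from msflow.preprocess import (CenterSpec, ConfigurationError, PreprocessModel,
                               Preprocessor, ScaleSpec, ZeroVarianceError,
                               center_control, center_multiset_whole,
                               center_per_sample, center_standard,
                               fit_preprocess, preprocess, scale_control,
                               scale_multiset_whole, scale_per_sample,
                               scale_standard, MAD_SCALE)
from msflow.transform import TransformSpec

from conftest import make_multiset, random_multiset


# ---------------------------------------------------------------------------
# brute-force oracles (plain Python loops, independent of the implementation)
# ---------------------------------------------------------------------------

def _loc_1d(values, estimator):
    return (statistics.fmean(values) if estimator == "mean"
            else statistics.median(values))


def _disp2_1d(values, estimator, ddof):
    if estimator == "sd":
        mu = statistics.fmean(values)
        return sum((v - mu) ** 2 for v in values) / (len(values) - ddof)
    med = statistics.median(values)
    mad = statistics.median(abs(v - med) for v in values)
    return (mad * MAD_SCALE) ** 2


def oracle_center_vector(ms, strategy, estimator="mean"):
    J = ms.n_markers
    if strategy == "standard_pooled":
        cols = [[float(v) for s in ms.samples for v in s.data[:, j]]
                for j in range(J)]
        return [_loc_1d(c, estimator) for c in cols]
    samples = ms.controls if strategy == "control_based" else ms.samples
    per_sample = [[_loc_1d(list(s.data[:, j]), estimator) for j in range(J)]
                  for s in samples]
    return [statistics.fmean(m[j] for m in per_sample) for j in range(J)]


def oracle_scale_vector(ms, strategy, estimator="sd", ddof=1):
    J = ms.n_markers
    if strategy == "standard_pooled":
        cols = [[float(v) for s in ms.samples for v in s.data[:, j]]
                for j in range(J)]
        return [_disp2_1d(c, estimator, ddof) ** 0.5 for c in cols]
    samples = ms.controls if strategy == "control_based" else ms.samples
    per_sample = [[_disp2_1d(list(s.data[:, j]), estimator, ddof)
                   for j in range(J)] for s in samples]
    return [statistics.fmean(v[j] for v in per_sample) ** 0.5
            for j in range(J)]


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------

class TestCentering:
    def test_pooled_mean_is_cell_weighted(self, two_sample_ms):
        _, m = center_standard(two_sample_ms)
        np.testing.assert_allclose(m, [3010 / 1010] * 2, atol=1e-9)

    def test_whole_set_mean_weights_samples_equally(self, two_sample_ms):
        _, m = center_multiset_whole(two_sample_ms)
        np.testing.assert_allclose(m, [2.0, 2.0], atol=1e-12)

    def test_identical_samples_center_to_zero(self):
        block = np.array([[1.0, 2.0], [3.0, 4.0]])
        ms = make_multiset([block, block.copy()], groups=[0, 1])
        out, _ = center_standard(ms)
        x, _ = concatenate(out)
        np.testing.assert_allclose(x.mean(axis=0), 0, atol=1e-14)

    def test_single_sample_standard_equals_per_sample(self):
        rng = np.random.default_rng(0)
        ms = make_multiset([rng.normal(size=(9, 3))])
        a, _ = center_standard(ms)
        b = center_per_sample(ms)
        np.testing.assert_allclose(a[0].data, b[0].data, atol=1e-14)

    def test_equal_n_standard_equals_whole_set(self):
        rng = np.random.default_rng(1)
        ms = make_multiset([rng.normal(i, 1, size=(20, 2)) for i in range(3)])
        _, m_std = center_standard(ms)
        _, m_whole = center_multiset_whole(ms)
        np.testing.assert_allclose(m_std, m_whole, atol=1e-12)

    def test_control_centering_preserves_group_offset(self):
        rng = np.random.default_rng(2)
        ctrl = rng.normal([0, -2], 0.1, size=(500, 2))
        resp = rng.normal([0, 2], 0.1, size=(500, 2))
        ms = make_multiset([ctrl, resp], groups=[0, 1])
        out, m0 = center_control(ms)
        np.testing.assert_allclose(out[0].data.mean(axis=0), [0, 0], atol=0.05)
        np.testing.assert_allclose(out[1].data.mean(axis=0), [0, 4], atol=0.05)

    def test_control_centering_without_controls_errors(self):
        ms = make_multiset([np.ones((3, 1))], groups=[1])
        with pytest.raises(ConfigurationError):
            center_control(ms)

    def test_zero_mean_controls_leave_responders_unchanged(self):
        ctrl = np.array([[1.0, -1.0], [-1.0, 1.0]])  # exact zero mean
        resp = np.array([[5.0, 6.0], [7.0, 8.0]])
        ms = make_multiset([ctrl, resp], groups=[0, 1])
        out, m0 = center_control(ms)
        np.testing.assert_allclose(m0, 0, atol=1e-15)
        np.testing.assert_array_equal(out[1].data, resp)

    def test_per_sample_centering_defining_property_and_idempotence(self):
        rng = np.random.default_rng(3)
        ms = make_multiset([rng.normal(5, 2, size=(rng.integers(2, 9), 3))
                            for _ in range(4)])
        out = center_per_sample(ms)
        for s in out.samples:
            np.testing.assert_allclose(s.data.mean(axis=0), 0, atol=1e-12)
        again = center_per_sample(out)
        for a, b in zip(again.samples, out.samples):
            np.testing.assert_allclose(a.data, b.data, atol=1e-14)

    def test_single_cell_sample_becomes_zero(self):
        ms = make_multiset([[[4.0, -3.0]]])
        out = center_per_sample(ms)
        np.testing.assert_array_equal(out[0].data, [[0.0, 0.0]])

    def test_median_centering_zeroes_per_sample_medians(self):
        rng = np.random.default_rng(4)
        ms = make_multiset([rng.exponential(2, size=(21, 2)) for _ in range(3)])
        out = center_per_sample(ms, estimator="median")
        for s in out.samples:
            np.testing.assert_allclose(np.median(s.data, axis=0), 0,
                                       atol=1e-14)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

class TestScaling:
    def test_pooled_scaling_unit_concatenated_sd(self, small_cohort):
        centered, _ = center_standard(small_cohort)
        out, s = scale_standard(centered, ddof=0)
        x, _ = concatenate(out)
        np.testing.assert_allclose(x.std(axis=0, ddof=0), 1, atol=1e-12)

    def test_whole_set_scaling_unit_average_within_variance(self, small_cohort):
        centered = center_per_sample(small_cohort)
        out, s = scale_multiset_whole(centered, ddof=0)
        within = np.stack([b.data.var(axis=0, ddof=0) for b in out.samples])
        np.testing.assert_allclose(within.mean(axis=0), 1, atol=1e-12)

    def test_control_scaling_unit_control_variance_only(self, small_cohort):
        centered = center_per_sample(small_cohort)
        out, s0 = scale_control(centered, ddof=0)
        ctrl_within = np.stack([b.data.var(axis=0, ddof=0)
                                for b in out.controls])
        np.testing.assert_allclose(ctrl_within.mean(axis=0), 1, atol=1e-12)
        with pytest.raises(ConfigurationError):
            scale_control(make_multiset([np.ones((3, 1))], groups=[1]))

    def test_single_control_uses_its_own_sd(self):
        rng = np.random.default_rng(5)
        ctrl = rng.normal(0, 3, size=(50, 2))
        resp = rng.normal(0, 1, size=(50, 2))
        ms = make_multiset([ctrl, resp], groups=[0, 1])
        _, s0 = scale_control(ms, ddof=1)
        np.testing.assert_allclose(s0, ctrl.std(axis=0, ddof=1), atol=1e-12)

    def test_per_sample_scaling_defining_property_and_idempotence(self):
        rng = np.random.default_rng(6)
        ms = center_per_sample(make_multiset(
            [rng.normal(0, rng.uniform(0.5, 4), size=(15, 2))
             for _ in range(3)]))
        out = scale_per_sample(ms, ddof=0)
        for s in out.samples:
            np.testing.assert_allclose(s.data.std(axis=0, ddof=0), 1,
                                       atol=1e-12)
        again = scale_per_sample(out, ddof=0)
        for a, b in zip(again.samples, out.samples):
            np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_zero_variance_marker_names_marker(self):
        ms = make_multiset([np.column_stack([np.ones(5), np.arange(5.0)])],
                           names=["flat", "ok"])
        with pytest.raises(ZeroVarianceError, match="flat"):
            scale_standard(ms)

    def test_single_cell_sample_with_ddof1_errors(self):
        ms = make_multiset([[[1.0, 2.0]], [[0.0, 1.0], [2.0, 3.0]]])
        with pytest.raises(ZeroVarianceError, match="s1"):
            scale_per_sample(ms, ddof=1)

    def test_mad_scaling_unit_mad(self):
        rng = np.random.default_rng(7)
        ms = make_multiset([rng.normal(0, 5, size=(101, 2))])
        out = scale_per_sample(ms, estimator="mad")
        from scipy.stats import median_abs_deviation
        mad = median_abs_deviation(out[0].data, axis=0, scale=1.0) * MAD_SCALE
        np.testing.assert_allclose(mad, 1, atol=1e-12)


# ---------------------------------------------------------------------------
# replication invariance (the central multi-set claim)
# ---------------------------------------------------------------------------

class TestReplicationInvariance:
    @pytest.fixture
    def cohort(self):
        rng = np.random.default_rng(8)
        return make_multiset([rng.normal(i, 1 + i, size=(30, 2))
                              for i in range(4)], groups=[0, 0, 1, 1])

    @pytest.mark.parametrize("strategy,center_fn", [
        ("multiset_whole", center_multiset_whole),
        ("control_based", center_control),
    ])
    def test_sample_weighted_centers_exact_under_replication(
            self, cohort, strategy, center_fn):
        rep = replicate_sample(cohort, 0, 7)
        _, m = center_fn(cohort)
        _, m_rep = center_fn(rep)
        # invariant up to summation-order rounding over the tiled block
        np.testing.assert_allclose(m, m_rep, rtol=0, atol=1e-14)

    @pytest.mark.parametrize("scale_fn", [scale_multiset_whole, scale_control])
    def test_sample_weighted_scales_exact_under_replication(self, cohort,
                                                            scale_fn):
        rep = replicate_sample(cohort, 0, 7)
        _, s = scale_fn(cohort, ddof=0)
        _, s_rep = scale_fn(rep, ddof=0)
        np.testing.assert_allclose(s, s_rep, rtol=0, atol=1e-14)

    def test_pooled_statistics_shift_under_replication(self, cohort):
        rep = replicate_sample(cohort, 3, 50)
        _, m = center_standard(cohort)
        _, m_rep = center_standard(rep)
        # the pooled mean moves toward the replicated sample's mean (3, 3)
        assert np.all(np.abs(m_rep - m) > 1e-2)
        assert np.all(m_rep > m)


# ---------------------------------------------------------------------------
# oracle equivalence and sample-order invariance
# ---------------------------------------------------------------------------

CENTERS = ["standard_pooled", "multiset_whole", "control_based"]
SCALES = ["standard_pooled", "multiset_whole", "control_based"]


class TestOracles:
    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("estimator", ["mean", "median"])
    def test_center_vectors_match_loop_oracle(self, seed, estimator):
        ms = random_multiset(np.random.default_rng(seed))
        for strategy, fn in zip(CENTERS, [center_standard,
                                          center_multiset_whole,
                                          center_control]):
            _, m = fn(ms, estimator)
            np.testing.assert_allclose(
                m, oracle_center_vector(ms, strategy, estimator), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("estimator,ddof", [("sd", 0), ("sd", 1),
                                                ("mad", 0)])
    def test_scale_vectors_match_loop_oracle(self, seed, estimator, ddof):
        ms = random_multiset(np.random.default_rng(100 + seed))
        for strategy, fn in zip(SCALES, [scale_standard, scale_multiset_whole,
                                         scale_control]):
            _, s = fn(ms, estimator, ddof)
            np.testing.assert_allclose(
                s, oracle_scale_vector(ms, strategy, estimator, ddof),
                atol=1e-10)

    def test_sample_order_never_changes_fitted_vectors(self):
        rng = np.random.default_rng(9)
        ms = random_multiset(rng, n_samples=5, n_controls=2)
        perm = [3, 0, 4, 2, 1]
        shuffled = ms.subset(perm)
        for fn in (center_standard, center_multiset_whole, center_control):
            np.testing.assert_allclose(fn(ms)[1], fn(shuffled)[1], atol=1e-12)
        for fn in (scale_standard, scale_multiset_whole, scale_control):
            np.testing.assert_allclose(fn(ms)[1], fn(shuffled)[1], atol=1e-12)


# ---------------------------------------------------------------------------
# fit / apply model
# ---------------------------------------------------------------------------

class TestFitApply:
    TRANSFORM = TransformSpec("none")

    def test_fit_excludes_held_out_sample(self, small_cohort):
        train = small_cohort.subset(range(7))
        held_out = small_cohort.subset([7])
        model = fit_preprocess(train, self.TRANSFORM,
                               CenterSpec("multiset_whole"),
                               ScaleSpec("multiset_whole"))
        assert held_out[0].key not in model.fitted_on
        assert len(model.fitted_on) == 7
        # applying to the held-out sample must use training vectors
        _, m_train = center_multiset_whole(train)
        np.testing.assert_allclose(model.location, m_train, atol=1e-14)
        model.apply(held_out)  # runs without refitting

    def test_per_sample_model_stores_no_global_vectors(self, small_cohort):
        model = fit_preprocess(small_cohort, self.TRANSFORM,
                               CenterSpec("per_sample"),
                               ScaleSpec("per_sample"))
        assert model.location is None
        assert model.scale_values is None

    def test_control_based_fit_without_controls_errors(self, small_cohort):
        responders = small_cohort.subset([4, 5, 6, 7])
        with pytest.raises(ConfigurationError):
            fit_preprocess(responders, self.TRANSFORM,
                           CenterSpec("control_based"), ScaleSpec("none"))

    def test_apply_fit_equals_one_shot_pipeline(self, small_cohort):
        for c in ["standard_pooled", "multiset_whole", "control_based",
                  "per_sample"]:
            for s in ["standard_pooled", "control_based", "per_sample",
                      "none"]:
                model = fit_preprocess(small_cohort, self.TRANSFORM,
                                       CenterSpec(c), ScaleSpec(s))
                via_model = model.apply(small_cohort)
                direct, _ = preprocess(small_cohort, self.TRANSFORM,
                                       CenterSpec(c), ScaleSpec(s))
                for a, b in zip(via_model.samples, direct.samples):
                    np.testing.assert_array_equal(a.data, b.data)

    def test_lps_style_combination_end_to_end(self, small_cohort):
        # the combination recommended for strong technical shifts:
        # per-sample centering with control-based scaling
        out, model = preprocess(small_cohort, self.TRANSFORM,
                                CenterSpec("per_sample"),
                                ScaleSpec("control_based"))
        for s in out.samples:
            np.testing.assert_allclose(s.data.mean(axis=0), 0, atol=1e-12)
        assert model.location is None and model.scale_values is not None

    def test_apply_rejects_panel_mismatch(self, small_cohort):
        model = fit_preprocess(small_cohort, self.TRANSFORM)
        other = make_multiset([np.ones((3, 2)) * [1, 2]], names=["x", "y"])
        from msflow.datamodel import PanelMismatchError
        with pytest.raises(PanelMismatchError):
            model.apply(other)

    def test_json_roundtrip(self, tmp_path, small_cohort):
        model = fit_preprocess(small_cohort, TransformSpec("arcsinh", 150.0),
                               CenterSpec("control_based", "median"),
                               ScaleSpec("multiset_whole", "mad", 0))
        path = tmp_path / "model.json"
        model.save(path)
        back = PreprocessModel.load(path)
        np.testing.assert_allclose(back.location, model.location)
        np.testing.assert_allclose(back.scale_values, model.scale_values)
        assert back.center == model.center and back.scale == model.scale
        out_a = model.apply(small_cohort)
        out_b = back.apply(small_cohort)
        for a, b in zip(out_a.samples, out_b.samples):
            np.testing.assert_array_equal(a.data, b.data)

    def test_low_cell_count_warning(self):
        ms = make_multiset([np.random.default_rng(0).normal(size=(20, 2)),
                            np.random.default_rng(1).normal(size=(200, 2))])
        with pytest.warns(UserWarning, match="median/MAD"):
            fit_preprocess(ms, self.TRANSFORM)

    def test_unpredictable_combination_warning(self, small_cohort):
        with pytest.warns(UserWarning, match="unpredictable"):
            fit_preprocess(small_cohort, self.TRANSFORM,
                           CenterSpec("multiset_whole"),
                           ScaleSpec("per_sample"))
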