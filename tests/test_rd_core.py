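import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdalert import (
    CohortConfig,
    Hospitalization,
    InsufficientDataError,
    KernelSpec,
    SchemaError,
    bandwidth_sweep,
    composite_outcome,
    fit_side,
    generate_cohort,
    kernel_weight,
    rd_estimate,
)
from _utils import make_cohort, make_event_cohort, oracle_rd_triangular, oracle_rd_uniform

C = 65.0


class TestKernelWeight:
    def test_apex(self):
        assert kernel_weight(65.0, C, KernelSpec("triangular", 7.0)) == 1.0

    def test_support_boundary(self):
        assert kernel_weight(72.0, C, KernelSpec("triangular", 7.0)) == 0.0

    def test_midpoint_linearity(self):
        assert kernel_weight(68.5, C, KernelSpec("triangular", 7.0)) == pytest.approx(0.5)

    def test_uniform_open_support(self):
        spec = KernelSpec("uniform", 7.0)
        assert kernel_weight(71.9, C, spec) == 1.0
        assert kernel_weight(72.0, C, spec) == 0.0

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            KernelSpec("triangular", 0.0)

    def test_unknown_kernel(self):
        with pytest.raises(ValueError):
            KernelSpec("epanechnikov", 1.0)

    @given(
        x=st.floats(0, 100),
        h=st.floats(0.1, 50),
        name=st.sampled_from(["triangular", "uniform"]),
    )
    def test_weight_properties(self, x, h, name):
        w = kernel_weight(x, C, KernelSpec(name, h))
        assert 0.0 <= w <= 1.0
        if abs(x - C) >= h:
            assert w == 0.0


class TestCompositeOutcome:
    def test_icu_only(self):
        rec = dict(rrt=0, icu_transfer=1, arrest=0, death=0)
        assert composite_outcome(rec, "primary") == 1
        assert composite_outcome(rec, "secondary") == 1

    def test_death_only_differs_between_composites(self):
        rec = dict(rrt=0, icu_transfer=0, arrest=0, death=1)
        assert composite_outcome(rec, "primary") == 0
        assert composite_outcome(rec, "secondary") == 1

    def test_all_zero(self):
        rec = dict(rrt=0, icu_transfer=0, arrest=0, death=0)
        assert composite_outcome(rec, "primary") == 0
        assert composite_outcome(rec, "secondary") == 0

    def test_dataclass_record(self):
        rec = Hospitalization("a", 70.0, 1, 1, 0, 0, 0, 60.0, 5.0, 2.0)
        assert composite_outcome(rec, "primary") == 1

    def test_missing_flag_is_schema_error(self):
        with pytest.raises(SchemaError):
            composite_outcome({"rrt": 1, "icu_transfer": 0}, "primary")


class TestFitSide:
    def test_constant_outcome(self):
        x = np.linspace(60, 64.9, 30)
        co = make_cohort(x, y=np.full(30, 0.3))
        sf = fit_side(co, "y", "below", C, KernelSpec("triangular", 7.0))
        assert sf.intercept == pytest.approx(0.3, abs=1e-12)
        assert np.allclose(sf.slopes, 0.0, atol=1e-12)
        assert sf.var_intercept == pytest.approx(0.0, abs=1e-18)

    def test_matches_closed_form_ols(self):
        # 12 hand-listed points, uniform kernel, order 1
        x = np.array([58.1, 59.3, 60.0, 61.2, 61.9, 62.5, 62.8, 63.1, 63.4, 64.0, 64.5, 64.9])
        y = np.array([0.2, 0.5, 0.1, 0.4, 0.3, 0.8, 0.2, 0.6, 0.1, 0.9, 0.4, 0.7])
        co = make_cohort(x, y=y)
        sf = fit_side(co, "y", "below", C, KernelSpec("uniform", 7.0))
        from _utils import ols_intercept_linear

        assert sf.intercept == pytest.approx(ols_intercept_linear(x, y, C), abs=1e-10)

    def test_exactly_p_plus_2_points(self):
        x = np.array([62.0, 63.0, 64.0])
        co = make_cohort(x, y=np.array([0.1, 0.2, 0.3]))
        sf = fit_side(co, "y", "below", C, KernelSpec("uniform", 7.0), order=1)
        assert sf.n == 3

    def test_p_plus_1_points_insufficient(self):
        co = make_cohort(np.array([62.0, 63.0]), y=np.array([0.1, 0.2]))
        with pytest.raises(InsufficientDataError, match="below"):
            fit_side(co, "y", "below", C, KernelSpec("uniform", 7.0), order=1)

    def test_threshold_point_belongs_above(self):
        x = np.array([63.0, 64.0, 65.0, 66.0, 67.0])
        co = make_cohort(x, y=np.ones(5))
        sf = fit_side(co, "y", "above", C, KernelSpec("uniform", 7.0))
        assert sf.n == 3  # 65.0 counts as above


class TestRDEstimate:
    def test_pure_step_function(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(50, 80, 400)
        co = make_event_cohort(x, (x >= C).astype(int))
        fit = rd_estimate(co, "primary", C, KernelSpec("triangular", 7.0))
        assert fit.estimate == pytest.approx(1.0, abs=1e-12)
        assert fit.se == pytest.approx(0.0, abs=1e-12)
        assert fit.p_value == 0.0

    def test_uniform_kernel_equals_ols_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(55, 75, 80)
        y = 0.3 + 0.01 * (x - C) - 0.15 * (x >= C) + rng.normal(0, 0.1, 80)
        co = make_cohort(x, y=y)
        fit = rd_estimate(co, "y", C, KernelSpec("uniform", 7.0))
        assert fit.estimate == pytest.approx(oracle_rd_uniform(x, y, C, 7.0), abs=1e-10)

    def test_triangular_kernel_equals_wls_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(55, 75, 100)
        y = 0.4 - 0.02 * (x - C) - 0.1 * (x >= C) + rng.normal(0, 0.2, 100)
        co = make_cohort(x, y=y)
        fit = rd_estimate(co, "y", C, KernelSpec("triangular", 7.0))
        assert fit.estimate == pytest.approx(oracle_rd_triangular(x, y, C, 7.0), abs=1e-10)

    def test_ci_brackets_estimate_and_p_consistency(self, effect_cohort):
        fit = rd_estimate(effect_cohort, "primary")
        assert fit.ci_low <= fit.estimate <= fit.ci_high
        assert 0.0 <= fit.p_value <= 1.0
        assert (fit.p_value < 0.05) == not_covered(fit)

    def test_affine_shift_invariance(self, effect_cohort):
        fit0 = rd_estimate(effect_cohort, "primary")
        shifted = effect_cohort.copy()
        shifted.data["max_score"] = shifted.data["max_score"] + 12.5
        shifted.threshold = C + 12.5
        fit1 = rd_estimate(shifted, "primary", C + 12.5)
        assert fit1.estimate == pytest.approx(fit0.estimate, abs=1e-9)
        assert fit1.se == pytest.approx(fit0.se, abs=1e-9)

    def test_out_of_window_records_irrelevant(self, effect_cohort):
        spec = KernelSpec("triangular", 7.0)
        fit0 = rd_estimate(effect_cohort, "primary", C, spec)
        inside = np.abs(effect_cohort.scores - C) < 7.0
        trimmed = type(effect_cohort)(
            effect_cohort.data.loc[inside].reset_index(drop=True), threshold=C
        )
        fit1 = rd_estimate(trimmed, "primary", C, spec)
        assert fit1.estimate == pytest.approx(fit0.estimate, abs=1e-12)
        assert fit1.se == pytest.approx(fit0.se, abs=1e-12)
        assert (fit1.n_left, fit1.n_right) == (fit0.n_left, fit0.n_right)

    def test_unknown_outcome_label(self, effect_cohort):
        with pytest.raises(SchemaError, match="unknown outcome"):
            rd_estimate(effect_cohort, "nonexistent")

    def test_quadratic_order_recorded(self, effect_cohort):
        fit = rd_estimate(effect_cohort, "primary", order=2)
        assert fit.order == 2


def not_covered(fit):
    return not (fit.ci_low <= 0.0 <= fit.ci_high)


class TestBandwidthSweep:
    def test_grid_of_15(self, effect_cohort):
        curve = bandwidth_sweep(effect_cohort, "primary")
        assert curve.bandwidths() == [float(h) for h in range(1, 16)]

    def test_entry_matches_direct_estimate(self, effect_cohort):
        curve = bandwidth_sweep(effect_cohort, "primary")
        direct = rd_estimate(effect_cohort, "primary", C, KernelSpec("triangular", 7.0))
        entry = dict(curve.entries)[7.0]
        assert entry == direct

    def test_unusable_bandwidths_skipped(self):
        x = np.concatenate([np.linspace(55, 64, 40), np.linspace(68, 75, 40)])
        co = make_cohort(x, y=np.linspace(0, 1, 80))
        with pytest.warns(UserWarning):
            curve = bandwidth_sweep(co, "y", C, [1, 2, 10])
        assert [h for h, _ in curve.skipped] == [1.0, 2.0]
        assert curve.bandwidths() == [10.0]

    def test_stable_when_baseline_globally_linear(self):
        rng = np.random.default_rng(3)
        n = 20_000
        x = rng.uniform(50, 80, n)
        y = 0.2 + 0.003 * (x - C) - 0.1 * (x >= C) + rng.normal(0, 0.1, n)
        co = make_cohort(x, y=y)
        curve = bandwidth_sweep(co, "y", C, list(range(1, 16)))
        est = np.array([f.estimate for _, f in curve.entries])
        ses = np.array([f.se for _, f in curve.entries])
        # spread is dominated by the noisiest (smallest-h) entry
        assert est.max() - est.min() < 3 * ses.max()
        widths = np.array([f.ci_high - f.ci_low for _, f in curve.entries])
        assert (np.diff(widths) <= widths[:-1] * 0.05).all()
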