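import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relpot import (
    DoseResponseTable,
    EndpointSimConfig,
    ParallelCurveModel,
    ParallelCurveSpec,
    exp_model_predict,
    fit_joint_model,
    select_c_mode,
    simulate_endpoint_table,
)
from relpot.exponential import choose_by_aic


class TestExpModelPredict:
    def test_background_at_zero_dose(self):
        assert exp_model_predict(2, 50, 4, 1, 0) == pytest.approx(2.0)

    def test_plateau_at_large_dose(self):
        assert exp_model_predict(1, 10, 4, 1, 1e9) == pytest.approx(4.0)

    def test_scalar_oracle_value(self):
        # 4 ** (1 - exp(-1)) evaluated in exact arithmetic
        assert exp_model_predict(1, 10, 4, 1, 10) == pytest.approx(
            2.4020082691254823, rel=1e-12)

    @pytest.mark.parametrize("bad", [(0, 1, 2, 1), (1, -1, 2, 1),
                                     (1, 1, 0, 1), (1, 1, 2, 0)])
    def test_nonpositive_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            exp_model_predict(*bad, 1.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            exp_model_predict(1, 1, 2, 1, -1.0)

    @settings(deadline=None, max_examples=50)
    @given(a=st.floats(0.1, 100), b=st.floats(0.1, 1e3),
           c=st.floats(1.01, 100), d=st.floats(0.2, 5))
    def test_monotone_in_dose(self, a, b, c, d):
        x = np.linspace(0, 5 * b, 50)
        y = exp_model_predict(a, b, c, d, x)
        assert np.all(np.diff(y) >= -1e-12 * np.max(y))


class TestJointFit:
    def test_zero_noise_parameter_recovery(self, noise_free_endpoint):
        cfg, table, truth = noise_free_endpoint
        fit = fit_joint_model(table, ParallelCurveSpec(cfg.index_substance))
        assert fit.converged
        for s, b_true in truth["b_s"].items():
            assert fit.b_s[s] == pytest.approx(b_true, rel=1e-4)
        assert fit.c == pytest.approx(truth["c"], rel=1e-4)
        assert fit.d == pytest.approx(truth["d"], rel=1e-4)
        for (s, e), a_true in truth["a_se"].items():
            assert fit.a_se[(s, e)] == pytest.approx(a_true, rel=1e-4)

    def test_potency_ratio_recovered_under_noise(self):
        cfg = EndpointSimConfig(rpfs={"A": 1.0, "B": 3.0}, index_substance="A",
                                sigma=0.1, seed=5)
        table, truth = simulate_endpoint_table(cfg)
        fit = fit_joint_model(table, ParallelCurveSpec("A"))
        assert fit.b_s["A"] / fit.b_s["B"] == pytest.approx(3.0, rel=0.35)

    def test_aic_identity(self, noisy_endpoint):
        _, table, _ = noisy_endpoint
        fit = fit_joint_model(table, ParallelCurveSpec("PFOA"))
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik,
                                        abs=1e-10)

    def test_flat_substance_flagged_undetermined(self):
        rng = np.random.default_rng(0)
        rows = []
        for x in (0.0, 10.0, 100.0, 400.0):
            for r in range(3):
                rows.append(("IDX", "e1", x,
                             exp_model_predict(100, 50, 2, 1, x)
                             * np.exp(rng.normal(0, 0.05))))
                rows.append(("FLAT", "e1", x, 50.0))  # constant across x
        table = DoseResponseTable(pd.DataFrame(
            rows, columns=["substance", "experiment", "concentration", "response"]))
        fit = fit_joint_model(table, ParallelCurveSpec("IDX"))
        assert fit.trend_pvalue("FLAT") > 0.05
        statuses = {r.substance: r.status for r in fit.compute_rpfs()}
        assert statuses["FLAT"] == "undetermined"

    def test_concentration_scale_equivariance(self, two_substance_table):
        table, truth = two_substance_table
        fit1 = fit_joint_model(table, ParallelCurveSpec("A"))
        scaled = table.frame.copy()
        scaled["concentration"] *= 7.0
        fit2 = fit_joint_model(DoseResponseTable(scaled), ParallelCurveSpec("A"))
        for s in fit1.b_s:
            assert fit2.b_s[s] == pytest.approx(7.0 * fit1.b_s[s], rel=1e-4)
        assert fit2.rpf("B") == pytest.approx(fit1.rpf("B"), rel=1e-4)

    def test_response_scale_equivariance(self, two_substance_table):
        table, truth = two_substance_table
        fit1 = fit_joint_model(table, ParallelCurveSpec("A"))
        scaled = table.frame.copy()
        one_exp = (scaled["substance"] == "B") & (scaled["experiment"] == "exp2")
        scaled.loc[one_exp, "response"] *= 5.0
        fit2 = fit_joint_model(DoseResponseTable(scaled), ParallelCurveSpec("A"))
        assert fit2.a_se[("B", "exp2")] == pytest.approx(
            5.0 * fit1.a_se[("B", "exp2")], rel=1e-4)
        assert fit2.a_se[("B", "exp1")] == pytest.approx(
            fit1.a_se[("B", "exp1")], rel=1e-4)
        for s in fit1.b_s:
            assert fit2.b_s[s] == pytest.approx(fit1.b_s[s], rel=1e-4)
        assert fit2.c == pytest.approx(fit1.c, rel=1e-4)
        assert fit2.d == pytest.approx(fit1.d, rel=1e-4)

    def test_index_rpf_is_exactly_one_and_inversion(self, noisy_endpoint):
        _, table, _ = noisy_endpoint
        fit_a = fit_joint_model(table, ParallelCurveSpec("PFOA"))
        results = {r.substance: r for r in fit_a.compute_rpfs()}
        assert results["PFOA"].rpf == 1.0
        assert results["PFOA"].rpf_l == results["PFOA"].rpf_u == 1.0
        fit_b = fit_joint_model(table, ParallelCurveSpec("S-HIGH"))
        assert fit_b.rpf("PFOA") == pytest.approx(1.0 / fit_a.rpf("S-HIGH"),
                                                  rel=1e-3)


class TestCModeSelection:
    def test_plateaued_data_prefers_free_c(self):
        # curve levels off well inside the tested range
        cfg = EndpointSimConfig(rpfs={"PFOA": 1.0}, index_b=20.0, c=3.0, d=2.0,
                                sigma=0.1, seed=3)
        table, _ = simulate_endpoint_table(cfg)
        fit = select_c_mode(table, ParallelCurveSpec("PFOA"))
        assert fit.c_mode == "free"

    def test_unbounded_trend_prefers_fixed_c(self):
        # potency far beyond the range: no plateau information at all
        cfg = EndpointSimConfig(rpfs={"PFOA": 1.0}, index_b=40000.0, c=1e4,
                                d=1.0, sigma=0.1, seed=3)
        table, _ = simulate_endpoint_table(cfg)
        fit = select_c_mode(table, ParallelCurveSpec("PFOA"))
        assert fit.c_mode == "fixed_large"

    def test_tie_goes_to_fixed_c(self, noisy_endpoint):
        _, table, _ = noisy_endpoint
        free = fit_joint_model(table, ParallelCurveSpec("PFOA", c_mode="free"))
        fixed = fit_joint_model(table,
                                ParallelCurveSpec("PFOA", c_mode="fixed_large"))
        fixed.aic = free.aic  # constructed exact tie
        assert choose_by_aic(free, fixed) is fixed


class TestProfileCI:
    def test_interval_contains_mle(self, noisy_endpoint):
        _, table, _ = noisy_endpoint
        fit = fit_joint_model(table, ParallelCurveSpec("PFOA"))
        for s in ("S-HIGH", "S-LOW"):
            lo, hi = fit.profile_ci_log_rpf(s)
            assert lo <= np.log(fit.rpf(s)) <= hi

    def test_index_substance_has_no_profile(self, noisy_endpoint):
        _, table, _ = noisy_endpoint
        fit = fit_joint_model(table, ParallelCurveSpec("PFOA"))
        with pytest.raises(ValueError):
            fit.profile_ci_log_rpf("PFOA")
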