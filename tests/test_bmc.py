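import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from relpot import BMCScreen, ExpressionDataset
from relpot.bmc import (
    anova_prefilter,
    fit_pvalue,
    max_fold_change,
    select_best_model,
)
from relpot.bmc_models import ModelFit, fit_one_model

GRID = np.repeat([0.0, 10.0, 100.0, 400.0], 3)


def _dataset(rows: dict) -> ExpressionDataset:
    labels = [f"s{i}" for i in range(GRID.size)]
    return ExpressionDataset(list(rows), labels, GRID,
                             np.vstack(list(rows.values())))


class TestAnovaPrefilter:
    def test_null_probe_excluded_responsive_probe_kept(self):
        rng = np.random.default_rng(0)
        rows = {"null": 8.0 + rng.normal(0, 0.01, GRID.size),
                "hit": 8.0 + 3.0 * (GRID > 0) + rng.normal(0, 0.1, GRID.size)}
        kept, table = anova_prefilter(_dataset(rows))
        assert "hit" in kept
        assert "null" not in kept

    def test_bh_matches_hand_step_up(self):
        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    @settings(deadline=None, max_examples=25)
    @given(st.permutations(range(6)))
    def test_bh_invariant_to_input_order(self, perm):
        pvals = np.array([0.001, 0.01, 0.04, 0.2, 0.5, 0.9])
        adj = multipletests(pvals, method="fdr_bh")[1]
        perm = np.array(perm)
        adj_perm = multipletests(pvals[perm], method="fdr_bh")[1]
        assert np.allclose(adj_perm, adj[perm])

    def test_degenerate_probe_warns_and_is_excluded(self):
        rows = {"flat": np.full(GRID.size, 5.0),
                "ok": np.linspace(0, 3, GRID.size)}
        with pytest.warns(UserWarning, match="undefined F"):
            kept, table = anova_prefilter(_dataset(rows))
        assert "flat" not in kept
        assert np.isnan(table.loc[table.probe_id == "flat", "p_raw"]).all()


class TestFitPValue:
    def test_exact_model_data_gives_p_near_one(self):
        y = 8.0 - 0.004 * GRID
        fit = fit_one_model("Linear", GRID, y)
        assert fit_pvalue(fit, GRID, y) == pytest.approx(1.0, abs=1e-6)

    def test_nonmonotone_data_rejects_linear(self):
        # strong up-then-down pattern: lack of fit for a straight line
        means = {0.0: 8.0, 10.0: 11.0, 100.0: 8.0, 400.0: 11.0}
        rng = np.random.default_rng(1)
        y = np.array([means[c] for c in GRID]) + rng.normal(0, 0.1, GRID.size)
        fit = fit_one_model("Linear", GRID, y)
        assert fit_pvalue(fit, GRID, y) < 0.1

    def test_saturated_model_has_no_pvalue(self):
        x = np.repeat([0.0, 10.0, 100.0, 400.0], 2)
        y = np.linspace(8, 9, x.size)
        fit = fit_one_model("Poly3", x, y)  # 4 mean params, 4 groups
        assert fit_pvalue(fit, x, y) is None


class TestBestModel:
    @staticmethod
    def _fit(name, aic, n_mean=2, bmd=1.0, converged=True):
        return ModelFit(name, {}, 1.0, 0.0, n_mean, aic, converged, bmd=bmd)

    def test_lowest_aic_wins(self):
        fits = [self._fit("Linear", 100), self._fit("Hill", 98, n_mean=4),
                self._fit("Power", 99, n_mean=3)]
        assert select_best_model(fits).aic == 98

    def test_tie_prefers_fewer_parameters(self):
        fits = [self._fit("Poly2", 98, n_mean=3), self._fit("Linear", 98)]
        assert select_best_model(fits).model_name == "Linear"

    def test_all_failed_gives_none(self):
        fits = [self._fit("Linear", 98, converged=False),
                self._fit("Hill", 99, bmd=None)]
        assert select_best_model(fits) is None


class TestMaxFoldChange:
    def test_one_log2_unit_up_is_plus_two(self):
        y = np.where(GRID == 400.0, 9.0, 8.0)
        assert max_fold_change(GRID, y) == pytest.approx(2.0)

    def test_fractional_down_change(self):
        y = np.where(GRID == 400.0, 8.0 - 0.263, 8.0)
        assert max_fold_change(GRID, y) == pytest.approx(-1.1999713823732154)

    def test_no_change_is_plus_one(self):
        assert max_fold_change(GRID, np.full(GRID.size, 8.0)) == 1.0

    def test_missing_control_errors(self):
        x = np.repeat([10.0, 100.0], 3)
        with pytest.raises(ValueError, match="control"):
            max_fold_change(x, np.ones(6))


class TestScreen:
    def test_screen_frame_and_directions(self, small_matrix_sim):
        cfg, ds, ann, cat, truth = small_matrix_sim
        res = BMCScreen(ds).fit()
        assert set(res.frame.columns) >= {"probe_id", "best_model", "bmd",
                                          "bmdl", "bmdu", "fit_p", "max_fc",
                                          "direction"}
        ok = res.frame.dropna(subset=["bmdl", "bmdu"])
        assert (ok["bmdl"] <= ok["bmd"] + 1e-9).all()
        assert (ok["bmd"] <= ok["bmdu"] + 1e-9).all()
        # directions of detected regulated genes match the generator truth
        gene_of = {p: next(iter(ann.genes(p))) for p in ds.probe_ids}
        for row in res.frame.itertuples():
            g = gene_of[row.probe_id]
            if g in truth["gene_direction"] and g not in truth["conflicting_genes"]:
                assert row.direction == truth["gene_direction"][g]
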