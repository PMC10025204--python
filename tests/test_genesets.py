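import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relpot import GeneSetCatalog, ProbeAnnotation
from relpot.genesets import (
    FilterConfig,
    GeneSetConfig,
    apply_gene_filters,
    classify_direction,
    fisher_enrichment,
    summarize_sets,
)


from _oracles import fisher_two_tail_oracle


class TestFisher:
    def test_oracle_fixture_values(self):
        # frozen from the exact enumeration above
        assert fisher_enrichment(5, 10, 10, 100) == pytest.approx(
            0.00067162774826505, rel=1e-12)
        assert fisher_enrichment(1, 10, 10, 100) == pytest.approx(1.0)
        assert fisher_enrichment(0, 1, 0, 100) == pytest.approx(1.0)

    def test_exhaustive_small_universes(self):
        for u in (5, 8, 12):
            for m in range(1, u + 1):
                for r in range(0, u + 1):
                    lo, hi = max(0, r - (u - m)), min(m, r)
                    for k in range(lo, hi + 1):
                        got = fisher_enrichment(k, m, r, u)
                        want = fisher_two_tail_oracle(k, m, r, u)
                        assert got == pytest.approx(want, abs=1e-12), (k, m, r, u)

    @settings(deadline=None, max_examples=200)
    @given(st.data())
    def test_random_tables_up_to_universe_200(self, data):
        u = data.draw(st.integers(10, 200))
        m = data.draw(st.integers(1, u))
        r = data.draw(st.integers(0, u))
        lo, hi = max(0, r - (u - m)), min(m, r)
        k = data.draw(st.integers(lo, hi))
        got = fisher_enrichment(k, m, r, u)
        want = fisher_two_tail_oracle(k, m, r, u)
        assert got == pytest.approx(want, abs=1e-12)

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(1, 300, 10, 200)  # set larger than universe


class TestDirection:
    @pytest.mark.parametrize("n_up,n_down,expected", [
        (6, 4, "up"),      # boundary inclusive at 60%
        (5, 5, "mixed"),
        (1, 9, "down"),
        (3, 2, "up"),
        (0, 1, "down"),
    ])
    def test_sixty_percent_rule(self, n_up, n_down, expected):
        assert classify_direction(n_up, n_down) == expected

    def test_zero_regulated_is_undefined(self):
        with pytest.raises(ValueError):
            classify_direction(0, 0)


def _probe_row(probe, bmd=50.0, bmdl=25.0, bmdu=100.0, fit_p=0.5,
               max_fc=2.0, direction="up"):
    return dict(probe_id=probe, best_model="Hill", bmd=bmd, bmdl=bmdl,
                bmdu=bmdu, fit_p=fit_p, max_fc=max_fc, direction=direction)


class TestGeneFilters:
    ANNOTATION = ProbeAnnotation({
        "P1": {"g1"}, "P2": {"g2"}, "P3": {"g3"}, "P4": {"g4", "g5"},
        "P6a": {"g6"}, "P6b": {"g6"},
    })

    def _run(self, rows, **cfg):
        table = pd.DataFrame(rows)
        return apply_gene_filters(table, self.ANNOTATION, max_dose=400.0,
                                  config=FilterConfig(**cfg))

    def test_bmd_above_max_dose_removed(self):
        genes, report = self._run([_probe_row("P1", bmd=450.0)])
        assert genes.empty
        assert report["bmd_above_max_dose"] == 1

    def test_bmd_bmdl_ratio_boundary(self):
        # ratio 25 removed, ratio exactly 20 kept
        genes, _ = self._run([_probe_row("P1", bmd=250.0, bmdl=10.0, bmdu=260),
                              _probe_row("P2", bmd=200.0, bmdl=10.0, bmdu=260)])
        assert set(genes["gene"]) == {"g2"}

    def test_bmdu_bmdl_ratio(self):
        genes, report = self._run([_probe_row("P1", bmdl=10.0, bmdu=450.0,
                                              bmd=50.0)])
        assert genes.empty
        assert report["wide_bmdu_bmdl"] == 1

    def test_promiscuous_probe_removed(self):
        genes, report = self._run([_probe_row("P4")])
        assert genes.empty
        assert report["promiscuous"] == 1

    def test_weak_fold_change_removed(self):
        genes, _ = self._run([_probe_row("P1", max_fc=1.1),
                              _probe_row("P2", max_fc=-1.3)])
        assert set(genes["gene"]) == {"g2"}

    def test_poor_fit_removed(self):
        genes, report = self._run([_probe_row("P1", fit_p=0.05)])
        assert genes.empty
        assert report["poor_fit"] == 1

    def test_conflicting_gene_removed(self):
        rows = [_probe_row("P6a", direction="up", max_fc=2.0),
                _probe_row("P6b", direction="down", max_fc=-2.0)]
        genes, report = self._run(rows)
        assert genes.empty
        assert report["conflicting_genes"] == 1

    def test_majority_direction_kept(self):
        ann = ProbeAnnotation({"Pa": {"g"}, "Pb": {"g"}, "Pc": {"g"}})
        rows = [_probe_row("Pa", direction="up", bmd=10.0),
                _probe_row("Pb", direction="up", bmd=20.0),
                _probe_row("Pc", direction="down", bmd=30.0)]
        genes, _ = apply_gene_filters(pd.DataFrame(rows), ann, 400.0)
        assert len(genes) == 1
        assert genes.iloc[0]["direction"] == "up"
        assert genes.iloc[0]["bmd"] == pytest.approx(20.0)  # mean of probes

    def test_filter_order_independence(self):
        rows = [_probe_row("P1"), _probe_row("P2", bmd=450.0),
                _probe_row("P3", max_fc=1.05)]
        genes_fwd, _ = self._run(rows)
        genes_rev, _ = self._run(rows[::-1])
        assert set(genes_fwd["gene"]) == set(genes_rev["gene"])


class TestSummarizeSets:
    CATALOG = GeneSetCatalog({
        "S1": ("set one", frozenset(f"g{i}" for i in range(1, 11))),
        "S2": ("set two", frozenset(f"g{i}" for i in range(11, 51))),
    })

    @staticmethod
    def _genes(names, bmds=None, direction="up"):
        bmds = bmds or [50.0] * len(names)
        return pd.DataFrame(dict(gene=names, bmd=bmds,
                                 direction=[direction] * len(names),
                                 max_fc=[2.0] * len(names),
                                 n_probes=[1] * len(names)))

    UNIVERSE = {f"g{i}" for i in range(1, 101)}

    def test_small_hit_count_excluded(self):
        # 4 regulated genes in the set: below the >=5 rule however small p is
        reg = self._genes(["g1", "g2", "g3", "g4"])
        assert summarize_sets(reg, self.CATALOG, self.UNIVERSE) == []

    def test_low_percentage_excluded(self):
        # 6 of 40 = 15% regulated: below the 20% rule
        reg = self._genes([f"g{i}" for i in range(11, 17)])
        results = summarize_sets(reg, self.CATALOG, self.UNIVERSE)
        assert all(r.set_id != "S2" for r in results)

    def test_median_bmc_over_regulated_genes(self):
        reg = self._genes(["g1", "g2", "g3", "g4", "g5"],
                          bmds=[10.0, 20.0, 30.0, 5.0, 100.0])
        results = summarize_sets(reg, self.CATALOG, self.UNIVERSE)
        assert len(results) == 1
        r = results[0]
        assert r.set_id == "S1"
        assert r.median_bmc == pytest.approx(20.0)
        assert r.n_regulated == r.n_up + r.n_down == 5
        assert r.pct_regulated == pytest.approx(50.0)
        assert r.direction_class == "up"
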