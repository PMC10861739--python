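"""Gene screening cascade: abundance, correlation, literature, panel assembly."""

import numpy as np
import pandas as pd
import pytest

from modpanel import genes as gs
from modpanel.repertoire import build_repertoire

from conftest import make_dataset


def counts_dataset(gene_values: dict[str, list[float]]):
    n = len(next(iter(gene_values.values())))
    tps = {f"s{i}": ("T1" if i < n // 2 else "PP") for i in range(n)}
    return make_dataset({g: dict(zip(tps, v)) for g, v in gene_values.items()}, tps)


class TestAbundanceFilter:
    def test_boundary_median_of_50_passes(self):
        ds = counts_dataset({"lo": [49.0] * 4, "hi": [50.0] * 4})
        passed, excluded = gs.abundance_filter(ds, ["lo", "hi"])
        assert passed == ["hi"]
        assert list(excluded["gene_id"]) == ["lo"]

    def test_no_exclusions_when_all_abundant(self):
        ds = counts_dataset({"a": [100.0] * 4, "b": [200.0] * 4})
        passed, excluded = gs.abundance_filter(ds, ["a", "b"])
        assert passed == ["a", "b"] and excluded.empty

    def test_absent_candidate_is_excluded_with_reason(self):
        ds = counts_dataset({"a": [100.0] * 4})
        _, excluded = gs.abundance_filter(ds, ["a", "ghost"])
        assert excluded.set_index("gene_id").loc["ghost", "reason"] == "absent"

    def test_intensity_platform_rejected(self):
        ds = make_dataset({"a": {"s0": 1.0, "s1": 2.0}}, {"s0": "T1", "s1": "PP"},
                          platform="intensity")
        with pytest.raises(ValueError):
            gs.abundance_filter(ds, ["a"])

    def test_raising_the_gate_never_adds_survivors(self, rng):
        vals = {f"g{i}": list(rng.lognormal(4, 1, 6)) for i in range(40)}
        ds = counts_dataset(vals)
        p50, _ = gs.abundance_filter(ds, list(vals), min_median=50)
        p80, _ = gs.abundance_filter(ds, list(vals), min_median=80)
        assert set(p80) <= set(p50)


class TestCorrelation:
    def make_traj(self, rows: dict[str, list[float]]):
        return pd.DataFrame(rows).T

    def test_gene_tracking_set_mean_scores_r_one(self):
        traj = self.make_traj({"g": [1, 2, 3, 4, 5, 6], "o1": [2, 4, 6, 8, 10, 12],
                               "o2": [1, 2, 3, 4, 5, 6]})
        r, p = gs.set_mean_correlation(traj, "g", ["g", "o1", "o2"])
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_orthogonal_gene_scores_near_zero(self):
        traj = self.make_traj({"g": [1, -1, 1, -1, 1, -1], "o1": [1, 2, 3, 4, 5, 6],
                               "o2": [2, 4, 6, 8, 10, 12]})
        r, _ = gs.set_mean_correlation(traj, "g", ["g", "o1", "o2"])
        assert abs(r) < 0.5

    def test_constant_gene_has_undefined_correlation(self):
        traj = self.make_traj({"g": [3, 3, 3, 3], "o1": [1, 2, 3, 4]})
        r, p = gs.set_mean_correlation(traj, "g", ["g", "o1"])
        assert np.isnan(r) and np.isnan(p)

    def test_gene_excluded_from_its_own_set_mean(self):
        # with only one other gene, the set mean IS the other gene
        traj = self.make_traj({"g": [1, 2, 3, 4], "o1": [4, 3, 2, 1]})
        r, _ = gs.set_mean_correlation(traj, "g", ["g", "o1"])
        assert r == pytest.approx(-1.0)

    def test_noisy_tracker_keeps_high_correlation(self, rng):
        shape = np.array([1, 2, 4, 3, 1, 1, 2, 4, 3, 1, 2, 3], dtype=float)
        rows = {f"o{i}": list(shape * (i + 1)) for i in range(5)}
        rows["g"] = list(shape + rng.normal(0, 0.1, len(shape)))
        r, _ = gs.set_mean_correlation(self.make_traj(rows), "g", list(rows))
        assert r > 0.9


class TestScores:
    @pytest.mark.parametrize("rs,expected", [
        ({"a": 0.8, "b": 0.6}, 0.7),
        ({"a": 1.0, "b": 1.0}, 1.0),
        ({"a": 0.5, "b": 0.9}, 0.7),
    ])
    def test_r_score_is_the_cohort_mean(self, rs, expected):
        assert gs.r_score(rs) == pytest.approx(expected)

    def test_r_score_requires_every_cohort(self):
        with pytest.raises(ValueError):
            gs.r_score({"a": 0.8, "b": float("nan")})

    @pytest.mark.parametrize("title,abstract,expected", [
        (True, True, 2), (True, False, 2), (False, True, 1), (False, False, 0),
    ])
    def test_literature_score_rules(self, title, abstract, expected):
        ann = pd.DataFrame({"title_hit": [title], "abstract_hit": [abstract]},
                           index=pd.Index(["g"], name="gene_id"))
        assert gs.literature_score(ann, "g") == expected

    def test_unannotated_gene_scores_zero(self):
        ann = pd.DataFrame(columns=["title_hit", "abstract_hit"])
        assert gs.literature_score(ann, "g") == 0


class TestPerSetSelection:
    def records(self, set_key, entries):
        rows = []
        for gene, final, r in entries:
            rows.append({"gene_id": gene, "set_key": set_key, "final_score": final,
                         "r_score": r, "fate": gs.FATE_NOT_RANKED, "fate_reason": ""})
        return pd.DataFrame(rows)

    def test_cap_of_four(self):
        rec = self.records("A1/S1", [(f"g{i}", 2.0 + i / 10, 0.9) for i in range(6)])
        sel = gs.select_genes_per_set(rec)
        assert sel["A1/S1"] == ["g5", "g4", "g3", "g2"]
        assert (rec.loc[rec["gene_id"].isin(sel["A1/S1"]), "fate"] == gs.FATE_SELECTED).all()

    def test_short_set_contributes_all_survivors(self):
        rec = self.records("A1/S1", [("a", 2.5, 0.8), ("b", 2.9, 0.9)])
        assert gs.select_genes_per_set(rec)["A1/S1"] == ["b", "a"]

    def test_ties_break_by_r_score_then_gene_id(self):
        rec = self.records("A1/S1", [("z", 2.5, 0.7), ("a", 2.5, 0.7), ("m", 2.5, 0.9)])
        sel = gs.select_genes_per_set(rec, max_per_set=2)
        assert sel["A1/S1"] == ["m", "a"]

    def test_score_algebra_holds_on_scenario_records(self, scenario_run):
        rec = scenario_run["records"]
        ranked = rec[rec["final_score"].notna()]
        assert np.allclose(ranked["final_score"], ranked["lit_score"] + ranked["r_score"])
        assert ranked["r_score"].between(-1, 1).all()
        assert ranked["final_score"].between(-1, 3).all()

    def test_every_candidate_has_exactly_one_fate(self, scenario_run):
        rec = scenario_run["records"]
        assert len(rec) == len(scenario_run["scenario"].candidate_genes)
        counts = rec["fate"].value_counts()
        assert counts.sum() == len(rec)
        assert set(counts.index) <= {gs.FATE_SELECTED, gs.FATE_LOW_ABUNDANCE,
                                     gs.FATE_LOW_CORRELATION, gs.FATE_NOT_RANKED}


class TestSupplementAndHousekeeping:
    def test_target_already_met_needs_no_supplements(self):
        rep = build_repertoire({"M1": ["a", "b"]}, {"M1": "A1"})
        ds = counts_dataset({"a": [100.0] * 4, "b": [100.0] * 4})
        ann = pd.DataFrame(columns=["title_hit", "abstract_hit"])
        cfg = gs.GeneScreenConfig(target_test_size=2)
        panel = gs.supplement_panel({"A1/S1": ["a", "b"]}, [], [], {}, ds, ann, rep,
                                    {"A1/S1": ["M1"]}, cfg)
        assert panel.supplements == []
        assert panel.test_genes == ["a", "b"]

    def test_unreachable_target_is_a_hard_error(self):
        rep = build_repertoire({"M1": ["a", "b"]}, {"M1": "A1"})
        ds = counts_dataset({"a": [100.0] * 4, "b": [100.0] * 4})
        ann = pd.DataFrame(columns=["title_hit", "abstract_hit"])
        cfg = gs.GeneScreenConfig(target_test_size=5)
        with pytest.raises(gs.PanelAssemblyError, match="shortfall"):
            gs.supplement_panel({"A1/S1": ["a"]}, [], [], {"A1/S1": ["b"]}, ds, ann,
                                rep, {"A1/S1": ["M1"]}, cfg)

    def test_planted_shortfall_filled_in_rank_order(self):
        rep = build_repertoire({"M1": ["a", "b", "c", "d", "e", "f"]}, {"M1": "A1"})
        ds = counts_dataset({g: [v] * 4 for g, v in
                             zip("abcdef", [100, 90, 80, 300, 200, 9])})
        ann = pd.DataFrame({"title_hit": [False], "abstract_hit": [True]},
                           index=pd.Index(["e"], name="gene_id"))
        cfg = gs.GeneScreenConfig(target_test_size=5)
        panel = gs.supplement_panel({"A1/S1": ["a", "b"]}, [], [],
                                    {"A1/S1": ["c", "d", "e", "f"]}, ds, ann, rep,
                                    {"A1/S1": ["M1"]}, cfg)
        # e first (abstract hit), then d (highest median); f fails the relaxed gate
        assert [g for _, g in panel.supplements] == ["e", "d", "c"]

    def test_constant_gene_wins_low_cv_slot(self):
        genes = {"p1": [10, 11], "p2": [10, 12], "p3": [9, 12], "p4": [8, 12],
                 "flat": [10, 10], "wob": [5, 15], "l1": [1, 2], "l2": [2, 3],
                 "x": [7, 14]}
        tps = {"s0": "T1", "s1": "PP"}
        ds_a = make_dataset({g: dict(zip(tps, v)) for g, v in genes.items()}, tps)
        ds_b = make_dataset({g: dict(zip(tps, v)) for g, v in genes.items()}, tps,
                            platform="intensity")
        hk = gs.select_housekeeping(ds_a, ds_b, ["p1", "p2", "p3", "p4"], ["l1", "l2"])
        assert [g for src, g in hk if src == "low_cv"][0] == "flat"
        assert [g for src, g in hk if src == "prior_panel"] == ["p1", "p2", "p3", "p4"]
        assert len(hk) == 8 and len({g for _, g in hk}) == 8

    def test_short_prior_panel_is_an_error(self):
        tps = {"s0": "T1", "s1": "PP"}
        ds = make_dataset({"a": {"s0": 1.0, "s1": 2.0}, "b": {"s0": 1.0, "s1": 2.0}},
                          tps)
        with pytest.raises(gs.PanelAssemblyError, match="prior panel"):
            gs.select_housekeeping(ds, ds, ["a"], ["b"])

    def test_planted_low_cv_pair_recovered(self, rng):
        tps = {f"s{i}": ("T1" if i < 4 else "PP") for i in range(8)}
        genes = {f"g{i}": list(rng.normal(100, 20, 8)) for i in range(20)}
        genes["calm1"] = list(rng.normal(100, 1, 8))
        genes["calm2"] = list(rng.normal(100, 1, 8))
        for g in ["hp1", "hp2", "hp3", "hp4", "hl1", "hl2"]:
            genes[g] = list(rng.normal(100, 30, 8))
        ds_a = make_dataset({g: dict(zip(tps, v)) for g, v in genes.items()}, tps)
        ds_b = make_dataset({g: dict(zip(tps, v)) for g, v in genes.items()}, tps,
                            platform="intensity")
        hk = gs.select_housekeeping(ds_a, ds_b, ["hp1", "hp2", "hp3", "hp4"],
                                    ["hl1", "hl2"])
        assert sorted(g for src, g in hk if src == "low_cv") == ["calm1", "calm2"]


def test_chip_capacity_arithmetic():
    assert gs.chip_capacity(n_chips=2, wells_per_chip=96, hk_wells=8) == 176
    with pytest.raises(ValueError):
        gs.chip_capacity(hk_wells=96)


def test_percent_cv_definition():
    tps = {"s0": "T1", "s1": "T1", "s2": "PP"}
    ds = make_dataset({"g": {"s0": 8.0, "s1": 10.0, "s2": 12.0}}, tps)
    expected = 100 * np.std([8, 10, 12], ddof=1) / 10.0
    assert gs.percent_cv(ds, ["g"])["g"] == pytest.approx(expected)
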