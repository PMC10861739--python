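"""Baseline, differential-expression calls and the module % response statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modpanel import fingerprint as fp
from modpanel.dataset import DatasetError
from modpanel.repertoire import RepertoireError, build_repertoire

from conftest import make_dataset


def two_timepoint_dataset(test_vals: dict[str, list[float]], ref_vals: dict[str, list[float]],
                          platform: str = "counts"):
    values: dict[str, dict[str, float]] = {}
    tps: dict[str, str] = {}
    genes = list(test_vals)
    for g in genes:
        values[g] = {}
        for i, v in enumerate(test_vals[g]):
            values[g][f"t{i}"] = v
            tps[f"t{i}"] = "T1"
        for i, v in enumerate(ref_vals[g]):
            values[g][f"r{i}"] = v
            tps[f"r{i}"] = "PP"
    return make_dataset(values, tps, platform=platform)


class TestBaseline:
    def test_singleton_and_pair_means(self):
        ds = two_timepoint_dataset({"g": [1.0]}, {"g": [7.0]})
        assert fp.compute_baseline(ds, "PP").reference_values["g"] == 7.0
        ds2 = two_timepoint_dataset({"g": [1.0]}, {"g": [4.0, 6.0]})
        assert fp.compute_baseline(ds2, "PP").reference_values["g"] == 5.0

    def test_recovers_known_means(self, rng):
        true_means = {f"g{i}": float(m) for i, m in enumerate(rng.uniform(10, 100, 5))}
        ref = {g: list(m + rng.normal(0, 1e-9, 20)) for g, m in true_means.items()}
        ds = two_timepoint_dataset({g: [1.0] for g in true_means}, ref)
        base = fp.compute_baseline(ds, "PP")
        for g, m in true_means.items():
            assert base.reference_values[g] == pytest.approx(m, abs=1e-6)

    def test_missing_reference_timepoint_is_an_error(self):
        ds = two_timepoint_dataset({"g": [1.0]}, {"g": [1.0]})
        with pytest.raises(DatasetError):
            fp.compute_baseline(ds, "nope")


class TestGroupCalls:
    def test_fold_change_boundary_is_inclusive(self):
        # intensity platform: no pseudocount, FC is the exact mean ratio
        ds = two_timepoint_dataset({"g": [15.0, 15.0, 15.0]}, {"g": [10.0, 10.0, 10.0]},
                                   platform="intensity")
        base = fp.compute_baseline(ds, "PP")
        calls = fp.gene_de_group(ds, base, "T1")
        assert calls.loc["g", "fc"] == pytest.approx(1.5)
        # zero-variance groups give p = NaN -> treated as 1, so the p gate
        # decides; perturb slightly to get a real t-statistic
        ds2 = two_timepoint_dataset({"g": [15.0, 15.01, 14.99]}, {"g": [10.0, 10.01, 9.99]},
                                    platform="intensity")
        calls2 = fp.gene_de_group(ds2, fp.compute_baseline(ds2, "PP"), "T1")
        assert calls2.loc["g", "call"] == "up"

    def test_unit_fold_change_is_null_regardless_of_p(self):
        ds = two_timepoint_dataset({"g": [10.0, 10.01, 9.99]}, {"g": [10.0, 10.01, 9.99]},
                                   platform="intensity")
        calls = fp.gene_de_group(ds, fp.compute_baseline(ds, "PP"), "T1")
        assert calls.loc["g", "call"] == "null"

    def test_planted_twofold_shift_is_called_up(self, rng):
        test = {"g": list(rng.normal(20, 0.5, 15))}
        ref = {"g": list(rng.normal(10, 0.5, 15))}
        ds = two_timepoint_dataset(test, ref, platform="intensity")
        calls = fp.gene_de_group(ds, fp.compute_baseline(ds, "PP"), "T1")
        assert calls.loc["g", "call"] == "up"
        assert calls.loc["g", "p"] < 0.1

    def test_welch_matches_scipy_oracle(self, rng):
        from scipy import stats
        test = rng.normal(12, 3, 8)
        ref = rng.normal(10, 1, 15)
        ds = two_timepoint_dataset({"g": list(test)}, {"g": list(ref)}, platform="intensity")
        calls = fp.gene_de_group(ds, fp.compute_baseline(ds, "PP"), "T1")
        expected = stats.ttest_ind(test, ref, equal_var=False).pvalue
        assert calls.loc["g", "p"] == pytest.approx(expected, rel=1e-10)

    def test_swapping_groups_flips_direction(self, rng):
        genes = {f"g{i}": None for i in range(30)}
        test = {g: list(rng.lognormal(3, 0.5, 10)) for g in genes}
        ref = {g: list(rng.lognormal(3.5, 0.5, 10)) for g in genes}
        ds = two_timepoint_dataset(test, ref, platform="intensity")
        fwd = fp.gene_de_group(ds, fp.compute_baseline(ds, "PP"), "T1")
        ds_swapped = two_timepoint_dataset(ref, test, platform="intensity")
        rev = fp.gene_de_group(ds_swapped, fp.compute_baseline(ds_swapped, "PP"), "T1")
        flip = {"up": "down", "down": "up", "null": "null"}
        assert list(rev["call"]) == [flip[c] for c in fwd["call"]]

    def test_raising_fc_threshold_never_adds_calls(self, rng):
        genes = {f"g{i}": None for i in range(50)}
        test = {g: list(rng.lognormal(3 + rng.normal(0, 0.5), 0.3, 10)) for g in genes}
        ref = {g: list(rng.lognormal(3, 0.3, 10)) for g in genes}
        ds = two_timepoint_dataset(test, ref, platform="intensity")
        base = fp.compute_baseline(ds, "PP")
        loose = fp.gene_de_group(ds, base, "T1", fp.ResponseThresholds(fc_group=1.5))
        tight = fp.gene_de_group(ds, base, "T1", fp.ResponseThresholds(fc_group=2.0))
        for direction in ("up", "down"):
            assert set(tight.index[tight["call"] == direction]) <= \
                set(loose.index[loose["call"] == direction])


class TestIndividualCalls:
    @pytest.mark.parametrize("value,expected", [
        (25.0, "up"),     # FC 2.5 and DIFF 15: both gates pass
        (14.0, "null"),   # FC 1.4: fold-change gate fails
        (16.0, "null"),   # FC 1.6 but DIFF 6: difference gate fails
    ])
    def test_conjunction_of_gates(self, value, expected):
        ds = two_timepoint_dataset({"g": [value]}, {"g": [10.0]}, platform="intensity")
        base = fp.compute_baseline(ds, "PP")
        calls = fp.gene_de_individual(ds, base, "t0")
        assert calls.loc["g", "call"] == expected

    def test_down_call_is_symmetric(self):
        ds = two_timepoint_dataset({"g": [10.0]}, {"g": [25.0]}, platform="intensity")
        base = fp.compute_baseline(ds, "PP")
        assert fp.gene_de_individual(ds, base, "t0").loc["g", "call"] == "down"


class TestModuleResponse:
    def make_calls(self, calls: dict[str, str]) -> pd.DataFrame:
        return pd.DataFrame({"call": pd.Series(calls)})

    def test_all_up_forty_gene_module_is_plus_100(self):
        genes = [f"g{i}" for i in range(40)]
        rep = build_repertoire({"M13.26": genes}, {"M13.26": "A13"})
        entry = fp.module_response(self.make_calls({g: "up" for g in genes}), rep, "M13.26")
        assert entry["pct_up"] == 100.0
        assert entry["response"] == 100.0

    def test_all_null_is_zero_and_blank_in_grid(self, tiny_rep):
        calls = self.make_calls({g: "null" for g in tiny_rep.all_genes})
        profile = fp.module_response_profile(calls, tiny_rep)
        assert (profile["response"] == 0).all()
        grid = fp.fingerprint_grid(profile, tiny_rep)
        assert (grid.table["response"] == 0).all()

    def test_mixed_module_nets_out(self):
        genes = [f"g{i}" for i in range(10)]
        rep = build_repertoire({"M": genes}, {"M": "A1"})
        calls = {g: "null" for g in genes}
        for g in genes[:3]:
            calls[g] = "up"
        calls[genes[3]] = "down"
        entry = fp.module_response(self.make_calls(calls), rep, "M")
        assert (entry["pct_up"], entry["pct_down"], entry["response"]) == (30.0, 10.0, 20.0)

    def test_unknown_module_is_an_error(self, tiny_rep):
        with pytest.raises(RepertoireError):
            fp.module_response(self.make_calls({"g1": "up"}), tiny_rep, "M99")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["up", "down", "null"]), min_size=1, max_size=10))
    def test_matches_exhaustive_recount(self, call_vector):
        genes = [f"g{i}" for i in range(len(call_vector))]
        rep = build_repertoire({"M": genes}, {"M": "A1"})
        calls = self.make_calls(dict(zip(genes, call_vector)))
        entry = fp.module_response(calls, rep, "M")
        n_up = sum(1 for c in call_vector if c == "up")
        n_down = sum(1 for c in call_vector if c == "down")
        assert entry["pct_up"] == pytest.approx(100 * n_up / len(call_vector))
        assert entry["pct_down"] == pytest.approx(100 * n_down / len(call_vector))
        assert entry["response"] == pytest.approx(entry["pct_up"] - entry["pct_down"])
        assert -100 <= entry["response"] <= 100


class TestGrid:
    def test_round_trip_through_tsv(self, tmp_path, tiny_rep):
        calls = pd.DataFrame({"call": pd.Series({g: "up" for g in tiny_rep.all_genes})})
        profile = fp.module_response_profile(calls, tiny_rep)
        grid = fp.fingerprint_grid(profile, tiny_rep)
        grid.to_tsv(tmp_path / "grid.tsv")
        back = fp.FingerprintGrid.from_tsv(tmp_path / "grid.tsv")
        pd.testing.assert_frame_equal(back.table, grid.table)

    def test_single_saturated_cell_at_fixed_position(self, tiny_rep):
        calls = {g: "null" for g in tiny_rep.all_genes}
        for g in tiny_rep.genes_of("M2.1"):
            calls[g] = "up"
        profile = fp.module_response_profile(pd.DataFrame({"call": pd.Series(calls)}), tiny_rep)
        grid = fp.fingerprint_grid(profile, tiny_rep).table.set_index("module_id")
        assert grid.loc["M2.1", "response"] == 100.0
        assert (grid.loc["M2.1", "row"], grid.loc["M2.1", "col"]) == tiny_rep.grid["M2.1"]
        assert (grid.drop("M2.1")["response"] == 0).all()

    def test_png_renders(self, tmp_path, tiny_rep):
        calls = pd.DataFrame({"call": pd.Series({g: "down" for g in tiny_rep.all_genes})})
        profile = fp.module_response_profile(calls, tiny_rep)
        out = tmp_path / "grid.png"
        fp.fingerprint_grid(profile, tiny_rep).to_png(out)
        assert out.stat().st_size > 0


def test_response_bounds_hold_on_simulated_study(mini_study):
    profiles = fp.fingerprint_profiles(mini_study.cohort_a, mini_study.repertoire, "P2")
    for profile in profiles.values():
        assert profile["response"].between(-100, 100).all()
        assert (profile["pct_up"] + profile["pct_down"] <= 100 + 1e-9).all()
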