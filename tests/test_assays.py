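"""Tests for the bench-assay quantification stage."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hsrpipe import (densitometry_normalize, fold_over_baseline,
                     generate_ct_table, generate_viability, group_test,
                     pool_group_stats, relative_expression, viability_percent)
from hsrpipe.errors import ConfigError, DegenerateInputError, InputError


def ct_fixture(**kw):
    return generate_ct_table(
        n_lines=3, conditions=["unstressed", "HS", "HS+R"],
        true_folds={"HSPA1A": {"HS": 8.0, "HS+R": 2.0}},
        line_folds={"HSPA1A": {"line2": 0.5}}, **kw)


class TestRelativeExpression:
    def test_reference_line_anchors_at_one(self):
        rel = relative_expression(ct_fixture(), ["GAPDH", "TBP"], "line1")
        ref = rel.loc[rel["line"] == "line1", "relative_expression"]
        np.testing.assert_allclose(ref, 1.0)

    def test_known_line_fold_recovered(self):
        rel = relative_expression(ct_fixture(), ["GAPDH", "TBP"], "line1")
        l2 = rel.loc[rel["line"] == "line2", "relative_expression"]
        np.testing.assert_allclose(l2, 0.5)  # planted half expression

    def test_one_cycle_below_reference_doubles(self):
        ct = pd.DataFrame([
            {"line": ln, "condition": "c", "gene": g, "ct": v}
            for ln, g, v in [("ref", "T", 25.0), ("ref", "HK1", 20.0),
                             ("ref", "HK2", 22.0),
                             ("mut", "T", 24.0), ("mut", "HK1", 20.0),
                             ("mut", "HK2", 22.0)]])
        rel = relative_expression(ct, ["HK1", "HK2"], "ref")
        mut = rel.loc[rel["line"] == "mut", "relative_expression"].iloc[0]
        assert mut == pytest.approx(2.0)

    def test_ct_shift_invariance(self):
        # adding a constant to every Ct of a (line, condition) cancels out
        ct = ct_fixture()
        shifted = ct.copy()
        mask = (shifted["line"] == "line3") & (shifted["condition"] == "HS")
        shifted.loc[mask, "ct"] += 3.7
        a = relative_expression(ct, ["GAPDH", "TBP"], "line1")
        b = relative_expression(shifted, ["GAPDH", "TBP"], "line1")
        np.testing.assert_allclose(a["relative_expression"],
                                   b["relative_expression"], rtol=1e-12)

    def test_degenerate_efficiency_warns(self):
        with pytest.warns(UserWarning, match="efficiency=1"):
            rel = relative_expression(ct_fixture(), ["GAPDH", "TBP"],
                                      "line1", efficiency=1.0)
        np.testing.assert_allclose(rel["relative_expression"], 1.0)

    def test_missing_housekeeping_is_an_error(self):
        ct = ct_fixture()
        ct = ct.loc[~((ct["gene"] == "GAPDH") & (ct["line"] == "line2")
                      & (ct["condition"] == "HS"))]
        with pytest.raises(InputError, match="line2"):
            relative_expression(ct, ["GAPDH", "TBP"], "line1")


class TestFoldOverBaseline:
    def test_round_trip_recovers_true_folds(self):
        # ddCt path: housekeeping-normalized quantities, each line against
        # its own baseline condition
        rel = relative_expression(ct_fixture(), ["GAPDH", "TBP"],
                                  reference_line=None)
        fc = fold_over_baseline(rel, "unstressed")
        hs = fc.loc[fc["condition"] == "HS", "fold_over_baseline"]
        np.testing.assert_allclose(hs, 8.0, rtol=1e-12)
        base = fc.loc[fc["condition"] == "unstressed", "fold_over_baseline"]
        np.testing.assert_allclose(base, 1.0)

    def test_simple_division(self):
        fc = pd.DataFrame({"line": ["l", "l"], "condition": ["base", "HS"],
                           "gene": ["g", "g"],
                           "relative_expression": [2.0, 6.0]})
        out = fold_over_baseline(fc, "base")
        assert out["fold_over_baseline"].tolist() == [1.0, 3.0]

    def test_missing_baseline_error(self):
        fc = pd.DataFrame({"line": ["l"], "condition": ["HS"],
                           "gene": ["g"], "relative_expression": [2.0]})
        with pytest.raises(InputError):
            fold_over_baseline(fc, "base")


class TestPoolGroupStats:
    def test_mean_and_sem(self):
        df = pd.DataFrame({"line": ["a", "b", "c"],
                           "fold_over_baseline": [2.0, 4.0, 6.0]})
        out = pool_group_stats(df, {"a": "ctrl", "b": "ctrl", "c": "ctrl"})
        assert out["mean"].iloc[0] == 4.0
        assert out["sem"].iloc[0] == pytest.approx(1.1547, abs=1e-4)

    def test_single_line_flags_undefined_sem(self):
        df = pd.DataFrame({"line": ["a"], "fold_over_baseline": [5.0]})
        out = pool_group_stats(df, {"a": "ctrl"})
        assert out["mean"].iloc[0] == 5.0
        assert np.isnan(out["sem"].iloc[0]) and not out["sem_defined"].iloc[0]

    def test_identical_values_zero_sem(self):
        df = pd.DataFrame({"line": list("abc"),
                           "fold_over_baseline": [3.0] * 3})
        assert pool_group_stats(df, dict.fromkeys("abc", "g"))[
            "sem"].iloc[0] == 0.0


class TestGroupTest:
    def test_two_groups_t(self):
        out = group_test({"ctrl": [1, 2, 3], "pat": [4, 5, 6]})
        assert out["p_value"] == pytest.approx(0.0213, abs=5e-5)

    def test_identical_groups(self):
        out = group_test({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert out["p_value"] == 1.0

    def test_anova_with_pairwise_correction(self):
        out = group_test({"a": [1.0, 2, 3], "b": [4.0, 5, 6],
                          "c": [1.5, 2.5, 3.5]}, design="one_way_anova")
        assert 0 < out["p_value"] < 1
        pw = out["pairwise"]
        assert len(pw) == 3
        assert (pw["p_adjusted"] >= pw["p_raw"] - 1e-15).all()

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            group_test({"a": [1, 1], "b": [2, 2]})

    def test_unknown_correction_rejected(self):
        with pytest.raises(ConfigError):
            group_test({"a": [1, 2], "b": [3, 4]}, correction="nope")


class TestViability:
    def test_stable_signal_is_100_percent(self):
        trace = generate_viability(n_lines=1, half_life_h=np.inf,
                                   noise_sd=0.0)
        out = viability_percent(trace)
        np.testing.assert_allclose(out["percent"], 100.0, rtol=1e-12)

    def test_floor_signal_is_0_percent(self):
        rows = []
        for t in (0.0, 1.0, 2.0):
            rows.append({"well": "w1", "line": "l1", "time_h": t,
                         "signal": 1000.0 if t == 0 else 50.0,
                         "negative_control": False})
            rows.append({"well": "neg", "line": "triton", "time_h": t,
                         "signal": 50.0, "negative_control": True})
        out = viability_percent(pd.DataFrame(rows))
        late = out.loc[out["time_h"] > 0, "percent"]
        np.testing.assert_allclose(late, 0.0, atol=1e-9)

    def test_half_life_round_trip(self):
        trace = generate_viability(n_lines=2, half_life_h=2.0, noise_sd=0.0)
        out = viability_percent(trace)
        expected = 100.0 * 2.0 ** (-out["time_h"] / 2.0)
        np.testing.assert_allclose(out["percent"], expected, rtol=1e-9)

    def test_degenerate_plate_rejected(self):
        trace = generate_viability(n_lines=1)
        trace.loc[~trace["negative_control"], "signal"] = 10.0  # below floor
        with pytest.raises(DegenerateInputError):
            viability_percent(trace)


class TestDensitometry:
    def test_examples(self):
        d = pd.DataFrame({"lane": ["ref", "x"],
                          "band_intensity": [3.0, 4.0],
                          "loading_control_intensity": [3.0, 2.0]})
        out = densitometry_normalize(d, "ref")
        assert out.loc[out["lane"] == "ref",
                       "relative_to_reference"].iloc[0] == 1.0
        assert out.loc[out["lane"] == "x",
                       "relative_to_reference"].iloc[0] == 2.0

    def test_zero_loading_rejected(self):
        d = pd.DataFrame({"lane": ["ref"], "band_intensity": [1.0],
                          "loading_control_intensity": [0.0]})
        with pytest.raises(InputError):
            densitometry_normalize(d, "ref")

    @given(st.floats(0.1, 10.0), st.integers(0, 1000))
    def test_global_rescaling_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        d = pd.DataFrame({
            "lane": [f"l{i}" for i in range(5)],
            "band_intensity": rng.uniform(1, 100, 5),
            "loading_control_intensity": rng.uniform(1, 100, 5)})
        base = densitometry_normalize(d, "l0")
        scaled = d.assign(
            loading_control_intensity=d["loading_control_intensity"] * scale)
        out = densitometry_normalize(scaled, "l0")
        np.testing.assert_allclose(out["relative_to_reference"],
                                   base["relative_to_reference"], rtol=1e-12)
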