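"""Welch ANOVA, BH adjustment and studentized-range post-hoc tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import bloodmirna as bm
from bloodmirna.core import ConfigurationError

from conftest import make_processed


def test_identical_groups_give_f0_p1():
    g = np.array([3.0, 3.0, 3.0])
    F, df1, df2, p = bm.welch_anova([g, g, g, g, g])
    assert F == 0.0 and p == 1.0


def test_two_group_welch_equals_squared_welch_t():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = rng.normal(0, 1, rng.integers(3, 10))
        b = rng.normal(0.5, 2, rng.integers(3, 10))
        F, df1, df2, p = bm.welch_anova([a, b])
        t, pt = stats.ttest_ind(a, b, equal_var=False)
        assert F == pytest.approx(t * t, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-9)


def test_separated_hand_groups_are_significant():
    F, df1, df2, p = bm.welch_anova([np.array([1.0, 2, 3]), np.array([4.0, 5, 6])])
    assert p < 0.05


def test_welch_invariances():
    rng = np.random.default_rng(1)
    groups = [rng.normal(i, 1 + i, 6) for i in range(4)]
    F0, *_ = bm.welch_anova(groups)
    Fshift, *_ = bm.welch_anova([g + 17.3 for g in groups])
    Fscale, *_ = bm.welch_anova([g * 4.2 for g in groups])
    assert Fshift == pytest.approx(F0, rel=1e-10)
    assert Fscale == pytest.approx(F0, rel=1e-10)


def test_welch_frame_matches_pingouin_oracle():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.normal(5, 2, (20, 15)), columns=[f"s{i}" for i in range(15)]
    )
    groups = pd.Series(
        ["A"] * 5 + ["B"] * 5 + ["C"] * 5, index=values.columns
    )
    result = bm.welch_anova_frame(values, groups)
    for probe in values.index[:10]:
        long = pd.DataFrame(
            {"y": values.loc[probe].to_numpy(), "g": groups.to_numpy()}
        )
        ref = pingouin.welch_anova(data=long, dv="y", between="g")
        assert result.loc[probe, "F"] == pytest.approx(ref["F"][0], rel=1e-8)
        assert result.loc[probe, "p"] == pytest.approx(ref["p_unc"][0], rel=1e-8)
        assert result.loc[probe, "df2"] == pytest.approx(ref["ddof2"][0], rel=1e-8)


def test_group_with_one_value_is_error():
    with pytest.raises(bm.PipelineError):
        bm.welch_anova([np.array([1.0]), np.array([2.0, 3.0])])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def _bh_bruteforce(p):
    """Independent step-up: q_(i) = min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def test_bh_hand_example():
    q = bm.bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_equal_and_single_p_pass_through():
    assert np.allclose(bm.bh_adjust([0.2, 0.2, 0.2]), 0.2)
    assert np.allclose(bm.bh_adjust([0.33]), 0.33)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
def test_bh_matches_bruteforce_stepup(p):
    assert np.allclose(bm.bh_adjust(p), _bh_bruteforce(p), atol=1e-12)


def test_bh_preserves_p_order_and_bounds():
    rng = np.random.default_rng(3)
    p = rng.uniform(0, 1, 200)
    q = bm.bh_adjust(p)
    assert ((q >= p - 1e-15) & (q <= 1.0)).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(bm.PipelineError):
        bm.bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# Post-hoc tests
# ---------------------------------------------------------------------------


def test_posthoc_identical_groups_one_subset():
    rng = np.random.default_rng(0)
    g = {c: rng.normal(0, 1, 6) for c in "abcde"}
    same = {c: g["a"] + rng.normal(0, 1e-6, 6) for c in g}
    res = bm.posthoc(same, mode="tukey")
    assert not res.significant.to_numpy().any()
    assert len(res.subsets) == 1 and set(res.subsets[0]) == set("abcde")


def test_posthoc_shifted_group_yields_exactly_four_pairs():
    rng = np.random.default_rng(1)
    groups = {c: rng.normal(0, 0.01, 5) for c in "abcd"}
    groups["z"] = rng.normal(50, 0.01, 5)
    res = bm.posthoc(groups, mode="tukey")
    sig_pairs = res.significant.to_numpy().sum() // 2
    assert sig_pairs == 4
    assert res.significant["z"].drop("z").all()


def test_tukey_matches_scipy_decisions():
    rng = np.random.default_rng(5)
    for _ in range(10):
        groups = {f"g{i}": rng.normal(i * 0.8, 1.0, 6) for i in range(4)}
        res = bm.posthoc(groups, mode="tukey", alpha=0.05)
        ref = stats.tukey_hsd(*groups.values())
        names = list(groups)
        for i in range(4):
            for j in range(i + 1, 4):
                assert bool(res.significant.loc[names[i], names[j]]) == bool(
                    ref.pvalue[i, j] < 0.05
                )


def test_snk_middle_group_joins_both_subsets():
    """Three ordered means where only the extremes differ."""
    resid = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
    groups = {"low": resid, "mid": resid + 0.9, "high": resid + 1.8}
    res = bm.posthoc(groups, mode="snk", alpha=0.05)
    assert bool(res.significant.loc["low", "high"])
    assert not res.significant.loc["low", "mid"]
    assert not res.significant.loc["mid", "high"]
    assert res.subsets == [["low", "mid"], ["mid", "high"]]


def test_snk_blocks_subranges_of_retained_ranges():
    # extremes non-significant -> everything inside declared homogeneous
    resid = np.array([-1.0, 0.0, 1.0, -0.5, 0.5])
    groups = {"a": resid, "b": resid + 0.1, "c": resid + 0.2}
    res = bm.posthoc(groups, mode="snk")
    assert not res.significant.to_numpy().any()
    assert len(res.subsets) == 1


def test_unknown_posthoc_mode_is_config_error():
    with pytest.raises(ConfigurationError):
        bm.posthoc({"a": [1.0, 2], "b": [3.0, 4]}, mode="duncan")


# ---------------------------------------------------------------------------
# Per-lineage DE lists
# ---------------------------------------------------------------------------


def test_planted_granulocyte_probe_lands_in_granulocyte_list(study):
    result = bm.de_by_cell_type(study["proc"])
    planted_gran = [
        p
        for p, (cts, fc) in study["truth"].de_probes.items()
        if cts == frozenset({"granulocyte"}) and fc >= 8
    ]
    gran_list = set(result.by_cell_type["granulocyte"]["probe"])
    assert set(planted_gran) <= gran_list


def test_absent_lineage_routes_probe_to_snk():
    rng = np.random.default_rng(0)
    vals = {}
    cts = {}
    for ct in ["A", "B", "C"]:
        for rep in range(3):
            s = f"{ct}{rep}"
            present = rng.uniform(100, 200, 2)
            vals[s] = np.array([0.0 if ct == "A" else present[0], present[1]])
            cts[s] = ct
    proc = make_processed(pd.DataFrame(vals, index=["absent_in_A", "everywhere"]), cts)
    result = bm.de_by_cell_type(proc)
    assert result.table.loc["absent_in_A", "mode"] == "snk"
    assert result.table.loc["everywhere", "mode"] == "tukey"


def test_selectively_reduced_rule(study):
    proc = study["proc"]
    result = bm.de_by_cell_type(proc)
    means = proc.cell_type_means()
    for probe in result.selectively_reduced:
        assert (means.loc[probe] > 5000).sum() >= 2
        assert (means.loc[probe] < 10).sum() >= 1
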