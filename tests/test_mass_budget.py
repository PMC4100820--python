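"""Mass chain: AUC fractions, per-cell masses, per-volume apportionment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bloodmirna as bm
from bloodmirna.core import ElectropherogramTrace, MassBudget
from bloodmirna.synthetic import (
    MIRNA_FG_PER_CELL,
    MIRNA_PG_PER_UL_BLOOD,
    TOTAL_RNA_FG_PER_CELL,
)


def _rect_trace(lo=0.0, hi=300.0, height=2.0, n=301):
    x = np.linspace(lo, hi, n)
    return ElectropherogramTrace(x, np.full(n, height))


def test_auc_rectangle_half():
    assert bm.auc_fraction(_rect_trace(), 150.0) == pytest.approx(0.5)


def test_auc_triangle_quarter():
    x = np.linspace(0.0, 300.0, 601)
    tri = ElectropherogramTrace(x, x.copy())
    assert bm.auc_fraction(tri, 150.0) == pytest.approx(0.25, rel=1e-6)


@pytest.mark.parametrize("cutoff,expected", [(-5.0, 0.0), (0.0, 0.0), (300.0, 1.0), (999.0, 1.0)])
def test_auc_cutoffs_outside_range_clamp(cutoff, expected):
    assert bm.auc_fraction(_rect_trace(), cutoff) == expected


def test_auc_zero_area_is_error():
    trace = ElectropherogramTrace([0.0, 1.0], [0.0, 0.0])
    with pytest.raises(bm.PipelineError):
        bm.auc_fraction(trace, 0.5)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_auc_fraction_monotone_in_cutoff(seed):
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.uniform(0.5, 3.0, 40))
    y = rng.uniform(0.0, 5.0, 40)
    if np.trapezoid(y, x) == 0:
        y[5] = 1.0
    trace = ElectropherogramTrace(x, y)
    cuts = np.linspace(x[0] - 1, x[-1] + 1, 23)
    fracs = [bm.auc_fraction(trace, c) for c in cuts]
    assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))


# ---------------------------------------------------------------------------
# Per-cell masses and fold ratios
# ---------------------------------------------------------------------------


def test_total_rna_per_cell_platelet():
    assert bm.total_rna_per_cell(2.20, 1e6) == pytest.approx(2.20)


def test_total_rna_per_cell_zero_mass():
    assert bm.total_rna_per_cell(0.0, 1e6) == 0.0


def test_lineage_fold_ratios_to_2dp():
    t_over_b = bm.fold_ratio(
        TOTAL_RNA_FG_PER_CELL["T-cell"], TOTAL_RNA_FG_PER_CELL["B-cell"]
    )
    b_over_g = bm.fold_ratio(
        TOTAL_RNA_FG_PER_CELL["B-cell"], TOTAL_RNA_FG_PER_CELL["granulocyte"]
    )
    assert round(t_over_b, 2) == 1.61
    assert round(b_over_g, 2) == 2.10


def test_mirna_fraction_is_product_of_auc_fractions():
    tot, small, _ = bm.generate_electropherogram(1.0, 0.5, 0.5, seed=0, noise_sd=0.0)
    assert bm.mirna_fraction_of_total(tot, small) == pytest.approx(0.25, rel=1e-3)


def test_platelet_like_fraction_yields_005_fg():
    target = MIRNA_FG_PER_CELL["platelet"] / TOTAL_RNA_FG_PER_CELL["platelet"]
    f = np.sqrt(target)
    tot, small, _ = bm.generate_electropherogram(2.2, f, f, seed=1, noise_sd=0.0)
    frac = bm.mirna_fraction_of_total(tot, small)
    assert 2.20 * frac == pytest.approx(0.05, rel=1e-2)


def test_zero_mirna_peak_gives_zero_fraction():
    tot, small, _ = bm.generate_electropherogram(1.0, 0.5, 0.0, seed=0, noise_sd=0.0)
    assert bm.mirna_fraction_of_total(tot, small) == 0.0


# ---------------------------------------------------------------------------
# Per-volume contributions
# ---------------------------------------------------------------------------


def test_per_volume_unit_conversion():
    budget = pd.DataFrame(
        {"mirna_fg_per_cell": [0.04, 0.0], "cells_per_ul": [4.6e6, 100.0]},
        index=["erythrocyte", "none"],
    )
    pg, _ = bm.per_volume_contribution(budget)
    assert pg["erythrocyte"] == pytest.approx(184.0)
    assert pg["none"] == 0.0


def test_rank_order_of_lineage_contributions():
    budget = pd.DataFrame(
        {
            "mirna_fg_per_cell": [MIRNA_FG_PER_CELL[ct] for ct in bm.CELL_TYPES],
            "cells_per_ul": [
                MIRNA_PG_PER_UL_BLOOD[ct] / MIRNA_FG_PER_CELL[ct] * 1e3
                for ct in bm.CELL_TYPES
            ],
        },
        index=list(bm.CELL_TYPES),
    )
    _, order = bm.per_volume_contribution(budget)
    assert order == ["erythrocyte", "granulocyte", "platelet", "T-cell", "B-cell"]


def _uniform_budget(cts, per_cell=1.0, conc=1.0):
    table = pd.DataFrame(
        {
            "total_rna_fg_per_cell": per_cell,
            "mirna_fraction_of_total": 1.0,
            "mirna_fg_per_cell": per_cell,
            "cells_per_ul": conc,
            "mirna_pg_per_ul_blood": per_cell * conc * 1e-3,
        },
        index=list(cts),
    )
    return MassBudget(table)


def test_apportion_single_cell_type_gets_100_percent():
    cts = ["A", "B", "C"]
    frac = pd.DataFrame([[0.0, 0.4, 0.0]], index=["m"], columns=cts)
    shares = bm.apportion_blood_shares(frac, _uniform_budget(cts))
    assert shares.shares.loc["m", "B"] == pytest.approx(100.0)
    assert shares.shares.loc["m", ["A", "C"]].eq(0.0).all()


def test_apportion_symmetric_inputs_give_20_percent_each():
    cts = list("ABCDE")
    frac = pd.DataFrame([[0.1] * 5], index=["m"], columns=cts)
    shares = bm.apportion_blood_shares(frac, _uniform_budget(cts))
    assert np.allclose(shares.shares.loc["m"], 20.0)


def test_apportion_recovers_planted_share_pattern():
    """Mass components planted proportional to 0/84/10/5/1 come back exactly."""
    cts = list(bm.CELL_TYPES)
    target = np.array([0.0, 84.0, 10.0, 5.0, 1.0])
    budget = _uniform_budget(cts, per_cell=2.0, conc=500.0)
    frac = pd.DataFrame([target / (2.0 * 500.0)], index=["m"], columns=cts)
    shares = bm.apportion_blood_shares(frac, budget)
    assert np.allclose(shares.shares.loc["m"].to_numpy(), target, atol=1e-9)


def test_apportion_scale_invariance_in_cell_concentrations():
    cts = list("ABC")
    rng = np.random.default_rng(5)
    frac = pd.DataFrame(rng.uniform(0, 0.2, (10, 3)), columns=cts)
    s1 = bm.apportion_blood_shares(frac, _uniform_budget(cts, conc=10.0))
    s2 = bm.apportion_blood_shares(frac, _uniform_budget(cts, conc=70.0))
    pd.testing.assert_frame_equal(s1.shares, s2.shares)


def test_apportion_zero_total_probe_flagged_null():
    cts = list("AB")
    frac = pd.DataFrame([[0.0, 0.0], [0.1, 0.3]], index=["dead", "live"], columns=cts)
    shares = bm.apportion_blood_shares(frac, _uniform_budget(cts))
    assert bool(shares.zero_total["dead"]) and not bool(shares.zero_total["live"])
    assert shares.shares.loc["dead"].isna().all()


def test_apportion_cell_type_mismatch_lists_difference():
    frac = pd.DataFrame([[0.1, 0.2]], columns=["A", "B"])
    with pytest.raises(bm.PipelineError, match="C"):
        bm.apportion_blood_shares(frac, _uniform_budget(["A", "C"]))


def test_build_mass_budget_reproduces_study_table(study):
    records = bm.generate_cell_records(seed=0)
    traces = bm.generate_study_traces(seed=0, noise_sd=0.0)
    mb = bm.build_mass_budget(records, traces)
    for ct in bm.CELL_TYPES:
        assert mb.table.loc[ct, "total_rna_fg_per_cell"] == pytest.approx(
            TOTAL_RNA_FG_PER_CELL[ct], rel=1e-6
        )
        assert mb.table.loc[ct, "mirna_fg_per_cell"] == pytest.approx(
            MIRNA_FG_PER_CELL[ct], rel=0.01
        )
        assert mb.table.loc[ct, "mirna_pg_per_ul_blood"] == pytest.approx(
            MIRNA_PG_PER_UL_BLOOD[ct], rel=0.01
        )
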