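"""Per-cell RNA/miRNA mass budgeting and blood-volume apportionment.

The mass chain runs in three stages.  First, total RNA per cell in
femtograms: extracted RNA (ng) times 1e6 over the number of cells extracted.
Second, the miRNA fraction of total RNA from two capillary-electrophoresis
traces: the area fraction of the total-RNA trace below 150 nt (small RNA)
times the area fraction of the small-RNA-assay trace below 40 nt (miRNA).
Third, mass per blood volume: miRNA fg/cell times cells/µl times 1e-3 gives
pg/µl of blood.

Apportionment distributes each individual miRNA's blood mass across the
lineages: the mass component of lineage *c* for probe *m* is that lineage's
average relative abundance of *m* times its per-cell miRNA mass times its
blood concentration, and the share is the component as a percentage of the
probe's summed components.  Shares use cell-type-average abundances, are
conserved to 100% per probe at full precision, and are rounded to whole
percent only at serialization time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import RelativeAbundanceTable
from .core import (
    BloodShareTable,
    CellPrepTable,
    ElectropherogramTrace,
    MassBudget,
    PipelineError,
)

#: Assay size cutoffs (nt): small RNA within total RNA, and miRNA within
#: the small-RNA fraction.
SMALL_RNA_CUTOFF_NT = 150.0
MIRNA_CUTOFF_NT = 40.0


def auc_fraction(trace: ElectropherogramTrace, cutoff_nt: float) -> float:
    """Fraction of trapezoidal area at sizes below ``cutoff_nt``.

    The intensity is linearly interpolated at the cutoff; cutoffs outside the
    size range clamp to 0 or 1.
    """
    total = float(np.trapezoid(trace.intensity, trace.size))
    if total <= 0:
        raise PipelineError("trace has zero total area")
    if cutoff_nt <= trace.size[0]:
        return 0.0
    if cutoff_nt >= trace.size[-1]:
        return 1.0
    mask = trace.size < cutoff_nt
    x = np.append(trace.size[mask], cutoff_nt)
    y = np.append(
        trace.intensity[mask], np.interp(cutoff_nt, trace.size, trace.intensity)
    )
    return float(np.trapezoid(y, x) / total)


def total_rna_per_cell(total_rna_ng: float, cells: float) -> float:
    """Total RNA per cell in femtograms: ng x 1e6 / cells."""
    if cells <= 0:
        raise PipelineError("cells must be > 0 for per-cell RNA mass")
    if total_rna_ng < 0:
        raise PipelineError("total_rna_ng must be >= 0")
    return total_rna_ng * 1e6 / cells


def fold_ratio(a: float, b: float) -> float:
    """Fold difference a/b (used for cross-lineage per-cell RNA comparisons)."""
    if b <= 0:
        raise PipelineError("fold_ratio denominator must be > 0")
    return a / b


def mirna_fraction_of_total(
    total_trace: ElectropherogramTrace,
    small_trace: ElectropherogramTrace,
    small_cutoff_nt: float = SMALL_RNA_CUTOFF_NT,
    mirna_cutoff_nt: float = MIRNA_CUTOFF_NT,
) -> float:
    """miRNA mass fraction of total RNA from the two assay traces."""
    return auc_fraction(total_trace, small_cutoff_nt) * auc_fraction(
        small_trace, mirna_cutoff_nt
    )


def per_volume_contribution(budget: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """pg of miRNA per µl blood per cell type, plus the lineage rank order.

    ``budget`` needs columns ``mirna_fg_per_cell`` and ``cells_per_ul``;
    fg/cell x cells/µl x 1e-3 = pg/µl.
    """
    if (budget[["mirna_fg_per_cell", "cells_per_ul"]] < 0).any().any():
        raise PipelineError("mass-budget inputs must be >= 0")
    pg = budget["mirna_fg_per_cell"] * budget["cells_per_ul"] * 1e-3
    pg.name = "mirna_pg_per_ul_blood"
    order = list(pg.sort_values(ascending=False).index)
    return pg, order


def build_mass_budget(
    records: CellPrepTable,
    traces: dict[str, tuple[ElectropherogramTrace, ElectropherogramTrace]],
    small_cutoff_nt: float = SMALL_RNA_CUTOFF_NT,
    mirna_cutoff_nt: float = MIRNA_CUTOFF_NT,
) -> MassBudget:
    """Assemble the full per-lineage mass budget from records and traces."""
    missing = set(records.table.index) - set(traces)
    if missing:
        raise PipelineError(f"no traces for cell types: {sorted(missing)}")
    rows = {}
    for ct, rec in records.table.iterrows():
        tot_trace, small_trace = traces[ct]
        total_fg = total_rna_per_cell(rec["total_rna_ng"], rec["cells_extracted"])
        frac = mirna_fraction_of_total(
            tot_trace, small_trace, small_cutoff_nt, mirna_cutoff_nt
        )
        rows[ct] = {
            "total_rna_fg_per_cell": total_fg,
            "mirna_fraction_of_total": frac,
            "mirna_fg_per_cell": total_fg * frac,
            "cells_per_ul": rec["cells_per_ul_blood"],
        }
    table = pd.DataFrame(rows).T
    pg, _ = per_volume_contribution(table)
    table["mirna_pg_per_ul_blood"] = pg
    return MassBudget(table)


def apportion_blood_shares(
    abund: RelativeAbundanceTable | pd.DataFrame, budget: MassBudget
) -> BloodShareTable:
    """Percentage contribution of each lineage to each miRNA's blood mass.

    ``abund`` is a RelativeAbundanceTable (its cell-type averages are used)
    or a probes x cell-types fraction frame.  Probes with zero total mass
    across lineages get NaN shares and are flagged rather than erroring.
    """
    frac = (
        abund.cell_type_avg if isinstance(abund, RelativeAbundanceTable) else abund
    )
    mismatch = set(frac.columns) ^ set(budget.cell_types)
    if mismatch:
        raise PipelineError(
            f"cell types differ between abundance and budget: {sorted(mismatch)}"
        )
    cols = list(frac.columns)
    per_cell = budget.table.loc[cols, "mirna_fg_per_cell"]
    conc = budget.table.loc[cols, "cells_per_ul"]
    # fg/µl blood contributed by lineage c to probe m
    mass = frac * (per_cell * conc)
    totals = mass.sum(axis=1)
    zero = totals <= 0
    shares = mass.div(totals.where(~zero), axis=0) * 100.0
    shares[zero] = np.nan
    return BloodShareTable(
        shares=shares,
        total_pg_per_ul=totals * 1e-3,
        zero_total=zero,
    )
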