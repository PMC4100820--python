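"""Relative abundance, ranking and detection analysis.

Normalized, background-corrected counts are converted to relative abundances
by dividing each probe's value by the sample's total; lineage profiles are
the arithmetic means of member samples' fractions.  Detection works on the
same corrected scale: a probe is expressed above background in a sample iff
its corrected value is positive, and "detected in a cell type" defaults to a
positive cell-type mean (an ``any-sample`` rule is available, since either
reading is compatible with per-lineage detection summaries).  Expression
classes use the conventional low/high cutoffs of 10 and 5,000 counts applied
to the cell-type mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfigurationError, PipelineError, ProcessedMatrix


@dataclass
class RelativeAbundanceTable:
    """Per-sample fractions, per-lineage average fractions and ranks."""

    fractions: pd.DataFrame       # probes x samples, each column sums to 1
    cell_type_avg: pd.DataFrame   # probes x cell types
    ranks: pd.DataFrame           # probes x cell types, 1 = most abundant


@dataclass
class DetectionSummary:
    expressed_per_cell_type: pd.Series   # mean per-sample expressed count
    detected_in: pd.DataFrame            # probes x cell types, bool
    classes: pd.DataFrame                # probes x cell types, str labels
    low: float
    high: float

    @property
    def cell_types(self) -> pd.Index:
        return self.detected_in.columns

    @property
    def n_detected_any(self) -> int:
        return int(self.detected_in.any(axis=1).sum())

    @property
    def n_detected_all(self) -> int:
        return int(self.detected_in.all(axis=1).sum())

    @property
    def n_not_detected(self) -> int:
        return int((~self.detected_in.any(axis=1)).sum())

    def class_counts(self) -> pd.DataFrame:
        """Per cell type: number of probes in each expression class."""
        return self.classes.apply(pd.Series.value_counts).fillna(0).astype(int)

    def to_dict(self) -> dict:
        return {
            "detected_in_any": self.n_detected_any,
            "detected_in_all": self.n_detected_all,
            "not_detected": self.n_not_detected,
            "expressed_per_cell_type": self.expressed_per_cell_type.to_dict(),
            "low_threshold": self.low,
            "high_threshold": self.high,
        }


def relative_abundance(proc: ProcessedMatrix) -> RelativeAbundanceTable:
    """Fraction of each sample's total counts carried by each probe.

    Raises on an all-zero sample (the fraction is undefined there).
    """
    totals = proc.values.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise PipelineError(f"sample {zero[0]!r} has zero total counts")
    fractions = proc.values.div(totals, axis=1)
    ct = proc.cell_types()
    avg = fractions.T.groupby(ct).mean().T
    # rank per lineage: descending abundance, ties broken by probe id
    ranks = pd.DataFrame(index=avg.index, columns=avg.columns, dtype=int)
    for c in avg.columns:
        order = sorted(avg[c].items(), key=lambda kv: (-kv[1], kv[0]))
        ranks[c] = pd.Series(
            {probe: i + 1 for i, (probe, _) in enumerate(order)}
        )
    return RelativeAbundanceTable(fractions=fractions, cell_type_avg=avg, ranks=ranks)


def top_n_union(table: RelativeAbundanceTable, n: int = 20) -> list[str]:
    """Union of each lineage's ``n`` most abundant probes.

    Order is deterministic: probes appear in cell-type column order, then by
    rank within the cell type, first appearance wins.
    """
    if len(table.cell_type_avg.index) < n:
        raise ConfigurationError(
            f"top_n_union: need >= {n} probes, have {len(table.cell_type_avg.index)}"
        )
    seen: list[str] = []
    for c in table.cell_type_avg.columns:
        top = table.ranks[c].sort_values().index[:n]
        for probe in top:
            if probe not in seen:
                seen.append(probe)
    return seen


def detection_summary(
    proc: ProcessedMatrix,
    low: float = 10.0,
    high: float = 5000.0,
    rule: str = "mean",
) -> DetectionSummary:
    """Detection sets and expression classes across lineages.

    ``rule='mean'``: detected in a cell type iff the cell-type mean corrected
    value is positive; ``rule='any-sample'``: iff any member sample is
    positive.  Classes (on the cell-type mean): ``not detected``, ``low``
    (< ``low``), ``high`` (> ``high``), else ``mid``.  The per-cell-type
    expressed count is the mean over member samples of the number of probes
    above background in that sample.
    """
    if low >= high:
        raise ConfigurationError(f"low threshold ({low}) must be < high ({high})")
    if rule not in ("mean", "any-sample"):
        raise ConfigurationError(f"unknown detection rule {rule!r}")
    ct = proc.cell_types()
    means = proc.cell_type_means()
    if rule == "mean":
        detected = means > 0
    else:
        detected = (proc.values > 0).T.groupby(ct).any().T

    classes = pd.DataFrame("mid", index=means.index, columns=means.columns)
    classes = classes.where(~(means < low), "low")
    classes = classes.where(~(means > high), "high")
    classes = classes.where(detected, "not detected")

    per_sample_expressed = (proc.values > 0).sum(axis=0)
    expressed = per_sample_expressed.groupby(ct).mean()
    return DetectionSummary(
        expressed_per_cell_type=expressed,
        detected_in=detected,
        classes=classes,
        low=low,
        high=high,
    )
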