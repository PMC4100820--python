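"""Shared data containers for the blood-cell miRNA pipeline.

The pipeline moves count data through a handful of tabular containers, all
backed by pandas so they serialize to plain CSV.  Probe classes follow the
hybridization-counting convention: ``Endogenous`` probes target real miRNAs,
``Negative`` probes carry no target and estimate background, ``Positive``
probes are spike-in controls (carried through but never analyzed here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_CLASSES = ("Endogenous", "Negative", "Positive")

#: Canonical lineage labels used by the synthetic generator and the default
#: cell-record table, in the column order of the study design.
CELL_TYPES = ("platelet", "T-cell", "B-cell", "granulocyte", "erythrocyte")


class PipelineError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PipelineError):
    """A configuration value is invalid; the message names the field."""


class ValidationError(PipelineError):
    """Input data violates a container invariant."""


class FormatError(PipelineError):
    """A file does not conform to the expected tabular format."""


@dataclass
class RawCountMatrix:
    """Probe-level counts (probes x samples) with probe classes and sample
    annotations.

    Parameters
    ----------
    counts
        Nonnegative values, indexed by probe id, one column per sample.
    probe_class
        Series mapping probe id to one of ``Endogenous | Negative | Positive``.
    samples
        One row per sample (index = sample id) with columns ``donor`` and
        ``cell_type``.
    codeset_version
        Free-text assay/codeset version tag.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    samples: pd.DataFrame
    codeset_version: str = ""

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate probe ids: {list(dupes)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            r, c = np.argwhere(self.counts.to_numpy() < 0)[0]
            raise ValidationError(
                f"negative count for probe {self.counts.index[r]!r} "
                f"in sample {self.counts.columns[c]!r}"
            )
        self.probe_class = self.probe_class.reindex(self.counts.index)
        if self.probe_class.isna().any():
            missing = self.counts.index[self.probe_class.isna()]
            raise ValidationError(f"probes without class: {list(missing)[:5]}")
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise ValidationError(f"unknown probe classes: {sorted(bad)}")
        missing_samples = set(self.counts.columns) - set(self.samples.index)
        if missing_samples:
            raise ValidationError(
                f"samples without annotation: {sorted(missing_samples)}"
            )
        for col in ("donor", "cell_type"):
            if col not in self.samples.columns:
                raise ValidationError(f"sample sheet missing column {col!r}")
        self.samples = self.samples.loc[list(self.counts.columns)]
        self.counts.index.name = "probe"
        self.samples.index.name = "sample"

    # ------------------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_probes(self) -> int:
        return len(self.counts.index)

    @property
    def n_endogenous(self) -> int:
        return int((self.probe_class == "Endogenous").sum())

    def endogenous(self) -> pd.DataFrame:
        return self.counts.loc[self.probe_class == "Endogenous"]

    def negative(self) -> pd.DataFrame:
        return self.counts.loc[self.probe_class == "Negative"]

    def cell_type_of(self, sample: str) -> str:
        return str(self.samples.loc[sample, "cell_type"])

    def restrict_probes(self, probes: list[str]) -> "RawCountMatrix":
        return RawCountMatrix(
            counts=self.counts.loc[probes].copy(),
            probe_class=self.probe_class.loc[probes].copy(),
            samples=self.samples.copy(),
            codeset_version=self.codeset_version,
        )


@dataclass
class ProcessedMatrix:
    """Normalized (and optionally background-corrected) expression.

    ``values`` holds the endogenous rows only; negative-control rows,
    normalized by the same per-sample factors, live in ``negatives`` so the
    background step can be computed or audited afterwards.
    """

    values: pd.DataFrame
    negatives: pd.DataFrame
    factors: pd.Series
    samples: pd.DataFrame
    thresholds: pd.Series | None = None
    threshold_overridden: pd.Series | None = None
    background_mode: str | None = None

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            bad = self.factors.index[self.factors <= 0][0]
            raise ValidationError(f"nonpositive normalization factor for {bad!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("processed values must be >= 0")
        if self.thresholds is not None and (self.thresholds < 0).any():
            raise ValidationError("background thresholds must be >= 0")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def cell_types(self) -> pd.Series:
        return self.samples.loc[list(self.values.columns), "cell_type"]

    def cell_type_means(self) -> pd.DataFrame:
        """Per cell type arithmetic mean of member samples (probes x types)."""
        ct = self.cell_types()
        return self.values.T.groupby(ct).mean().T


@dataclass
class ElectropherogramTrace:
    """Capillary-electrophoresis trace: fluorescence vs fragment size (nt)."""

    size: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.size = np.asarray(self.size, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.size.ndim != 1 or self.size.size < 2:
            raise ValidationError("trace needs >= 2 points")
        if self.size.shape != self.intensity.shape:
            raise ValidationError("size and intensity length mismatch")
        if not (np.isfinite(self.size).all() and np.isfinite(self.intensity).all()):
            raise ValidationError("trace values must be finite")
        if (np.diff(self.size) <= 0).any():
            raise ValidationError("size coordinate must be strictly increasing")
        if (self.intensity < 0).any():
            raise ValidationError("intensity must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size_nt": self.size, "intensity": self.intensity})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ElectropherogramTrace":
        return cls(df["size_nt"].to_numpy(), df["intensity"].to_numpy())


@dataclass
class CellPrepTable:
    """Per cell type: cells extracted, total RNA yield (ng) and blood
    concentration (cells per microliter)."""

    table: pd.DataFrame  # index: cell_type; columns below

    REQUIRED = ("cells_extracted", "total_rna_ng", "cells_per_ul_blood")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"cell-prep table missing column {col!r}")
            if (self.table[col] <= 0).any():
                bad = self.table.index[self.table[col] <= 0][0]
                raise ValidationError(
                    f"cell-prep value {col!r} must be > 0 (cell type {bad!r})"
                )
        self.table.index.name = "cell_type"


@dataclass
class MassBudget:
    """Per cell type RNA/miRNA mass accounting (per cell and per µl blood)."""

    table: pd.DataFrame
    # columns: total_rna_fg_per_cell, mirna_fraction_of_total,
    #          mirna_fg_per_cell, cells_per_ul, mirna_pg_per_ul_blood

    def __post_init__(self) -> None:
        t = self.table
        if (t < 0).any().any():
            raise ValidationError("mass budget entries must be >= 0")
        expect = t["total_rna_fg_per_cell"] * t["mirna_fraction_of_total"]
        if not np.allclose(expect, t["mirna_fg_per_cell"], rtol=1e-9, atol=1e-12):
            raise ValidationError(
                "mirna_fg_per_cell must equal total_rna_fg_per_cell x fraction"
            )

    @property
    def cell_types(self) -> pd.Index:
        return self.table.index


@dataclass
class BloodShareTable:
    """Per-probe apportionment of blood miRNA mass across cell types.

    ``shares`` rows are percentages summing to 100 (pre-rounding) except for
    probes with zero total mass, which carry NaN shares and are flagged.
    """

    shares: pd.DataFrame            # probes x cell types, percent
    total_pg_per_ul: pd.Series      # per probe
    zero_total: pd.Series = field(default=None)  # bool per probe

    def __post_init__(self) -> None:
        if self.zero_total is None:
            self.zero_total = pd.Series(False, index=self.shares.index)
        ok = ~self.zero_total
        sums = self.shares.loc[ok].sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-6):
            raise ValidationError("non-null share rows must sum to 100%")

    def rounded(self) -> pd.DataFrame:
        """Whole-percent display table (rows may sum to 99-101 after rounding)."""
        return self.shares.round(0)
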