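"""Synthetic study generator.

Emulates the design of the profiling study the pipeline targets: five highly
purified blood cell lineages (platelets, T-cells, B-cells, granulocytes,
erythrocytes) sampled from the same five donors, profiled on a
hybridization-counting codeset of ~623 endogenous miRNA probes plus negative
controls, together with capillary-electrophoresis size traces and per-cell-type
cell-count / RNA-yield records.  Every downstream stage is testable against
the planted ground truth returned alongside each artifact.

Counts are lognormal-around-lineage-profile and then rounded: the counting
platform reports deterministic molecule counts, and all downstream statistics
operate on normalized continuous values, so a lognormal mean/dispersion model
is the simplest one matching the analysis assumptions (a negative-binomial
error model would add nothing the pipeline measures).  The donor effect is a
single additive log2 shift shared by all of one donor's samples, emulating
paired sampling of the same individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CELL_TYPES,
    CellPrepTable,
    ConfigurationError,
    ElectropherogramTrace,
    RawCountMatrix,
)

# ---------------------------------------------------------------------------
# Study constants
# ---------------------------------------------------------------------------

#: Per-cell total RNA mass (femtogram/cell) for the five lineages, as
#: measured in the study this pipeline reproduces.  Used (together with the
#: per-µl masses below) to back-compute realistic default cell-record and
#: size-fraction parameters; the back-computation is deliberate — the study
#: does not print its raw CBC counts.
TOTAL_RNA_FG_PER_CELL = {
    "platelet": 2.20,
    "T-cell": 2187.97,
    "B-cell": 1360.34,
    "granulocyte": 646.30,
    "erythrocyte": 0.57,
}

#: Per-cell miRNA mass (femtogram/cell), same provenance.
MIRNA_FG_PER_CELL = {
    "platelet": 0.05,
    "T-cell": 3.28,
    "B-cell": 3.16,
    "granulocyte": 10.23,
    "erythrocyte": 0.04,
}

#: miRNA mass per blood volume (picogram/µl), same provenance.
MIRNA_PG_PER_UL_BLOOD = {
    "platelet": 16.90,
    "T-cell": 3.55,
    "B-cell": 0.64,
    "granulocyte": 50.24,
    "erythrocyte": 184.0,
}

#: Cells extracted per preparation (defaults; realistic bench-scale yields).
CELLS_EXTRACTED = {
    "platelet": 1.0e9,
    "T-cell": 5.0e6,
    "B-cell": 2.0e6,
    "granulocyte": 5.0e6,
    "erythrocyte": 5.0e9,
}


def default_cell_concentrations() -> dict[str, float]:
    """Cells per µl blood consistent with the per-cell and per-volume masses."""
    return {
        ct: MIRNA_PG_PER_UL_BLOOD[ct] / MIRNA_FG_PER_CELL[ct] * 1e3
        for ct in CELL_TYPES
    }


def default_mirna_fractions() -> dict[str, float]:
    """miRNA fraction of total RNA per lineage (dimensionless)."""
    return {
        ct: MIRNA_FG_PER_CELL[ct] / TOTAL_RNA_FG_PER_CELL[ct] for ct in CELL_TYPES
    }


# ---------------------------------------------------------------------------
# Configuration / ground truth
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of the count-matrix simulation.

    ``de_plan`` entries are ``(probe_id, lineages, fold_change)``: the probe's
    log2 mean is raised by ``log2(fold_change)`` in every named lineage.
    ``stable_plan`` probes receive no lineage effect and a reduced residual
    SD (``stable_residual_sd``) — planted reference-normalizer candidates.
    """

    n_donors: int = 5
    cell_types: Sequence[str] = CELL_TYPES
    n_endogenous: int = 623
    n_negative: int = 6
    de_plan: list[tuple[str, frozenset, float]] = field(default_factory=list)
    stable_plan: list[str] = field(default_factory=list)
    baseline_log_mean: float = 6.0
    probe_baseline_sd: float = 3.5
    donor_sd: float = 0.3
    residual_sd: float = 0.25
    stable_residual_sd: float = 0.05
    neg_mean: float = 8.0
    neg_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_types = tuple(self.cell_types)
        self.de_plan = [
            (p, frozenset(cts), float(fc)) for p, cts, fc in self.de_plan
        ]
        if self.n_donors < 2:
            raise ConfigurationError("n_donors must be >= 2")
        if len(self.cell_types) < 2:
            raise ConfigurationError("cell_types must list >= 2 lineages")
        if self.n_endogenous < 1:
            raise ConfigurationError("n_endogenous must be >= 1")
        if self.n_negative < 2:
            raise ConfigurationError("n_negative must be >= 2")
        for probe, cts, fc in self.de_plan:
            if fc <= 0:
                raise ConfigurationError(f"de_plan fold change for {probe!r} must be > 0")
            unknown = cts - set(self.cell_types)
            if unknown:
                raise ConfigurationError(
                    f"de_plan names unknown cell types {sorted(unknown)}"
                )
        for name, value in (
            ("donor_sd", self.donor_sd),
            ("residual_sd", self.residual_sd),
            ("stable_residual_sd", self.stable_residual_sd),
            ("neg_mean", self.neg_mean),
            ("neg_sd", self.neg_sd),
        ):
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        overlap = {p for p, _, _ in self.de_plan} & set(self.stable_plan)
        if overlap:
            raise ConfigurationError(
                f"probes cannot be both DE-planted and stable: {sorted(overlap)}"
            )

    def probe_ids(self) -> list[str]:
        return [f"mir-{i:04d}" for i in range(1, self.n_endogenous + 1)]

    def negative_ids(self) -> list[str]:
        return [f"NEG_{chr(ord('A') + i)}" for i in range(self.n_negative)]


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    true_log2_means: pd.DataFrame | None = None     # probes x cell types
    de_probes: dict[str, tuple[frozenset, float]] = field(default_factory=dict)
    stable_probes: list[str] = field(default_factory=list)
    small_fraction: float | None = None             # total-RNA AUC < 150 nt
    mirna_fraction_of_small: float | None = None    # small-RNA AUC < 40 nt
    cell_concentrations: dict[str, float] | None = None


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-scale configuration with a realistic planted structure.

    Plants six lineage-preferential miRNAs per lineage (fold changes 4-64,
    emulating the strong lineage markers the real profiles show), five stable
    low-dispersion normalizer candidates, and one erythrocyte-dominant probe
    so abundant it emulates the single miRNA that carries nearly half the
    erythrocyte content.
    """
    de_plan: list[tuple[str, frozenset, float]] = []
    idx = 1
    for ct in CELL_TYPES:
        for fc in (4, 8, 8, 16, 32, 64):
            de_plan.append((f"mir-{idx:04d}", frozenset({ct}), float(fc)))
            idx += 1
    # lymphoid-shared probe (elevated in both lymphocyte lineages)
    de_plan.append((f"mir-{idx:04d}", frozenset({"T-cell", "B-cell"}), 16.0))
    idx += 1
    # erythrocyte-dominant, very large effect on a high baseline probe
    de_plan.append((f"mir-{idx:04d}", frozenset({"erythrocyte"}), 512.0))
    stable_plan = [f"mir-{i:04d}" for i in range(601, 606)]
    cfg = dict(seed=seed, de_plan=de_plan, stable_plan=stable_plan)
    cfg.update(overrides)
    return SimulationConfig(**cfg)


# ---------------------------------------------------------------------------
# Count-matrix generation
# ---------------------------------------------------------------------------


def generate_count_dataset(
    config: SimulationConfig,
) -> tuple[RawCountMatrix, GroundTruth]:
    """Simulate a probes x samples count matrix with annotated sample sheet.

    Endogenous counts are ``round(2 ** (baseline_i + lineage_effect_ic +
    donor_effect_d + residual))``; negative controls are truncated-normal at
    zero (only their first two moments matter to the background threshold).
    Identical seeds produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    probes = config.probe_ids()
    negs = config.negative_ids()
    cts = list(config.cell_types)
    donors = [f"D{d + 1}" for d in range(config.n_donors)]

    baselines = rng.normal(
        config.baseline_log_mean, config.probe_baseline_sd, size=len(probes)
    )
    base = pd.Series(baselines, index=probes)
    # Stable normalizer candidates sit at a moderate, fixed expression level.
    for p in config.stable_plan:
        base.loc[p] = config.baseline_log_mean + 2.0

    true_means = pd.DataFrame(
        np.tile(base.to_numpy()[:, None], (1, len(cts))), index=probes, columns=cts
    )
    for probe, lineages, fc in config.de_plan:
        for ct in lineages:
            true_means.loc[probe, ct] += np.log2(fc)

    donor_effect = {d: rng.normal(0.0, config.donor_sd) for d in donors}
    res_sd = pd.Series(config.residual_sd, index=probes)
    res_sd.loc[list(config.stable_plan)] = config.stable_residual_sd

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for ct in cts:
        for d in donors:
            sample = f"{ct}_{d}"
            log2_expr = (
                true_means[ct].to_numpy()
                + donor_effect[d]
                + rng.normal(0.0, 1.0, size=len(probes)) * res_sd.to_numpy()
            )
            endo = np.round(np.exp2(log2_expr))
            if config.neg_sd > 0:
                a = (0.0 - config.neg_mean) / config.neg_sd
                neg = stats.truncnorm.rvs(
                    a, np.inf, loc=config.neg_mean, scale=config.neg_sd,
                    size=len(negs), random_state=rng,
                )
            else:
                neg = np.full(len(negs), config.neg_mean)
            columns[sample] = np.concatenate([endo, np.round(neg)])
            sheet_rows.append({"sample": sample, "donor": d, "cell_type": ct})

    counts = pd.DataFrame(columns, index=probes + negs)
    probe_class = pd.Series(
        ["Endogenous"] * len(probes) + ["Negative"] * len(negs), index=probes + negs
    )
    samples = pd.DataFrame(sheet_rows).set_index("sample")
    matrix = RawCountMatrix(counts, probe_class, samples, codeset_version="sim-v1")
    truth = GroundTruth(
        true_log2_means=true_means,
        de_probes={p: (cts_, fc) for p, cts_, fc in config.de_plan},
        stable_probes=list(config.stable_plan),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Electropherograms
# ---------------------------------------------------------------------------


def _compact_gaussian(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    """Gaussian peak truncated to ±6 SD (exact zero outside its window)."""
    g = np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    return np.where(np.abs(x - mu) > 6 * sd, 0.0, g)


def generate_electropherogram(
    total_mass_ng: float,
    small_fraction: float,
    mirna_fraction_of_small: float,
    seed: int = 0,
    noise_sd: float = 0.02,
) -> tuple[ElectropherogramTrace, ElectropherogramTrace, GroundTruth]:
    """Simulate a total-RNA and a small-RNA size trace with known fractions.

    The total-RNA trace carries a small-RNA peak (<150 nt) holding
    ``small_fraction`` of the area plus two ribosomal-RNA-like peaks; the
    small-RNA-assay trace carries a miRNA peak (<40 nt) holding
    ``mirna_fraction_of_small`` of its area plus a larger small-RNA peak.
    Peak positions keep each component entirely on its side of the assay
    cutoff, so the area fractions reproduce the inputs to well under 1%.
    """
    for name, f in (
        ("small_fraction", small_fraction),
        ("mirna_fraction_of_small", mirna_fraction_of_small),
    ):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {f}")
    if total_mass_ng < 0:
        raise ValueError("total_mass_ng must be >= 0")
    rng = np.random.default_rng(seed)

    # total-RNA assay: 20-4500 nt
    x_tot = np.linspace(20.0, 4500.0, 1600)
    small_peak = _compact_gaussian(x_tot, 70.0, 13.0)       # support < 150 nt
    rrna_18s = _compact_gaussian(x_tot, 1900.0, 100.0)
    rrna_28s = _compact_gaussian(x_tot, 3900.0, 150.0)
    y_tot = total_mass_ng * (
        small_fraction * small_peak
        + (1.0 - small_fraction) * (0.45 * rrna_18s + 0.55 * rrna_28s)
    )
    # small-RNA assay: 4-160 nt
    x_small = np.linspace(4.0, 160.0, 800)
    mirna_peak = _compact_gaussian(x_small, 22.0, 3.0)      # support < 40 nt
    other_small = _compact_gaussian(x_small, 95.0, 9.0)     # support > 40 nt
    y_small = total_mass_ng * small_fraction * (
        mirna_fraction_of_small * mirna_peak
        + (1.0 - mirna_fraction_of_small) * other_small
    )

    if noise_sd > 0:
        y_tot = y_tot * np.clip(1.0 + rng.normal(0, noise_sd, y_tot.shape), 0, None)
        y_small = y_small * np.clip(
            1.0 + rng.normal(0, noise_sd, y_small.shape), 0, None
        )

    truth = GroundTruth(
        small_fraction=small_fraction,
        mirna_fraction_of_small=mirna_fraction_of_small,
    )
    return (
        ElectropherogramTrace(x_tot, y_tot),
        ElectropherogramTrace(x_small, y_small),
        truth,
    )


# ---------------------------------------------------------------------------
# Cell records
# ---------------------------------------------------------------------------


def generate_cell_records(seed: int = 0, jitter: float = 0.0) -> CellPrepTable:
    """Per-cell-type extraction records and blood concentrations.

    Defaults reproduce the study's per-cell RNA masses exactly
    (``total_rna_ng * 1e6 / cells_extracted`` equals the per-cell femtogram
    values above); ``jitter`` > 0 applies a multiplicative lognormal
    perturbation with that log-SD for stochastic scenarios.
    """
    rng = np.random.default_rng(seed)
    conc = default_cell_concentrations()
    rows = {}
    for ct in CELL_TYPES:
        cells = CELLS_EXTRACTED[ct]
        ng = TOTAL_RNA_FG_PER_CELL[ct] * cells / 1e6
        rows[ct] = {
            "cells_extracted": cells,
            "total_rna_ng": ng,
            "cells_per_ul_blood": conc[ct],
        }
    table = pd.DataFrame(rows).T
    if jitter > 0:
        table = table * np.exp(rng.normal(0.0, jitter, size=table.shape))
    return CellPrepTable(table)


def generate_study_traces(
    seed: int = 0, noise_sd: float = 0.02
) -> dict[str, tuple[ElectropherogramTrace, ElectropherogramTrace]]:
    """One (total-RNA, small-RNA) trace pair per lineage.

    Size fractions are chosen so that the resulting miRNA fraction of total
    RNA matches each lineage's per-cell miRNA:total ratio: the total-trace
    small fraction is set to ``sqrt(fraction)`` and the small-trace miRNA
    fraction likewise, so their product recovers the target ratio.
    """
    fractions = default_mirna_fractions()
    out = {}
    for i, ct in enumerate(CELL_TYPES):
        f = float(np.sqrt(fractions[ct]))
        total_ng = TOTAL_RNA_FG_PER_CELL[ct] * CELLS_EXTRACTED[ct] / 1e6
        tot, small, _ = generate_electropherogram(
            total_ng, f, f, seed=seed + 101 * i, noise_sd=noise_sd
        )
        out[ct] = (tot, small)
    return out
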