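"""Count normalization and negative-control background correction.

Lane (sample) normalization follows the counting platform's standard
convention: each sample is scaled by the ratio of the across-sample mean of
the top-``n`` geometric means to the sample's own geometric mean of its
``n`` highest-expressed endogenous probes (n = 100 by default).  The
background threshold is the mean of the sample's normalized negative-control
probes plus ``k`` sample standard deviations (k = 2, SD with n-1
denominator), and is subtracted with a floor at zero — expression cannot be
negative, and a probe counts as "expressed above background" in a sample iff
its corrected value is positive.

Erythrocytes on this platform show anomalously low negative-control values;
to avoid flooding the erythrocyte profile with biologically irrelevant
low-level calls, their per-sample threshold is overridden with the mean of
the other lineages' own-sample thresholds (the override set is
configurable, as is a ``censor`` alternative that zeroes values at or below
threshold without shifting the rest).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    PipelineError,
    ProcessedMatrix,
    RawCountMatrix,
)


class NormalizationError(PipelineError):
    pass


def _top_n_geomean(col: pd.Series, top_n: int, pseudocount: float) -> float:
    # deterministic top-n: sort by count descending, ties by probe id
    order = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
    top = np.array([v for _, v in order[:top_n]], dtype=float) + pseudocount
    if (top <= 0).any():
        raise NormalizationError(
            f"sample {col.name!r}: top-{top_n} geometric mean is zero"
        )
    return float(np.exp(np.mean(np.log(top))))


def top100_geomean_normalize(
    raw: RawCountMatrix, top_n: int = 100, pseudocount: float = 0.0
) -> ProcessedMatrix:
    """Scale each sample to the cohort mean of top-``n`` geometric means.

    Negative-control rows are scaled by the same per-sample factor so the
    background threshold is computed on the normalized scale.
    """
    endo = raw.endogenous()
    if endo.shape[0] < top_n:
        raise NormalizationError(
            f"need >= {top_n} endogenous probes, have {endo.shape[0]}"
        )
    gms = pd.Series(
        {s: _top_n_geomean(endo[s], top_n, pseudocount) for s in endo.columns}
    )
    factors = gms.mean() / gms
    return ProcessedMatrix(
        values=endo.mul(factors, axis=1),
        negatives=raw.negative().mul(factors, axis=1),
        factors=factors,
        samples=raw.samples.copy(),
    )


def background_threshold(neg_values: Iterable[float], k: float = 2.0) -> float:
    """Mean of negative-control values plus ``k`` sample SDs (ddof = 1)."""
    vals = np.asarray(list(neg_values), dtype=float)
    if vals.size < 2:
        raise NormalizationError("background threshold needs >= 2 negative values")
    thr = float(vals.mean() + k * vals.std(ddof=1))
    return max(thr, 0.0)


def apply_background(
    pre: ProcessedMatrix,
    thresholds: pd.Series | None = None,
    override: Iterable[str] = ("erythrocyte",),
    k: float = 2.0,
    mode: str = "subtract",
) -> ProcessedMatrix:
    """Subtract (or censor at) the per-sample background threshold.

    ``thresholds`` defaults to mean + k*SD of each sample's normalized
    negative controls.  For samples of a cell type named in ``override``, the
    threshold is replaced by the mean of the own-sample thresholds of all
    samples of the *other* cell types, and the sample is flagged.

    ``mode='subtract'``: value' = max(value - threshold, 0).
    ``mode='censor'``:   value' = value if value > threshold else 0.
    """
    if mode not in ("subtract", "censor"):
        raise ConfigurationError(f"unknown background mode {mode!r}")
    cell_types = pre.cell_types()
    override = set(override)
    unknown = override - set(cell_types.unique())
    if unknown:
        raise ConfigurationError(
            f"override names unknown cell types: {sorted(unknown)}"
        )
    if thresholds is None:
        thresholds = pd.Series(
            {s: background_threshold(pre.negatives[s], k=k) for s in pre.sample_ids}
        )
    else:
        missing = set(pre.sample_ids) - set(thresholds.index)
        if missing:
            raise NormalizationError(f"thresholds missing samples: {sorted(missing)}")
        thresholds = thresholds.loc[list(pre.sample_ids)].astype(float)

    overridden = cell_types.isin(override)
    effective = thresholds.copy()
    if overridden.any():
        if (~overridden).sum() == 0:
            raise ConfigurationError("override cannot cover every cell type")
        other_mean = thresholds[~overridden.to_numpy()].mean()
        effective[overridden.to_numpy()] = other_mean

    if mode == "subtract":
        values = (pre.values - effective).clip(lower=0.0)
    else:
        values = pre.values.where(pre.values.gt(effective, axis=1), 0.0)

    return ProcessedMatrix(
        values=values,
        negatives=pre.negatives,
        factors=pre.factors,
        samples=pre.samples,
        thresholds=effective,
        threshold_overridden=overridden,
        background_mode=mode,
    )


def normalize_pipeline(
    raw: RawCountMatrix,
    top_n: int = 100,
    k: float = 2.0,
    override: Iterable[str] = ("erythrocyte",),
    mode: str = "subtract",
) -> ProcessedMatrix:
    """Full normalization: top-n geomean scaling then background correction."""
    pre = top100_geomean_normalize(raw, top_n=top_n)
    return apply_background(pre, override=override, k=k, mode=mode)
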