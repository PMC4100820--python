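"""Reference-normalizer selection: model-based stability and CV ranking.

For qRT-PCR validation across cell types one needs a reference miRNA whose
expression is as constant as possible across lineages.  Two criteria are
implemented side by side:

* A model-based stability value in the spirit of Andersen's reference-gene
  model: log-scale values are sample-centered (subtracting each sample's
  mean across candidate probes removes per-sample loading), then each probe
  is scored by combining the magnitude of its lineage-specific deviation
  (shrunken toward zero by an empirical-Bayes factor) with the sampling
  noise of its within-lineage variance:

      stability_i = mean_g( |d~_ig| + sqrt(s2_ig / n_g) )

  where d_ig is the probe's centered lineage-mean deviation from its overall
  mean, s2_ig its bias-corrected within-lineage variance (the correction
  subtracts the lineage's average candidate variance divided by (k - 1),
  compensating the covariance introduced by sample centering, and is floored
  at 0), and d~_ig = d_ig * gamma2 / (gamma2 + s2_ig / n_g) with gamma2 the
  moment estimate of the true inter-lineage variance (floored at 0).  Lower
  is more stable.

* The coefficient of variation, SD / mean over all samples on the linear
  normalized scale — scale-free and model-free.

Candidates absent from any lineage (all member samples zero) are excluded:
a normalizer must be expressed everywhere.  The qRT-PCR companion transform
2^-(Ct_target - Ct_reference) is provided for validation workflows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PipelineError, ProcessedMatrix


@dataclass
class StabilityRanking:
    """Per-probe stability metrics and the two ranked criteria."""

    table: pd.DataFrame
    # columns: stability, intra_var, inter_var, cv (NaN where excluded)

    def top_k(self, k: int = 10, by: str = "stability") -> pd.DataFrame:
        """k best candidates, ascending in the chosen criterion."""
        return self.table.dropna(subset=[by]).nsmallest(k, by)


def normfinder_stability(
    values: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Model-based stability on a probes x samples log2 matrix.

    Returns a frame with columns ``stability`` (lower = more stable),
    ``inter_var`` (mean squared lineage deviation) and ``intra_var`` (mean
    bias-corrected within-lineage variance).
    """
    labels = groups.loc[list(values.columns)]
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise PipelineError("stability needs >= 2 groups")
    if values.shape[0] < 3:
        raise PipelineError("stability needs >= 3 candidate probes")
    k = values.shape[0]
    x = values.to_numpy(dtype=float)
    # sample centering: remove per-sample loading shared by all candidates
    x = x - x.mean(axis=0, keepdims=True)

    n_g, d, s2 = [], [], []
    for u in uniq:
        mask = (labels == u).to_numpy()
        if mask.sum() < 2:
            raise PipelineError(f"group {u!r} has < 2 samples")
        xg = x[:, mask]
        n_g.append(mask.sum())
        d.append(xg.mean(axis=1))
        v = xg.var(axis=1, ddof=1)
        # bias correction for the covariance induced by sample centering
        v = np.maximum(v - v.mean() / (k - 1), 0.0)
        s2.append(v)
    n_g = np.asarray(n_g, dtype=float)
    d = np.stack(d, axis=1)                      # probes x groups
    d = d - x.mean(axis=1, keepdims=True)        # deviation from overall mean
    s2 = np.stack(s2, axis=1)

    G = len(uniq)
    noise = s2 / n_g[None, :]
    # moment estimate of the true inter-group variance, floored at 0
    gamma2 = max(
        (d ** 2).sum() / ((G - 1) * k) - noise.mean(), 0.0
    )
    shrink = gamma2 / (gamma2 + noise) if gamma2 > 0 else np.zeros_like(noise)
    d_shrunk = d * shrink
    stability = (np.abs(d_shrunk) + np.sqrt(noise)).mean(axis=1)
    return pd.DataFrame(
        {
            "stability": stability,
            "inter_var": (d ** 2).mean(axis=1),
            "intra_var": s2.mean(axis=1),
        },
        index=values.index,
    )


def cv_stability(values: pd.DataFrame) -> pd.Series:
    """Coefficient of variation per probe on linear values (SD/mean, ddof=1).

    Probes with nonpositive mean get NaN (flagged null, excluded from
    ranking) rather than erroring.
    """
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    cv = sd / mean.where(mean > 0)
    cv.name = "cv"
    return cv


def rank_normalizers(
    proc: ProcessedMatrix, pseudocount: float = 1.0
) -> StabilityRanking:
    """Rank every eligible probe by model stability and by CV.

    Input to the model criterion is log2(value + pseudocount); CV is computed
    on the linear normalized scale.  Probes with any all-zero lineage are
    excluded from candidacy.
    """
    ct = proc.cell_types()
    present = (proc.values > 0).T.groupby(ct).any().T
    eligible = present.all(axis=1)
    if eligible.sum() < 3:
        raise PipelineError("fewer than 3 probes expressed in every lineage")
    candidates = proc.values.loc[eligible]
    logvals = np.log2(candidates + pseudocount)
    model = normfinder_stability(logvals, ct)
    cv = cv_stability(candidates)
    table = pd.DataFrame(index=proc.values.index, columns=model.columns, dtype=float)
    table.loc[model.index] = model
    table["cv"] = cv.reindex(table.index)
    table.loc[~eligible, ["stability", "inter_var", "intra_var", "cv"]] = np.nan
    return StabilityRanking(table=table)


def delta_ct_normalize(ct_target: float, ct_reference: float) -> float:
    """Relative expression by the 2^-dCt rule against a reference gene."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise PipelineError("Ct values must be finite")
    return float(2.0 ** -(ct_target - ct_reference))
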