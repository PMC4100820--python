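"""Differential expression across hematopoietic lineages.

The omnibus test is Welch's unequal-variance one-way ANOVA with the
Welch-Satterthwaite denominator degrees of freedom, applied per probe with
Benjamini-Hochberg control of the false discovery rate at q < 0.05.
Post-hoc pairwise separation uses the studentized-range distribution:
Tukey's HSD (all pairs at family alpha) when a miRNA is present in all five
lineages, and the Student-Newman-Keuls stepwise procedure (range-dependent
critical values on ordered means) when it is absent in one or more — "absent"
meaning every sample of that lineage is zero after background subtraction.
Both post-hoc procedures use the classical pooled equal-variance critical
ranges even though the omnibus test is Welch's; the pairing is kept for
fidelity with the profiling workflow being reproduced rather than for
statistical purity.

Tests default to log2(x + 1) transformed processed values; the raw linear
scale is available via ``scale='linear'``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ConfigurationError, PipelineError, ProcessedMatrix


# ---------------------------------------------------------------------------
# Welch one-way ANOVA
# ---------------------------------------------------------------------------


def welch_anova(groups: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's unequal-variance one-way ANOVA.

    Returns ``(F, df1, df2, p)``.  Groups that are all constant and equal
    give ``F = 0, p = 1``; a zero within-group variance in an otherwise
    varying probe is floored at 1e-12 of the grand variance so a lineage
    that is uniformly zero still contributes a (large) mean separation.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise PipelineError("welch_anova needs >= 2 groups")
    for g in groups:
        if g.size < 2:
            raise PipelineError("every group needs >= 2 values")
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    k = len(groups)
    df1 = float(k - 1)

    allvals = np.concatenate(groups)
    grand_var = allvals.var(ddof=1)
    if grand_var == 0.0:
        return 0.0, df1, float("inf"), 1.0
    v = np.maximum(v, 1e-12 * grand_var)

    w = n / v
    W = w.sum()
    mw = (w * m).sum() / W
    A = (w * (m - mw) ** 2).sum() / df1
    t = ((1.0 - w / W) ** 2 / (n - 1.0)).sum()
    B = 1.0 + 2.0 * (k - 2.0) / (k * k - 1.0) * t
    F = float(A / B)
    df2 = float((k * k - 1.0) / (3.0 * t))
    p = float(stats.f.sf(F, df1, df2))
    return F, df1, df2, p


def welch_anova_frame(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Vectorized per-row Welch ANOVA over a probes x samples frame.

    ``groups`` maps sample id to lineage.  Returns a frame with columns
    ``F, df1, df2, p`` indexed like ``values``.
    """
    labels = groups.loc[list(values.columns)]
    uniq = list(dict.fromkeys(labels))
    k = len(uniq)
    if k < 2:
        raise PipelineError("need >= 2 groups")
    mats = [values.loc[:, (labels == u).to_numpy()].to_numpy() for u in uniq]
    n = np.array([m.shape[1] for m in mats], dtype=float)
    if (n < 2).any():
        raise PipelineError("every group needs >= 2 samples")
    means = np.stack([m.mean(axis=1) for m in mats], axis=1)
    varis = np.stack([m.var(axis=1, ddof=1) for m in mats], axis=1)
    grand_var = values.to_numpy().var(axis=1, ddof=1)

    degenerate = grand_var == 0.0
    safe_gv = np.where(degenerate, 1.0, grand_var)
    v = np.maximum(varis, 1e-12 * safe_gv[:, None])
    w = n[None, :] / v
    W = w.sum(axis=1)
    mw = (w * means).sum(axis=1) / W
    df1 = float(k - 1)
    A = (w * (means - mw[:, None]) ** 2).sum(axis=1) / df1
    t = ((1.0 - w / W[:, None]) ** 2 / (n[None, :] - 1.0)).sum(axis=1)
    B = 1.0 + 2.0 * (k - 2.0) / (k * k - 1.0) * t
    F = A / B
    df2 = (k * k - 1.0) / (3.0 * t)
    p = stats.f.sf(F, df1, df2)
    F = np.where(degenerate, 0.0, F)
    p = np.where(degenerate, 1.0, p)
    df2 = np.where(degenerate, np.inf, df2)
    return pd.DataFrame(
        {"F": F, "df1": df1, "df2": df2, "p": p}, index=values.index
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise PipelineError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Post-hoc: Tukey HSD and Student-Newman-Keuls
# ---------------------------------------------------------------------------


@dataclass
class PosthocResult:
    groups: list[str]
    significant: pd.DataFrame            # symmetric bool matrix
    q_statistic: pd.DataFrame            # observed studentized range per pair
    subsets: list[list[str]]             # homogeneous subsets on ordered means
    mode: str


def _homogeneous_subsets(order: list[str], sig: pd.DataFrame) -> list[list[str]]:
    """Maximal runs of mean-ordered groups with no significant pair inside."""
    subsets: list[list[str]] = []
    n = len(order)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and not any(
            sig.loc[order[a], order[b]]
            for a in range(i, j + 2)
            for b in range(a + 1, j + 2)
        ):
            j += 1
        run = order[i : j + 1]
        if not subsets or set(run) - set(subsets[-1]):
            subsets.append(run)
        i += 1
    # keep only maximal runs
    maximal = [s for s in subsets if not any(
        set(s) < set(t) for t in subsets if t is not s
    )]
    return maximal


def posthoc(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    mode: str = "tukey",
    alpha: float = 0.05,
) -> PosthocResult:
    """All-pairs post-hoc comparison on the studentized-range distribution.

    ``tukey``: every pair tested at family alpha with critical range
    ``q(alpha, k, df_w)`` (Tukey-Kramer standard error for unequal n).
    ``snk``: means are ordered and each pair's critical value uses the
    number of means it spans; a non-significant range protects all ranges
    nested inside it (classical stepwise logic).
    """
    if mode not in ("tukey", "snk"):
        raise ConfigurationError(f"unknown post-hoc mode {mode!r}")
    if not isinstance(groups, dict):
        groups = {f"g{i + 1}": g for i, g in enumerate(groups)}
    names = list(groups)
    data = {c: np.asarray(groups[c], dtype=float) for c in names}
    if len(names) < 2:
        raise PipelineError("posthoc needs >= 2 groups")
    n = {c: data[c].size for c in names}
    if min(n.values()) < 2:
        raise PipelineError("every group needs >= 2 values")
    m = {c: data[c].mean() for c in names}
    k = len(names)
    df_w = sum(n.values()) - k
    msw = sum((n[c] - 1) * data[c].var(ddof=1) for c in names) / df_w

    sig = pd.DataFrame(False, index=names, columns=names)
    qs = pd.DataFrame(0.0, index=names, columns=names)
    order = sorted(names, key=lambda c: m[c])

    def q_obs(a: str, b: str) -> float:
        se = np.sqrt(msw / 2.0 * (1.0 / n[a] + 1.0 / n[b]))
        if se == 0.0:
            return np.inf if m[a] != m[b] else 0.0
        return abs(m[a] - m[b]) / se

    if mode == "tukey":
        qcrit = stats.studentized_range.ppf(1.0 - alpha, k, df_w)
        for a, b in itertools.combinations(names, 2):
            q = q_obs(a, b)
            qs.loc[a, b] = qs.loc[b, a] = q
            if q > qcrit:
                sig.loc[a, b] = sig.loc[b, a] = True
    else:
        # SNK: test spans from widest to narrowest; a retained (non-
        # significant) range blocks every range nested inside it.
        blocked = pd.DataFrame(False, index=names, columns=names)
        pos = {c: i for i, c in enumerate(order)}
        for span in range(k, 1, -1):
            qcrit = stats.studentized_range.ppf(1.0 - alpha, span, df_w)
            for i in range(k - span + 1):
                a, b = order[i], order[i + span - 1]
                q = q_obs(a, b)
                qs.loc[a, b] = qs.loc[b, a] = q
                if blocked.loc[a, b]:
                    continue
                if q > qcrit:
                    sig.loc[a, b] = sig.loc[b, a] = True
                else:
                    for x in range(i, i + span):
                        for y in range(x + 1, i + span):
                            blocked.loc[order[x], order[y]] = True
                            blocked.loc[order[y], order[x]] = True
    subsets = _homogeneous_subsets(order, sig)
    return PosthocResult(
        groups=names, significant=sig, q_statistic=qs, subsets=subsets, mode=mode
    )


# ---------------------------------------------------------------------------
# Per-lineage DE lists
# ---------------------------------------------------------------------------


@dataclass
class DEResult:
    table: pd.DataFrame                  # F, df1, df2, p, q, mode, de per probe
    by_cell_type: dict[str, pd.DataFrame] = field(default_factory=dict)
    selectively_reduced: list[str] = field(default_factory=list)

    @property
    def n_de(self) -> int:
        return int(self.table["de"].sum())


def de_by_cell_type(
    proc: ProcessedMatrix,
    alpha_q: float = 0.05,
    posthoc_alpha: float = 0.05,
    scale: str = "log2p1",
    high: float = 5000.0,
    low: float = 10.0,
) -> DEResult:
    """Omnibus Welch ANOVA + BH, then post-hoc lineage assignment.

    A probe is globally DE iff q < ``alpha_q``.  It lands on a lineage's DE
    list iff the post-hoc test separates that lineage from all others; the
    direction is the sign of the lineage mean minus the mean of the rest.
    Post-hoc mode per probe: SNK when the probe is absent (all member
    samples zero) in at least one lineage, Tukey HSD otherwise.
    "Selectively reduced" probes are highly expressed (cell-type mean >
    ``high``) in at least two lineages yet below ``low`` in at least one.
    """
    if scale not in ("log2p1", "linear"):
        raise ConfigurationError(f"unknown DE scale {scale!r}")
    values = np.log2(proc.values + 1.0) if scale == "log2p1" else proc.values
    ct = proc.cell_types()
    cts = list(dict.fromkeys(ct))

    omnibus = welch_anova_frame(values, ct)
    omnibus["q"] = bh_adjust(omnibus["p"].to_numpy())
    present = (proc.values > 0).T.groupby(ct).any().T  # probe x ct: any positive
    omnibus["mode"] = np.where(present.all(axis=1), "tukey", "snk")
    omnibus["de"] = omnibus["q"] < alpha_q

    by_ct: dict[str, list[dict]] = {c: [] for c in cts}
    for probe in omnibus.index[omnibus["de"]]:
        row = values.loc[probe]
        grp = {c: row[(ct == c).to_numpy()].to_numpy() for c in cts}
        ph = posthoc(grp, mode=omnibus.loc[probe, "mode"], alpha=posthoc_alpha)
        for c in cts:
            others = [o for o in cts if o != c]
            if all(ph.significant.loc[c, o] for o in others):
                mean_c = grp[c].mean()
                mean_o = np.concatenate([grp[o] for o in others]).mean()
                by_ct[c].append(
                    {
                        "probe": probe,
                        "direction": "up" if mean_c > mean_o else "down",
                        "q": omnibus.loc[probe, "q"],
                    }
                )

    means = proc.cell_type_means()
    reduced = means.index[
        ((means > high).sum(axis=1) >= 2) & ((means < low).sum(axis=1) >= 1)
    ]
    return DEResult(
        table=omnibus,
        by_cell_type={
            c: pd.DataFrame(rows, columns=["probe", "direction", "q"])
            for c, rows in by_ct.items()
        },
        selectively_reduced=list(reduced),
    )
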