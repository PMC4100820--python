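"""Hierarchical clustering of samples on correlation distance.

Samples are compared by 1 - Pearson correlation between their expression
vectors (restricted to a probe list, conventionally the union of each
lineage's top-20 most abundant miRNAs, on log2(x + 1) values) and
agglomerated with complete linkage, whose merge heights are monotone
non-decreasing.  The log-ratio transform for heatmap display divides each
probe row by its own mean (with a +1 stabilizer) on the log2 scale, so rows
are centered near zero and lineage-preferential expression shows as
symmetric deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import PipelineError


@dataclass
class LinkageTree:
    """Complete-linkage merge history over correlation distance."""

    linkage: np.ndarray          # scipy linkage matrix (n-1 x 4)
    labels: list[str]            # leaf (sample) names, input order

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        order = hierarchy.dendrogram(self.linkage, no_plot=True)["leaves"]
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels (1..k) at k clusters."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def pearson_complete_linkage(
    values: pd.DataFrame, probes: list[str] | None = None
) -> LinkageTree:
    """Cluster samples (columns) by complete linkage on 1 - Pearson r.

    ``probes`` optionally restricts the rows used.  A constant sample vector
    makes the correlation undefined and raises, naming the sample.
    """
    sub = values.loc[probes] if probes is not None else values
    if sub.shape[1] < 2 or sub.shape[0] < 2:
        raise PipelineError("clustering needs >= 2 samples and >= 2 probes")
    X = sub.to_numpy(dtype=float).T  # samples x probes
    sds = X.std(axis=1)
    if (sds == 0).any():
        bad = sub.columns[np.argmax(sds == 0)]
        raise PipelineError(
            f"sample {bad!r} is constant; Pearson correlation undefined"
        )
    dist = pdist(X, metric="correlation")  # 1 - r
    Z = hierarchy.linkage(dist, method="complete")
    return LinkageTree(linkage=Z, labels=list(sub.columns))


def heatmap_logratio(values: pd.DataFrame) -> pd.DataFrame:
    """Per-row log2 ratio against the row mean: log2((x+1)/(mean+1)).

    Rows with zero mean come out all-zero (every entry is then zero too).
    """
    if (values.to_numpy() < 0).any():
        raise PipelineError("log-ratio input must be >= 0")
    row_mean = values.mean(axis=1)
    return np.log2(values.add(1.0).div(row_mean + 1.0, axis=0))
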