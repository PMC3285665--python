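"""Hierarchical clustering of the probe-response matrix.

Both axes of the lines x features fold-change matrix can be clustered —
cell lines by their response profiles, probes by their response patterns —
to produce the familiar two-way heatmap ordering.  An origin-purity score
quantifies how well a k-group cut of the line dendrogram recovers the
tissue-of-origin partition.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy


@dataclass
class Dendrogram:
    """Agglomerative tree for one axis of the feature matrix.

    ``Z`` is the standard (n-1) x 4 linkage matrix; leaf order follows the
    deterministic left-to-right traversal in which each merge lists the
    earlier-formed cluster first, so exchangeable leaves end up adjacent.
    """

    Z: np.ndarray
    labels: list[str]
    axis: str                      # "lines" | "probes"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def leaf_order(self) -> list[int]:
        return [int(i) for i in hierarchy.leaves_list(self.Z)]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def cut(self, k: int) -> np.ndarray:
        """Cluster assignment (1..k) from cutting the tree into k groups."""
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > self.n_leaves:
            raise ValueError("k exceeds the number of leaves")
        return hierarchy.fcluster(self.Z, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Serialize with branch lengths = parent height - child height."""
        n = self.n_leaves

        def node(i: int, parent_h: float) -> str:
            if i < n:
                return f"{self.labels[i]}:{parent_h:.6g}"
            a, b, h, _ = self.Z[i - n]
            inner = f"({node(int(a), h)},{node(int(b), h)})"
            return f"{inner}:{parent_h - h:.6g}"

        root_h = float(self.Z[-1, 2]) if len(self.Z) else 0.0
        return node(2 * n - 2, root_h) + ";" if n > 1 else f"{self.labels[0]};"


def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "lines",
                         metric: str = "euclidean",
                         method: str = "average") -> Dendrogram:
    """Cluster one axis of a (lines x features) matrix.

    The matrix is taken as given — pass log2 folds for ratio data.  NaNs are
    rejected; rows of ``matrix`` are clustered for ``axis="lines"``, columns
    for ``axis="probes"``.
    """
    if axis not in ("lines", "probes"):
        raise ValueError("axis must be 'lines' or 'probes'")
    data = matrix if axis == "lines" else matrix.T
    if len(data) < 2:
        raise ValueError("need >= 2 items on the clustered axis")
    X = np.asarray(data, dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains NaN")
    Z = hierarchy.linkage(X, method=method, metric=metric)
    return Dendrogram(Z, [str(i) for i in data.index], axis)


def origin_purity(dendro: Dendrogram, origins: Sequence[str],
                  k: int) -> float:
    """Majority-origin purity of a k-group cut, in [1/g, 1].

    purity = (sum over clusters of the majority-origin count) / n.  A cut
    into singletons trivially scores 1.0 — the measure rewards coarse cuts
    that still separate origins, e.g. k = 9 for the 9-origin panel.
    """
    if len(origins) != dendro.n_leaves:
        raise ValueError("one origin label per leaf required")
    assign = dendro.cut(k)
    labels = np.asarray(origins)
    correct = 0
    for c in np.unique(assign):
        _, counts = np.unique(labels[assign == c], return_counts=True)
        correct += int(counts.max())
    return correct / len(labels)
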