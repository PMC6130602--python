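"""Hierarchical clustering of profiles from likelihood-ratio statistics.

Large LR means strongly correlated evolution, so every LR is subtracted
from the largest observed LR to yield a symmetric distance matrix
(the best-supported pair sits at distance zero).  Profiles are then
merged by between-group average linkage (UPGMA) and clusters are read
off by cutting the dendrogram at a height ``h`` on the same LR scale:
merge heights are the plain between-group mean distances, not halved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = ["lr_to_distance", "upgma", "cut", "cut_k", "Dendrogram",
           "ClusterAssignment"]


def lr_to_distance(lr: pd.DataFrame) -> pd.DataFrame:
    """d(i, j) = max LR - LR(i, j) off-diagonal; d(i, i) = 0.

    Adding a constant to every LR leaves the distances unchanged.
    """
    if not lr.index.equals(lr.columns):
        raise ValueError("LR matrix must be square with matching labels")
    values = lr.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = [(lr.index[i], lr.columns[j])
               for i, j in zip(*np.where(np.isnan(values)))]
        raise ValueError(f"NaN LR entries for pairs: {bad[:10]}")
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValueError("LR matrix must be symmetric")
    off = ~np.eye(len(lr), dtype=bool)
    d = values.max(initial=-np.inf, where=off) - values
    d[~off] = 0.0
    return pd.DataFrame(d, index=lr.index, columns=lr.columns)


@dataclass
class Dendrogram:
    """UPGMA merge tree: scipy linkage matrix plus leaf identifiers.

    ``ids`` are in the (sorted) order matching linkage leaf indices.
    """

    ids: list
    linkage: np.ndarray

    def merge_table(self) -> pd.DataFrame:
        """One row per merge: step, left, right, height, size."""
        names = list(self.ids)
        rows = []
        for step, (a, b, h, size) in enumerate(self.linkage):
            left, right = names[int(a)], names[int(b)]
            names.append(f"node{step}")
            rows.append({"step": step, "left": left, "right": right,
                         "height": float(h), "size": int(size)})
        return pd.DataFrame(rows)

    def cophenetic(self) -> pd.DataFrame:
        d = hierarchy.cophenet(self.linkage)
        return pd.DataFrame(squareform(d), index=self.ids, columns=self.ids)

    def to_newick(self) -> str:
        """Dendrogram as Newick; branch lengths from merge heights."""
        n = len(self.ids)
        height = {i: 0.0 for i in range(n)}
        label = {i: str(self.ids[i]) for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node = n + step
            label[node] = f"({label[a]}:{la:.10g},{label[b]}:{lb:.10g})"
            height[node] = h
        return label[n + len(self.linkage) - 1] + ";"


@dataclass
class ClusterAssignment:
    """Partition of profiles: id -> cluster label (1-based ints)."""

    labels: pd.Series

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def members(self) -> dict:
        return {c: sorted(g.index) for c, g in self.labels.groupby(self.labels)}

    def nonsingleton(self) -> dict:
        return {c: m for c, m in self.members().items() if len(m) > 1}

    def to_tsv(self, path: str, header_lines=None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.labels.rename("cluster").to_csv(fh, sep="\t",
                                                 index_label="profile")


def upgma(d: pd.DataFrame) -> Dendrogram:
    """Between-group average-linkage clustering of a distance matrix.

    Ids are sorted lexically before linkage so the result does not
    depend on input order; equidistant merge ties follow that sorted
    order deterministically.
    """
    if not d.index.equals(d.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if len(d) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    ids = sorted(map(str, d.index))
    d = d.loc[ids, ids]
    values = d.to_numpy(dtype=float)
    if not np.allclose(np.diag(values), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    Z = hierarchy.linkage(squareform(values, checks=False), method="average")
    return Dendrogram(ids=ids, linkage=Z)


def cut(dend: Dendrogram, h: float) -> ClusterAssignment:
    """Clusters = leaf sets connected only through merges of height <= h."""
    if h < 0:
        raise ValueError("cut height must be >= 0")
    flat = hierarchy.fcluster(dend.linkage, t=h, criterion="distance")
    return ClusterAssignment(labels=pd.Series(flat, index=dend.ids))


def cut_k(dend: Dendrogram, k: int) -> ClusterAssignment:
    """Cut at the intermediate height that yields exactly ``k`` clusters
    (i.e. just below the k-1 highest merge)."""
    if not 1 <= k <= len(dend.ids):
        raise ValueError("k must be between 1 and the number of profiles")
    flat = hierarchy.fcluster(dend.linkage, t=k, criterion="maxclust")
    return ClusterAssignment(labels=pd.Series(flat, index=dend.ids))
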