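"""Ecotype clustering of per-sample taxonomic contribution profiles.

Samples are clustered by Ward's method on Manhattan (L1) distances between
their D_t profiles.  The Ward variant applies the Lance-Williams update
directly to the supplied dissimilarities (the behaviour of R's ``hclust``
``ward.D`` handed a Manhattan distance object); ``ward.D2``, which squares
the dissimilarities inside the update, is available as an option.  Note
ward.D on arbitrary dissimilarities may in principle produce height
inversions; they are recorded, not forbidden.

The implementation feeds sqrt(d) to scipy's Ward linkage and squares the
resulting heights, which is algebraically identical to running the ward.D
recurrence on d itself:

    e = sqrt(d)  =>  e'(k, ij)^2 = [(n_i+n_k) e_ki^2 + (n_j+n_k) e_kj^2
                                    - n_k e_ij^2] / (n_i+n_j+n_k)

is exactly the ward.D update on d.  Cluster counts are chosen automatically
by maximizing mean silhouette width; recurring compositions are labelled by
their dominant taxa ("T", "P+C", ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .contribution import ContributionProfile

__all__ = [
    "Dendrogram",
    "manhattan_distance_matrix",
    "ward_linkage",
    "cut_clusters",
    "label_ecotype",
    "assign_ecotypes",
    "to_newick",
    "DEFAULT_INITIALS",
]

#: Taxon -> initial used to compose ecotype labels.
DEFAULT_INITIALS = {
    "Thaumarchaeota": "T",
    "Proteobacteria": "P",
    "Cyanobacteria": "C",
}


def manhattan_distance_matrix(
    profile: ContributionProfile | pd.DataFrame,
) -> pd.DataFrame:
    """Pairwise L1 distances between sample profiles.

    d(i, j) = sum_t |D_it - D_jt|; symmetric with zero diagonal.
    """
    D = profile.D if isinstance(profile, ContributionProfile) else profile
    if len(D) < 2:
        raise ValueError("need >= 2 retained samples for a distance matrix")
    dist = squareform(pdist(D.to_numpy(dtype=float), metric="cityblock"))
    return pd.DataFrame(dist, index=D.index, columns=D.index)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge sequence in scipy linkage encoding.

    ``merges`` is an (n-1, 4) array: merged node ids (original leaves are
    0..n-1, new nodes n, n+1, ...), merge height on the input dissimilarity
    scale, and member count.  ``labels`` are the leaf (sample) ids.
    """

    merges: np.ndarray
    labels: tuple[str, ...]
    variant: str = "ward.D"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def has_inversions(self) -> bool:
        return bool(np.any(np.diff(self.heights) < -1e-12))

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self._scipy_linkage())
        return [self.labels[i] for i in order]

    def _scipy_linkage(self) -> np.ndarray:
        Z = self.merges.copy()
        # scipy plotting/traversal helpers expect non-decreasing heights.
        Z[:, 2] = np.maximum.accumulate(Z[:, 2])
        return Z

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "left": self.merges[:, 0].astype(int),
                "right": self.merges[:, 1].astype(int),
                "height": self.merges[:, 2],
                "size": self.merges[:, 3].astype(int),
            }
        )


def ward_linkage(
    dist: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | None = None,
    variant: str = "ward.D",
) -> Dendrogram:
    """Ward agglomeration of a dissimilarity matrix.

    ``variant="ward.D"`` applies the Lance-Williams update to the
    dissimilarities as supplied; ``"ward.D2"`` to their squares (heights
    returned on the original scale).
    """
    if isinstance(dist, pd.DataFrame):
        if labels is None:
            labels = [str(s) for s in dist.index]
        mat = dist.to_numpy(dtype=float)
    else:
        mat = np.asarray(dist, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if labels is None:
        labels = [str(i) for i in range(mat.shape[0])]
    condensed = squareform(mat, checks=False)
    if variant == "ward.D":
        Z = hierarchy.linkage(np.sqrt(condensed), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    elif variant == "ward.D2":
        Z = hierarchy.linkage(condensed, method="ward")
    else:
        raise ValueError(f"unknown ward variant {variant!r}")
    return Dendrogram(merges=Z, labels=tuple(labels), variant=variant)


def _cut_k(dend: Dendrogram, k: int) -> np.ndarray:
    """Cluster ids (0-based, ordered by first sample appearance) at k groups."""
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be within [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in range(n - k):
        left, right = int(dend.merges[m, 0]), int(dend.merges[m, 1])
        node = n + m
        parent[find(left)] = node
        parent[find(right)] = node
    roots: dict[int, int] = {}
    ids = np.empty(n, dtype=int)
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        ids[leaf] = roots[r]
    return ids


def cut_clusters(
    dend: Dendrogram,
    k: int | str = "auto",
    dist: pd.DataFrame | np.ndarray | None = None,
) -> np.ndarray:
    """Cut the merge sequence into k clusters.

    ``k="auto"`` scans k in [2, min(10, n-1)] and keeps the k maximizing
    mean silhouette width on ``dist`` (required in that case); ties go to
    the smallest k.  Cluster ids are deterministic: numbered by first
    appearance in leaf (sample) order.
    """
    if k == "auto":
        if dist is None:
            raise ValueError('k="auto" needs the distance matrix')
        mat = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
        best_k, best_width = None, -np.inf
        for kk in range(2, min(10, dend.n_leaves - 1) + 1):
            ids = _cut_k(dend, kk)
            if len(np.unique(ids)) < 2:
                continue
            width = silhouette_score(mat, ids, metric="precomputed")
            if width > best_width + 1e-12:
                best_k, best_width = kk, width
        if best_k is None:
            raise ValueError("could not select k automatically")
        return _cut_k(dend, best_k)
    return _cut_k(dend, int(k))


def label_ecotype(
    member_profiles: pd.DataFrame,
    dominance: float = 0.50,
    co_dominance: float = 0.25,
    initials: Mapping[str, str] = DEFAULT_INITIALS,
) -> str:
    """Label a cluster by its dominant taxa.

    The cluster's mean profile yields a single-initial label when one taxon
    reaches the dominance threshold, a "+"-joined label for taxa above the
    co-dominance threshold (descending mean order), and ``"mixed"`` when no
    taxon stands out.  Taxa missing from ``initials`` use their first
    letter.
    """
    if len(member_profiles) == 0:
        raise ValueError("cluster is empty")
    mean = member_profiles.mean(axis=0).sort_values(ascending=False, kind="mergesort")

    def initial(taxon: str) -> str:
        return initials.get(taxon, taxon[:1].upper())

    top = mean.index[0]
    if mean.iloc[0] >= dominance:
        return initial(top)
    co = [t for t in mean.index if mean[t] >= co_dominance]
    if co:
        return "+".join(initial(t) for t in co)
    return "mixed"


def assign_ecotypes(
    profile: ContributionProfile,
    k: int | str = "auto",
    variant: str = "ward.D",
    dominance: float = 0.50,
    co_dominance: float = 0.25,
    initials: Mapping[str, str] = DEFAULT_INITIALS,
) -> tuple[pd.DataFrame, Dendrogram]:
    """Cluster a profile and label each cluster; one row per sample."""
    dist = manhattan_distance_matrix(profile)
    dend = ward_linkage(dist, variant=variant)
    ids = cut_clusters(dend, k=k, dist=dist)
    D = profile.D
    labels = {
        cid: label_ecotype(
            D.iloc[np.flatnonzero(ids == cid)],
            dominance=dominance,
            co_dominance=co_dominance,
            initials=initials,
        )
        for cid in np.unique(ids)
    }
    out = pd.DataFrame(
        {
            "sample_id": list(D.index),
            "cluster_id": ids,
            "label": [labels[c] for c in ids],
        }
    )
    return out, dend


def to_newick(dend: Dendrogram) -> str:
    """Render the dendrogram as a Newick string.

    Branch lengths are height differences between a node's merge height and
    its child's (leaves sit at height 0); negative differences from ward.D
    inversions are clamped to 0.
    """
    n = dend.n_leaves
    heights = {i: 0.0 for i in range(n)}

    def node_height(i: int) -> float:
        return heights[i]

    def render(i: int) -> str:
        if i < n:
            return dend.labels[i]
        row = dend.merges[i - n]
        left, right = int(row[0]), int(row[1])
        h = float(row[2])
        heights[i] = h
        parts = []
        for child in (left, right):
            child_str = render(child)
            bl = max(h - node_height(child), 0.0)
            parts.append(f"{child_str}:{bl:.6g}")
        return "(" + ",".join(parts) + ")"

    root = 2 * n - 2
    return render(root) + ";"
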