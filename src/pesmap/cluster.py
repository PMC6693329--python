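"""Hierarchical clustering and 2-D embedding of minima libraries.

Given a pairwise similarity matrix over local minima (distance-matrix or
cosine metric), two agglomerative linkage schemes are offered:

* WPGMA — at each step the two nearest groups P, Q merge, and the distance of
  the merged group to any other group R is the plain average
  (d_{P,R} + d_{Q,R})/2.  Implemented directly so the nearest-pair tie rule
  is fixed (lowest lexicographic cluster-id pair), making runs deterministic.
* Ward — the pair whose merge minimally increases total within-cluster
  variance, via the Lance–Williams recurrence (scipy).  The similarity
  indices used here are not exactly Euclidean, which Ward formally assumes;
  the linkage is applied to the raw matrix regardless, trading geometric
  rigour for the variance-based grouping behaviour.

A classical-MDS-initialised, stress-majorised 2-D embedding (`mds2d`) is
provided for visual inspection of how minima partition the surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from sklearn.manifold import MDS as _SKMDS

from .bh import MinimaLibrary
from .geom import (
    CompositionError,
    Geometry,
    cosine_distance,
    dm_similarity,
    mass_weighted_vector,
)

__all__ = [
    "PairwiseDistances",
    "Linkage",
    "Embedding2D",
    "pairwise",
    "wpgma",
    "ward",
    "cut_groups",
    "mds2d",
    "to_newick",
    "merge_table",
]


@dataclass(frozen=True)
class PairwiseDistances:
    """Symmetric zero-diagonal matrix of pairwise similarity indices."""

    labels: tuple[str, ...]
    M: np.ndarray
    metric: Literal["dm", "cosine"] = "dm"

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        m = len(self.labels)
        if M.shape != (m, m):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(M, M.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(M) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(M < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def m(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class Linkage:
    """Ordered agglomerative merge list.

    Each merge is (member_a, member_b, merge_distance, new_group_id); leaves
    are 0..m−1 and merged groups take ids m, m+1, …  ``sizes`` holds the leaf
    count of each merged group, so the scipy linkage format can be emitted.
    """

    merges: tuple[tuple[int, int, float, int], ...]
    sizes: tuple[int, ...]
    method: Literal["wpgma", "ward"]
    n_leaves: int

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a linkage over m leaves has m−1 merges")
        if any(h < -1e-12 for *_, h, _ in [(a, b, h, g) for a, b, h, g in self.merges]):
            raise ValueError("merge distances must be non-negative")

    def to_scipy(self) -> np.ndarray:
        Z = np.zeros((len(self.merges), 4))
        for row, (a, b, h, _gid) in enumerate(self.merges):
            Z[row] = [a, b, max(h, 0.0), self.sizes[row]]
        return Z

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h, _ in self.merges])


@dataclass(frozen=True)
class Embedding2D:
    labels: tuple[str, ...]
    coords: np.ndarray  # (m, 2)
    stress: float

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.labels), 2) or not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite (m, 2)")
        if self.stress < 0:
            raise ValueError("stress is non-negative")
        object.__setattr__(self, "coords", coords)


# ---------------------------------------------------------------------------
# Pairwise matrices


def pairwise(
    lib: MinimaLibrary | Sequence[Geometry],
    metric: Literal["dm", "cosine"] = "dm",
    mapping: Literal["identity", "element"] = "identity",
    sorted_vectors: bool = False,
    labels: Sequence[str] | None = None,
) -> PairwiseDistances:
    """All-pairs similarity matrix over a minima library (or geometry list).

    ``mapping`` applies to the distance-matrix metric; ``sorted_vectors``
    selects the relabelling-invariant convention for the cosine metric.
    """
    if isinstance(lib, MinimaLibrary):
        geoms = [r.geometry for r in lib.records]
        default_labels = [r.label or r.geometry.label or f"min{i}" for i, r in enumerate(lib.records)]
    else:
        geoms = list(lib)
        default_labels = [g.label or f"g{i}" for i, g in enumerate(geoms)]
    labels = list(labels) if labels is not None else default_labels
    if len(labels) != len(geoms):
        raise ValueError("label count must match geometry count")
    comp0 = sorted(geoms[0].elements)
    for g in geoms[1:]:
        if sorted(g.elements) != comp0:
            raise CompositionError("all records must share one element composition")
    m = len(geoms)
    M = np.zeros((m, m))
    if metric == "cosine":
        vecs = [mass_weighted_vector(g, sorted=sorted_vectors) for g in geoms]
    for i in range(m - 1):
        for j in range(i + 1, m):
            if metric == "dm":
                M[i, j] = M[j, i] = dm_similarity(geoms[i], geoms[j], mapping=mapping)
            elif metric == "cosine":
                M[i, j] = M[j, i] = cosine_distance(vecs[i], vecs[j])
            else:
                raise ValueError(f"unknown metric {metric!r}")
    return PairwiseDistances(tuple(labels), M, metric=metric)


# ---------------------------------------------------------------------------
# Linkage


def wpgma(pd_: PairwiseDistances) -> Linkage:
    """WPGMA agglomerative clustering with a deterministic tie rule.

    The globally nearest active pair merges at its current distance; ties go
    to the lowest (id_a, id_b) lexicographic pair.  New distances are plain
    averages of the two members' distances.
    """
    m = pd_.m
    if m < 2:
        raise ValueError("clustering needs at least two items")
    dist: dict[tuple[int, int], float] = {}
    for i in range(m - 1):
        for j in range(i + 1, m):
            dist[(i, j)] = pd_.M[i, j]
    active = list(range(m))
    sizes = {i: 1 for i in range(m)}
    merges: list[tuple[int, int, float, int]] = []
    out_sizes: list[int] = []
    next_id = m
    while len(active) > 1:
        best_pair = min(
            ((a, b) for idx, a in enumerate(active) for b in active[idx + 1 :]),
            key=lambda ab: (dist[ab], ab),
        )
        a, b = best_pair
        h = dist[(a, b)]
        new = next_id
        next_id += 1
        active.remove(a)
        active.remove(b)
        for r in active:
            d_ar = dist.pop(tuple(sorted((a, r))))
            d_br = dist.pop(tuple(sorted((b, r))))
            dist[(r, new) if r < new else (new, r)] = 0.5 * (d_ar + d_br)
        dist.pop((a, b))
        active.append(new)
        sizes[new] = sizes[a] + sizes[b]
        merges.append((a, b, h, new))
        out_sizes.append(sizes[new])
    return Linkage(tuple(merges), tuple(out_sizes), method="wpgma", n_leaves=m)


def ward(pd_: PairwiseDistances) -> Linkage:
    """Ward minimum-variance linkage via the Lance–Williams recurrence."""
    m = pd_.m
    if m < 2:
        raise ValueError("clustering needs at least two items")
    iu = np.triu_indices(m, k=1)
    Z = _hier.linkage(pd_.M[iu], method="ward")
    merges = []
    sizes = []
    for row in range(Z.shape[0]):
        a, b = int(min(Z[row, 0], Z[row, 1])), int(max(Z[row, 0], Z[row, 1]))
        merges.append((a, b, float(Z[row, 2]), m + row))
        sizes.append(int(Z[row, 3]))
    return Linkage(tuple(merges), tuple(sizes), method="ward", n_leaves=m)


def cut_groups(
    linkage: Linkage, k: int | None = None, height: float | None = None
) -> np.ndarray:
    """Flat group assignment by cluster count or by cutting height.

    Returns one integer group id per leaf, consecutive from 0.
    """
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    if k is not None:
        if not 1 <= k <= linkage.n_leaves:
            raise ValueError(f"k must lie in [1, {linkage.n_leaves}]")
        raw = _hier.fcluster(linkage.to_scipy(), t=k, criterion="maxclust")
    else:
        raw = _hier.fcluster(linkage.to_scipy(), t=height, criterion="distance")
    # renumber by first appearance for stable, order-independent ids
    remap: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, gid in enumerate(raw):
        out[i] = remap.setdefault(int(gid), len(remap))
    return out


# ---------------------------------------------------------------------------
# Multidimensional scaling


def _classical_mds_init(M: np.ndarray) -> np.ndarray:
    m = M.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (M**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:2]
    L = np.sqrt(np.clip(w[idx], 0.0, None))
    return V[:, idx] * L


def embedding_stress(coords: np.ndarray, M: np.ndarray) -> float:
    """Raw squared-error stress Σ_{i<j} (‖x_i − x_j‖ − M_ij)²."""
    diff = coords[:, None, :] - coords[None, :, :]
    D = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(M.shape[0], k=1)
    return float(np.sum((D[iu] - M[iu]) ** 2))


def mds2d(pd_: PairwiseDistances, seed: int = 0) -> Embedding2D:
    """Metric MDS to 2-D: classical (eigendecomposition) initialisation
    refined by iterative stress majorisation (SMACOF).

    The reported stress is recomputed from the returned coordinates, so it is
    self-consistent by construction.
    """
    if pd_.m < 3:
        raise ValueError("2-D embedding needs at least three items")
    init = _classical_mds_init(pd_.M)
    mds = _SKMDS(
        n_components=2,
        metric="precomputed",
        metric_mds=True,
        n_init=1,
        init="classical_mds",
        random_state=int(seed),
        normalized_stress=False,
    )
    coords = mds.fit_transform(pd_.M, init=init)
    return Embedding2D(pd_.labels, coords, embedding_stress(coords, pd_.M))


# ---------------------------------------------------------------------------
# Export


def to_newick(linkage: Linkage, labels: Sequence[str] | None = None) -> str:
    """Newick serialisation with branch lengths from merge heights.

    A node's branch length is its parent's merge height minus its own height
    (leaves sit at height 0); rare non-monotone linkages are clamped at 0.
    """
    labels = list(labels) if labels is not None else [f"L{i}" for i in range(linkage.n_leaves)]
    if len(labels) != linkage.n_leaves:
        raise ValueError("label count must match leaf count")
    height = {i: 0.0 for i in range(linkage.n_leaves)}
    node: dict[int, str] = {i: labels[i] for i in range(linkage.n_leaves)}
    for a, b, h, gid in linkage.merges:
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        node[gid] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[gid] = h
    root = linkage.merges[-1][3]
    return node[root] + ";"


def merge_table(linkage: Linkage) -> pd.DataFrame:
    """Flat merge list as a table (member_a, member_b, distance, new_group_id)."""
    return pd.DataFrame(
        [(a, b, h, g) for a, b, h, g in linkage.merges],
        columns=["member_a", "member_b", "distance", "new_group_id"],
    )


def save_embedding(e: Embedding2D, path: str | Path) -> None:
    pd.DataFrame(
        {"label": e.labels, "x": e.coords[:, 0], "y": e.coords[:, 1]}
    ).to_csv(path, sep="\t", index=False)
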