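"""Shared test helpers: random geometries, rigid motions, brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.transform import Rotation

from pesmap.geom import Geometry, distance_matrix


def random_geometry(
    n: int, seed: int, elements: list[str] | None = None, spread: float = 3.0,
    min_separation: float = 0.4,
) -> Geometry:
    """Random non-degenerate geometry: no two atoms closer than min_separation."""
    rng = np.random.default_rng(seed)
    elements = elements or ["X"] * n
    coords = np.empty((n, 3))
    placed = 0
    while placed < n:
        trial = rng.uniform(0.0, spread, 3)
        if placed == 0 or np.all(
            np.linalg.norm(coords[:placed] - trial, axis=1) >= min_separation
        ):
            coords[placed] = trial
            placed += 1
    return Geometry(elements, coords)


def random_rigid_motion(g: Geometry, seed: int) -> Geometry:
    """Apply a random rotation plus translation."""
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-10.0, 10.0, 3)
    return g.with_coords(g.coords @ R.T + t)


def dm_sum_under_permutation(a: Geometry, b: Geometry, perm) -> float:
    """Σ_{i<j} |D_A,ij − D_B,perm(i)perm(j)| for an explicit atom mapping."""
    DA, DB = distance_matrix(a).D, distance_matrix(b).D
    perm = np.asarray(perm)
    DBp = DB[np.ix_(perm, perm)]
    iu = np.triu_indices(a.n_atoms, k=1)
    return float(np.abs(DA[iu] - DBp[iu]).sum())


def exhaustive_best_mapping(a: Geometry, b: Geometry) -> tuple[float, tuple[int, ...]]:
    """Brute-force optimum of the distance-matrix index over all
    element-preserving permutations (feasible only for small n)."""
    groups: dict[str, list[int]] = {}
    for idx, e in enumerate(b.elements):
        groups.setdefault(e, []).append(idx)
    slots: dict[str, list[int]] = {}
    for idx, e in enumerate(a.elements):
        slots.setdefault(e, []).append(idx)
    best = (np.inf, None)
    element_orders = {e: list(itertools.permutations(groups[e])) for e in groups}
    keys = sorted(groups)
    for combo in itertools.product(*(element_orders[e] for e in keys)):
        perm = np.empty(a.n_atoms, dtype=int)
        for e, order in zip(keys, combo):
            for slot, bi in zip(slots[e], order):
                perm[slot] = bi
        val = dm_sum_under_permutation(a, b, perm)
        if val < best[0]:
            best = (val, tuple(perm))
    return best


def literal_wpgma_recursion(M: np.ndarray):
    """Independent WPGMA oracle: explicit matrix recursion of the averaging
    rule, merging the minimum entry (lowest lexicographic tie), shrinking the
    matrix one row/column per step.  Returns merges as (id_a, id_b, height)
    with new clusters numbered m, m+1, ...
    """
    M = M.astype(float).copy()
    m = M.shape[0]
    ids = list(range(m))
    merges = []
    next_id = m
    while len(ids) > 1:
        k = len(ids)
        best_val, best_pos, best_pos_ids = np.inf, None, None
        for i in range(k - 1):
            for j in range(i + 1, k):
                val = M[i, j]
                pos_ids = tuple(sorted((ids[i], ids[j])))
                if val < best_val or (val == best_val and pos_ids < best_pos_ids):
                    best_val, best_pos, best_pos_ids = val, (i, j), pos_ids
        i, j = best_pos
        merges.append((min(ids[i], ids[j]), max(ids[i], ids[j]), best_val))
        new_row = 0.5 * (M[i, :] + M[j, :])
        keep = [t for t in range(k) if t not in (i, j)]
        M2 = np.zeros((k - 1, k - 1))
        M2[: k - 2, : k - 2] = M[np.ix_(keep, keep)]
        M2[-1, : k - 2] = new_row[keep]
        M2[: k - 2, -1] = new_row[keep]
        ids = [ids[t] for t in keep] + [next_id]
        next_id += 1
        M = M2
    return merges
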