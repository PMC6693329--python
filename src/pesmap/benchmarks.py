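"""Self-contained benchmark studies on toy potentials.

These encode the package's scaled-down study conditions for validating the
search-augmentation machinery end to end on the Lennard-Jones 13-atom
cluster, a system whose global minimum (the icosahedron, −44.3268 ε) is
reliably identifiable by an independent multi-start oracle:

* basin-hopping at kT = 0.8 ε for 500 steps from a seeded random start;
* uniqueness thresholds ΔE ≥ 1e-5 ε OR distance-matrix similarity ≥ 10 σ
  (element-constrained atom mapping);
* post-run interpolation over at most 50 candidate pairs more distant than
  15 σ, at the midpoint λ = 0.5, registered with the same thresholds.

All randomness is derived from a single base seed, kept below 2³¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bh import BHConfig, run_bh
from .fixtures import make_lj_cluster
from .interp import augment_library
from .potentials import LennardJones, local_minimize

__all__ = ["LJ13_CONDITIONS", "lj13_config", "lj13_oracle_gm", "lj13_augmentation_study", "RunResult"]

#: Frozen study conditions for the LJ13 augmentation benchmark.
LJ13_CONDITIONS = dict(
    n_atoms=13,
    thermal_energy=0.8,
    n_steps=500,
    min_interatomic=0.5,
    interaction_radius=6.0,
    energy_tol=1e-5,
    similarity_tol=10.0,
    interp_min_distance=15.0,
    interp_max_pairs=50,
    lam=0.5,
)


def _sub_seed(base_seed: int, k: int) -> int:
    return int((base_seed * 1_000 + k) % (2**31 - 1))


def lj13_config(seed: int) -> BHConfig:
    c = LJ13_CONDITIONS
    return BHConfig(
        thermal_energy=c["thermal_energy"],
        n_steps=c["n_steps"],
        min_interatomic=c["min_interatomic"],
        interaction_radius=c["interaction_radius"],
        energy_tol=c["energy_tol"],
        similarity_tol=c["similarity_tol"],
        mapping="element",
        seed=seed,
    )


def lj13_oracle_gm(base_seed: int, n_starts: int = 500) -> float:
    """Multi-start oracle: best energy over seeded random-start minimisations."""
    model = LennardJones()
    best = np.inf
    for k in range(n_starts):
        g = make_lj_cluster(LJ13_CONDITIONS["n_atoms"], seed=_sub_seed(base_seed, 100_000 + k))
        _, e, conv = local_minimize(model, g)
        if conv:
            best = min(best, e)
    return float(best)


@dataclass(frozen=True)
class RunResult:
    seed: int
    n_bh: int
    e_low_bh: float
    n_new_interp: int
    e_low_final: float


def lj13_augmentation_study(
    base_seed: int, n_runs: int = 8
) -> tuple[list[RunResult], float]:
    """Parallel seeded BH runs plus post-run interpolation on LJ13.

    Returns per-run results and the multi-start oracle's global-minimum
    energy, against which run success is judged.
    """
    model = LennardJones()
    results = []
    for k in range(n_runs):
        seed = _sub_seed(base_seed, k)
        cfg = lj13_config(seed)
        start = make_lj_cluster(LJ13_CONDITIONS["n_atoms"], seed=seed)
        lib, _ = run_bh(model, start, cfg)
        n_bh, e_bh = len(lib), lib.e_low
        n_new, _ = augment_library(
            lib, model, cfg,
            min_distance=LJ13_CONDITIONS["interp_min_distance"],
            max_pairs=LJ13_CONDITIONS["interp_max_pairs"],
            lam=LJ13_CONDITIONS["lam"],
            seed=seed,
        )
        results.append(RunResult(seed, n_bh, e_bh, n_new, lib.e_low))
    oracle = lj13_oracle_gm(base_seed)
    return results, oracle
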