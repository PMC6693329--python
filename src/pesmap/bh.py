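"""Basin-hopping global optimisation with similarity-based uniqueness tracking.

The loop alternates random geometric perturbation, pre-optimisation screening,
local minimisation, and a two-criterion acceptance test:

* *definite replacement*: a minimum below the lowest energy found so far
  (E_low) is always adopted;
* *conditional acceptance*: otherwise the step is accepted with Metropolis
  probability min(1, exp(−ΔE/thermal_energy)) relative to the current
  structure, so the thermal energy sets the statistically accessible window.

Every converged minimum encountered — accepted or not — is offered to the
minima library, which deduplicates with joint energy/geometry thresholds: two
records are the *same* minimum only when both their energy difference is
below ``energy_tol`` and their distance-matrix similarity is below
``similarity_tol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geom import Geometry, center_of_mass, dm_similarity
from .potentials import PotentialModel, Topology, local_minimize

__all__ = [
    "BHConfig",
    "MinimumRecord",
    "MinimaLibrary",
    "ScreenResult",
    "ConfigurationError",
    "StartupError",
    "perturb",
    "screen",
    "accept_step",
    "register_unique",
    "run_bh",
]


class ConfigurationError(ValueError):
    """The move set has no movable degrees of freedom."""


class StartupError(RuntimeError):
    """The initial structure fails screening after minimisation."""


@dataclass(frozen=True)
class BHConfig:
    """Basin-hopping run parameters.

    ``thermal_energy`` is the k_B·T of the Metropolis acceptance window, in
    the potential model's energy units.  Step ranges follow the convention of
    uniform draws in ±step: ``dihedral_step`` and ``rigid_rot_step`` in
    degrees, ``translation_step`` in Å.  ``energy_tol``/``similarity_tol``
    are the uniqueness thresholds (model units / Å).
    """

    thermal_energy: float = 1.0
    n_steps: int = 1000
    dihedral_step: float = 5.0
    rigid_rot_step: float = 5.0
    translation_step: float = 0.5
    min_interatomic: float = 0.8
    interaction_radius: float = 15.0
    energy_tol: float = 1e-5
    similarity_tol: float = 50.0
    mapping: Literal["identity", "element"] = "identity"
    minimize_tol: float = 1e-6
    minimize_max_iter: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thermal_energy <= 0:
            raise ValueError("thermal_energy must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        for name in ("dihedral_step", "rigid_rot_step", "translation_step"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class MinimumRecord:
    """A locally minimised geometry with its energy and provenance."""

    geometry: Geometry
    energy: float
    step_found: int = 0
    provenance: Literal["bh", "interpolation"] = "bh"
    label: str = ""


@dataclass
class MinimaLibrary:
    """Deduplicated registry of local minima; tracks the running global minimum."""

    records: list[MinimumRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def e_low(self) -> float:
        if not self.records:
            return np.inf
        return min(r.energy for r in self.records)

    @property
    def best(self) -> MinimumRecord:
        return min(self.records, key=lambda r: r.energy)

    def energies(self) -> np.ndarray:
        return np.array([r.energy for r in self.records])


@dataclass(frozen=True)
class ScreenResult:
    accepted: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.accepted


# ---------------------------------------------------------------------------
# Moves


def _rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    return Rotation.from_rotvec(axis / np.linalg.norm(axis) * angle_rad).as_matrix()


def perturb(
    g: Geometry,
    cfg: BHConfig,
    rng: np.random.Generator,
    topology: Topology | None = None,
) -> Geometry:
    """Random perturbation: dihedral twists plus per-moiety rigid moves.

    Each rotatable dihedral is twisted by a uniform draw in ±dihedral_step;
    each designated moiety is rigidly rotated about its geometric centre by
    uniform draws in ±rigid_rot_step per body axis and translated by uniform
    draws in ±translation_step per Cartesian direction.  Bonded distances are
    preserved by construction.
    """
    topology = topology or Topology(moieties=tuple((i,) for i in range(g.n_atoms)))
    if not topology.dihedrals and not topology.moieties:
        raise ConfigurationError("no movable degrees of freedom in topology")
    coords = g.coords.copy()
    for (i, j, k, l), rot_set in zip(topology.dihedrals, topology.rotating_sets):
        angle = np.deg2rad(rng.uniform(-cfg.dihedral_step, cfg.dihedral_step))
        if angle == 0.0 or not rot_set:
            continue
        axis = coords[k] - coords[j]
        R = _rotation(axis, angle)
        idx = list(rot_set)
        coords[idx] = (coords[idx] - coords[k]) @ R.T + coords[k]
    for moiety in topology.moieties:
        idx = list(moiety)
        if len(idx) > 1 and cfg.rigid_rot_step > 0:
            angles = np.deg2rad(rng.uniform(-cfg.rigid_rot_step, cfg.rigid_rot_step, 3))
            R = Rotation.from_euler("xyz", angles).as_matrix()
            centre = coords[idx].mean(axis=0)
            coords[idx] = (coords[idx] - centre) @ R.T + centre
        shift = rng.uniform(-cfg.translation_step, cfg.translation_step, 3)
        coords[idx] = coords[idx] + shift
    return g.with_coords(coords, energy=None)


def screen(
    g: Geometry, cfg: BHConfig, topology: Topology | None = None
) -> ScreenResult:
    """Pre-optimisation screening: clash and dissociation guards.

    Rejects when any non-bonded pair is closer than ``min_interatomic`` or
    any atom lies further than ``interaction_radius`` from the centre of
    mass; the reason names the violated rule and the offending atoms.
    """
    n = g.n_atoms
    bonded = set()
    if topology is not None:
        bonded = {tuple(sorted(b)) for b in topology.bonds}
    diff = g.coords[:, None, :] - g.coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    for i in range(n - 1):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            if dist[i, j] < cfg.min_interatomic:
                return ScreenResult(
                    False, f"clash: atoms {i},{j} at {dist[i, j]:.3f} Å "
                           f"< min_interatomic {cfg.min_interatomic}"
                )
    r_com = np.linalg.norm(g.coords - center_of_mass(g), axis=1)
    far = int(np.argmax(r_com))
    if r_com[far] > cfg.interaction_radius:
        return ScreenResult(
            False, f"dissociation: atom {far} at {r_com[far]:.3f} Å "
                   f"> interaction_radius {cfg.interaction_radius}"
        )
    return ScreenResult(True)


# ---------------------------------------------------------------------------
# Acceptance and registration


def accept_step(
    e_new: float,
    e_current: float,
    e_low: float,
    cfg: BHConfig,
    rng: np.random.Generator,
) -> Literal["replace_gm", "accept", "reject"]:
    """Dual acceptance criterion.

    A new global minimum is adopted unconditionally; otherwise the move is
    accepted with Metropolis probability exp(−(e_new − e_current)/kT),
    downhill moves always.
    """
    if not (np.isfinite(e_new) and np.isfinite(e_current)):
        raise ValueError("energies must be finite")
    if e_new < e_low:
        return "replace_gm"
    if e_new <= e_current:
        return "accept"
    p = np.exp(-(e_new - e_current) / cfg.thermal_energy)
    return "accept" if rng.random() < p else "reject"


def register_unique(lib: MinimaLibrary, rec: MinimumRecord, cfg: BHConfig) -> bool:
    """Add ``rec`` unless it duplicates a stored minimum.

    Duplicate means *jointly* energy-near (|ΔE| < energy_tol) and
    geometry-near (distance-matrix similarity < similarity_tol); a record
    distinct in either sense is registered.
    """
    for stored in lib.records:
        if abs(stored.energy - rec.energy) >= cfg.energy_tol:
            continue
        d = dm_similarity(rec.geometry, stored.geometry, mapping=cfg.mapping)
        if d < cfg.similarity_tol:
            return False
    lib.records.append(rec)
    return True


# ---------------------------------------------------------------------------
# Main loop


def run_bh(
    model: PotentialModel,
    start: Geometry,
    cfg: BHConfig,
    library: MinimaLibrary | None = None,
    constraint: Callable[[Geometry], bool] | None = None,
) -> tuple[MinimaLibrary, pd.DataFrame]:
    """Run the basin-hopping loop; returns the minima library and a step log.

    ``constraint``, when given, is evaluated on each minimised candidate; a
    failing candidate is rejected and not registered (used for
    similarity-constrained sampling between two minima).  The run is fully
    reproducible under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    topology = model.topology(start)
    lib = library if library is not None else MinimaLibrary()

    current, e_current, conv = local_minimize(
        model, start, tol=cfg.minimize_tol, max_iter=cfg.minimize_max_iter
    )
    ok = screen(current, cfg, topology)
    if not ok:
        raise StartupError(f"initial structure fails screening: {ok.reason}")
    register_unique(
        lib, MinimumRecord(current, e_current, step_found=0, provenance="bh"), cfg
    )

    log: list[dict] = []
    for step in range(1, cfg.n_steps + 1):
        cand = perturb(current, cfg, rng, topology)
        sc = screen(cand, cfg, topology)
        if not sc:
            log.append(dict(step=step, energy=np.nan, decision="screened",
                            reason=sc.reason, added=False, e_low=lib.e_low))
            continue
        gmin, e_new, conv = local_minimize(
            model, cand, tol=cfg.minimize_tol, max_iter=cfg.minimize_max_iter
        )
        if not conv:
            log.append(dict(step=step, energy=e_new, decision="reject",
                            reason="minimisation did not converge", added=False,
                            e_low=lib.e_low))
            continue
        if constraint is not None and not constraint(gmin):
            log.append(dict(step=step, energy=e_new, decision="reject",
                            reason="outside similarity constraint", added=False,
                            e_low=lib.e_low))
            continue
        decision = accept_step(e_new, e_current, lib.e_low, cfg, rng)
        added = register_unique(
            lib, MinimumRecord(gmin, e_new, step_found=step, provenance="bh"), cfg
        )
        if decision in ("replace_gm", "accept"):
            current, e_current = gmin, e_new
        log.append(dict(step=step, energy=e_new, decision=decision, reason=None,
                        added=added, e_low=lib.e_low))
    return lib, pd.DataFrame(
        log, columns=["step", "energy", "decision", "reason", "added", "e_low"]
    )
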