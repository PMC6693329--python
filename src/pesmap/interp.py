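"""Generation of intermediate geometries between known minima.

Two implicit interpolation routes are provided:

* **Artificial force field** — the target distance matrix
  r̄ = λ·D_A + (1−λ)·D_B is imposed by minimising
  V = χ·Σ (D_C,ij − r̄_ij)²/r̄_ij from a superposition-aligned Cartesian
  blend of the endpoints (stage 1), after which the realised structure is
  re-minimised under the real potential model (stage 2).
* **Constrained Monte Carlo** — a basin-hopping walk whose acceptance
  additionally rejects any minimised structure farther than a threshold from
  either endpoint, confining sampling to an ellipsoid-like region between
  the two minima.

Interpolants found this way augment a basin-hopping minima library (with the
same uniqueness thresholds) and provide guess structures for transition-state
searches that want a reactant/guess/product triple.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .bh import BHConfig, MinimaLibrary, MinimumRecord, register_unique, run_bh
from .geom import Geometry, distance_matrix, dm_similarity, write_xyz
from .potentials import PotentialModel, artificial_ff_build, local_minimize

__all__ = [
    "InterpolationJob",
    "InterpolationFailure",
    "ConstraintError",
    "ExportError",
    "Eq1Report",
    "select_pairs",
    "interpolate_ff",
    "mc_constrained_sample",
    "verify_ratio",
    "ts_guess_export",
    "augment_library",
    "align_to",
]


class InterpolationFailure(RuntimeError):
    """Stage-1 force-field minimisation did not converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConstraintError(ValueError):
    """Constraint radii too small to admit any structure between the minima."""


class ExportError(ValueError):
    """Structures are not consistently atom-ordered for export."""


@dataclass(frozen=True)
class InterpolationJob:
    """A pair of minima to interpolate between, with factor λ and method."""

    record_a: MinimumRecord
    record_b: MinimumRecord
    lam: float = 0.5
    method: Literal["ff", "mc"] = "ff"
    radius_a: float = np.inf
    radius_b: float = np.inf

    def __post_init__(self) -> None:
        if not 0.0 < self.lam < 1.0:
            raise ValueError("interior interpolation needs 0 < λ < 1")


def align_to(g: Geometry, ref: Geometry) -> Geometry:
    """Optimal-rotation (Kabsch) superposition of ``g`` onto ``ref``."""
    c_g = g.coords - g.coords.mean(axis=0)
    c_r = ref.coords - ref.coords.mean(axis=0)
    rot, _ = Rotation.align_vectors(c_r, c_g)
    return g.with_coords(c_g @ rot.as_matrix().T + ref.coords.mean(axis=0))


def select_pairs(
    lib: MinimaLibrary,
    min_distance: float,
    max_pairs: int,
    seed: int = 0,
    mapping: Literal["identity", "element"] = "identity",
) -> list[tuple[int, int]]:
    """Interpolation-candidate pairs: record indices with distance-matrix
    similarity above ``min_distance``, uniformly subsampled to ``max_pairs``.
    """
    eligible = []
    for i in range(len(lib) - 1):
        for j in range(i + 1, len(lib)):
            d = dm_similarity(lib.records[i].geometry, lib.records[j].geometry, mapping=mapping)
            if d > min_distance:
                eligible.append((i, j))
    if len(eligible) <= max_pairs:
        return eligible
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=max_pairs, replace=False)
    return [eligible[k] for k in sorted(idx)]


def interpolate_ff(
    job: InterpolationJob,
    model: PotentialModel,
    chi: float = 1.0,
    stage1_tol: float = 1e-6,
    max_iter: int = 2000,
) -> tuple[MinimumRecord, dict]:
    """Two-stage force-field interpolation between two minima.

    Stage 1 minimises the artificial distance-targeting force field built
    from the endpoints at factor λ, starting from the Kabsch-aligned
    Cartesian blend λ·A + (1−λ)·B.  Stage 2 re-minimises the realised
    structure under the real model.  Returns the interpolated record
    (provenance "interpolation") and a diagnostics dict with the stage-1
    residual (max |D_C − r̄|), stage-1 energy, and final energy.
    """
    a, b = job.record_a.geometry, job.record_b.geometry
    if sorted(a.elements) != sorted(b.elements):
        raise ValueError("endpoints differ in composition")
    ff = artificial_ff_build(distance_matrix(a), distance_matrix(b), job.lam, chi=chi)
    b_aligned = align_to(b, a)
    start_coords = job.lam * a.coords + (1.0 - job.lam) * b_aligned.coords
    # a degenerate blend (near-coincident atoms) would make the FF singular
    d = distance_matrix(a.with_coords(start_coords)).D
    if np.any(d[np.triu_indices(a.n_atoms, k=1)] < 1e-3):
        rng = np.random.default_rng(0)
        start_coords = start_coords + 1e-2 * rng.standard_normal(start_coords.shape)
    start = a.with_coords(start_coords, energy=None, label="interpolant start")

    stage1, v1, conv1 = local_minimize(ff, start, tol=stage1_tol, max_iter=max_iter)
    resid = float(np.max(np.abs(distance_matrix(stage1).D - ff.rbar)))
    diagnostics = {"stage1_energy": v1, "stage1_residual": resid, "stage1_converged": conv1}
    if not conv1:
        raise InterpolationFailure(
            f"artificial-force-field minimisation did not converge (V = {v1:.3g}, "
            f"max distance residual {resid:.3g} Å)", diagnostics,
        )
    final, e_final, conv2 = local_minimize(model, stage1, max_iter=max_iter)
    diagnostics.update({"final_energy": e_final, "stage2_converged": conv2})
    rec = MinimumRecord(final, e_final, step_found=0, provenance="interpolation")
    return rec, diagnostics


def stage1_interpolant(
    a: Geometry, b: Geometry, lam: float = 0.5, chi: float = 1.0, tol: float = 1e-6
) -> Geometry:
    """Convenience: just the stage-1 structure realising r̄ (no model re-minimisation)."""
    job = InterpolationJob(MinimumRecord(a, 0.0), MinimumRecord(b, 0.0), lam=lam)
    ff = artificial_ff_build(distance_matrix(a), distance_matrix(b), lam, chi=chi)
    b_aligned = align_to(b, a)
    start = a.with_coords(lam * a.coords + (1.0 - lam) * b_aligned.coords, energy=None)
    out, _, _ = local_minimize(ff, start, tol=tol)
    return out


def mc_constrained_sample(
    job: InterpolationJob,
    model: PotentialModel,
    bh_cfg: BHConfig,
    mapping: Literal["identity", "element"] = "identity",
) -> list[MinimumRecord]:
    """Similarity-constrained Monte Carlo sampling between two minima.

    Runs a basin-hopping walk from the midpoint interpolant whose acceptance
    rejects any minimised structure with d(·,A) > radius_a or
    d(·,B) > radius_b, then returns the registered records satisfying both
    constraints.  Radii below half the endpoint separation are infeasible.
    """
    a, b = job.record_a.geometry, job.record_b.geometry
    d_ab = dm_similarity(a, b, mapping=mapping)
    if job.radius_a < d_ab / 2 or job.radius_b < d_ab / 2:
        raise ConstraintError(
            f"radii ({job.radius_a}, {job.radius_b}) cannot both hold with "
            f"endpoint separation {d_ab:.3g}"
        )

    def within(g: Geometry) -> bool:
        return (
            dm_similarity(g, a, mapping=mapping) <= job.radius_a
            and dm_similarity(g, b, mapping=mapping) <= job.radius_b
        )

    if np.isinf(job.radius_a) and np.isinf(job.radius_b):
        start = a
        constraint = None
    else:
        rec, _ = interpolate_ff(job, model)
        start = rec.geometry
        constraint = within
    lib, _ = run_bh(model, start, bh_cfg, constraint=constraint)
    return [r for r in lib.records if constraint is None or within(r.geometry)]


@dataclass(frozen=True)
class Eq1Report:
    """Similarity ratios of an interpolant C between endpoints A and B.

    An ideal interpolant at factor λ (with r̄ = λ·D_A + (1−λ)·D_B) satisfies
    d(A,C) = (1−λ)·d(A,B) and d(B,C) = λ·d(A,B); the deviations quantify how
    far the realised structure falls from that proportionality.
    """

    d_ab: float
    d_ac: float
    d_bc: float
    lam: float
    deviation_a: float  # |(1−λ)·d(A,B) − d(A,C)|
    deviation_b: float  # |λ·d(A,B) − d(B,C)|


def verify_ratio(
    a: Geometry,
    b: Geometry,
    c: Geometry,
    lam: float,
    metric: Literal["dm"] = "dm",
    mapping: Literal["identity", "element"] = "identity",
) -> Eq1Report:
    """Measure how well interpolant ``c`` divides the A–B separation at λ."""
    d_ab = dm_similarity(a, b, mapping=mapping)
    d_ac = dm_similarity(a, c, mapping=mapping)
    d_bc = dm_similarity(b, c, mapping=mapping)
    return Eq1Report(
        d_ab=d_ab, d_ac=d_ac, d_bc=d_bc, lam=lam,
        deviation_a=abs((1.0 - lam) * d_ab - d_ac),
        deviation_b=abs(lam * d_ab - d_bc),
    )


def ts_guess_export(a: Geometry, c: Geometry, b: Geometry, path: str | Path) -> None:
    """Write a reactant/guess/product triple as a 3-frame XYZ file.

    Atom ordering must be identical across the three frames (a transition-
    state search pairs atoms by position in the file).
    """
    if not (a.elements == c.elements == b.elements):
        raise ExportError("atom ordering/elements differ between frames")
    write_xyz(
        [
            replace(a, label=(a.label or "reactant")),
            replace(c, label=(c.label or "ts guess")),
            replace(b, label=(b.label or "product")),
        ],
        path,
    )


def augment_library(
    lib: MinimaLibrary,
    model: PotentialModel,
    cfg: BHConfig,
    min_distance: float,
    max_pairs: int,
    lam: float = 0.5,
    chi: float = 1.0,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Post-run interpolation sweep: select distant pairs, interpolate each,
    and register the results against the existing library with the same
    uniqueness thresholds.  Returns (number of new minima, report table).
    """
    pairs = select_pairs(lib, min_distance, max_pairs, seed=seed, mapping=cfg.mapping)
    rows = []
    n_new = 0
    for i, j in pairs:
        job = InterpolationJob(lib.records[i], lib.records[j], lam=lam)
        try:
            rec, diag = interpolate_ff(job, model, chi=chi)
        except InterpolationFailure as exc:
            rows.append(dict(pair=(i, j), lam=lam, stage1_residual=np.nan,
                             final_energy=np.nan, outcome="failed",
                             detail=str(exc)))
            continue
        added = register_unique(lib, rec, cfg)
        n_new += int(added)
        rows.append(dict(pair=(i, j), lam=lam,
                         stage1_residual=diag["stage1_residual"],
                         final_energy=rec.energy,
                         outcome="new" if added else "duplicate", detail=""))
    report = pd.DataFrame(
        rows, columns=["pair", "lam", "stage1_residual", "final_energy", "outcome", "detail"]
    )
    return n_new, report
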