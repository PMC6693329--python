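"""Model potential-energy functions and local minimisation.

Three concrete models are provided:

* :class:`LennardJones` — pairwise 4ε[(σ/r)¹² − (σ/r)⁶] clusters in reduced
  units, the classic global-optimisation benchmark substrate.
* :class:`TorsionChain` — a molecular-mechanics-style chain whose
  conformational energy lives in its dihedral angles (cosine series) plus a
  soft-sphere repulsion between distant atoms.  Harmonic bond and angle
  restraints keep Cartesian minimisation well-posed; they vanish at the ideal
  chain geometry, so the conformational landscape is set by the torsion terms.
* :class:`ArtificialFF` — the interpolation force field
  V = χ·Σ_{i<j} (D_C,ij − r̄_ij)²/r̄_ij, a collection of harmonic terms whose
  force constants are inversely proportional to the target distances r̄_ij.
  Minimising it drives a structure's distance matrix onto the blend
  r̄ = λ·D_A + (1−λ)·D_B of two endpoint matrices.

All models expose analytic gradients and are minimised with a quasi-Newton
(L-BFGS-B) optimiser via :func:`local_minimize`.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .geom import DistanceMatrixRep, Geometry, distance_matrix

__all__ = [
    "PotentialModel",
    "Topology",
    "LennardJones",
    "TorsionParams",
    "TorsionChain",
    "ArtificialFF",
    "artificial_ff_build",
    "local_minimize",
    "CoincidentAtomsError",
    "DivergenceError",
    "dihedral_angle",
]


class CoincidentAtomsError(FloatingPointError):
    """Two atoms (near-)coincide; the pair energy would overflow."""


class DivergenceError(RuntimeError):
    """Minimisation hit a non-finite energy; carries the last good iterate."""

    def __init__(self, message: str, last_geometry: Geometry | None = None):
        super().__init__(message)
        self.last_geometry = last_geometry


@dataclass(frozen=True)
class Topology:
    """Movable degrees of freedom of a model system.

    ``dihedrals`` are (i, j, k, l) quadruples with ``rotating_sets[t]`` the
    atom indices displaced when dihedral ``t`` turns about bond (j, k).
    ``moieties`` are atom groups eligible for rigid-body rotation/translation
    moves.  ``bonds`` are used by the screening step to exempt bonded pairs
    from the minimum-distance rule.
    """

    bonds: tuple[tuple[int, int], ...] = ()
    dihedrals: tuple[tuple[int, int, int, int], ...] = ()
    rotating_sets: tuple[tuple[int, ...], ...] = ()
    moieties: tuple[tuple[int, ...], ...] = ()


class PotentialModel(ABC):
    """Contract for a model potential: energy, analytic gradient, topology."""

    name: str = "model"
    units: str = "model units"

    @abstractmethod
    def energy(self, g: Geometry) -> float: ...

    @abstractmethod
    def gradient(self, g: Geometry) -> np.ndarray:
        """Per-atom (n, 3) gradient dE/dr in energy-unit/Å."""

    def topology(self, g: Geometry) -> Topology:
        """Default: every atom is its own rigid moiety, no dihedrals."""
        return Topology(moieties=tuple((i,) for i in range(g.n_atoms)))


# ---------------------------------------------------------------------------
# Lennard-Jones clusters


class LennardJones(PotentialModel):
    """Pairwise-additive Lennard-Jones potential, reduced units by default."""

    name = "lj"

    def __init__(self, epsilon: float = 1.0, sigma: float = 1.0):
        self.epsilon = float(epsilon)
        self.sigma = float(sigma)
        self.units = "epsilon"

    def _pair_terms(self, g: Geometry):
        diff = g.coords[:, None, :] - g.coords[None, :, :]
        r = np.linalg.norm(diff, axis=-1)
        iu = np.triu_indices(g.n_atoms, k=1)
        rij = r[iu]
        if np.any(rij < 1e-8 * self.sigma):
            raise CoincidentAtomsError("coincident atoms in Lennard-Jones evaluation")
        return diff, r, iu, rij

    def energy(self, g: Geometry) -> float:
        if g.n_atoms < 2:
            raise ValueError("Lennard-Jones needs at least two atoms")
        _, _, _, rij = self._pair_terms(g)
        s6 = (self.sigma / rij) ** 6
        return float(4.0 * self.epsilon * np.sum(s6 * s6 - s6))

    def gradient(self, g: Geometry) -> np.ndarray:
        diff, r, iu, _ = self._pair_terms(g)
        np.fill_diagonal(r, np.inf)
        s6 = (self.sigma / r) ** 6
        # dV/dr / r for each pair
        dvdr_over_r = 24.0 * self.epsilon * (s6 - 2.0 * s6 * s6) / (r * r)
        return np.einsum("ij,ijk->ik", dvdr_over_r, diff)


def lj_energy(g: Geometry, epsilon: float = 1.0, sigma: float = 1.0) -> float:
    return LennardJones(epsilon, sigma).energy(g)


# ---------------------------------------------------------------------------
# Torsional chain


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (radians) for four points."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(m @ n2, n1 @ n2))


def _dihedral_gradient(p0, p1, p2, p3):
    """Analytic dφ/dp for the four dihedral atoms (Blondel–Karplus form)."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    g0 = nb2 / (n1 @ n1) * n1
    g3 = -nb2 / (n2 @ n2) * n2
    c1 = (b1 @ b2) / (nb2 * nb2)
    c3 = (b3 @ b2) / (nb2 * nb2)
    g1 = -(1.0 + c1) * g0 + c3 * g3
    g2 = c1 * g0 - (1.0 + c3) * g3
    return g0, g1, g2, g3


def _angle_and_gradient(p0, p1, p2):
    u, v = p0 - p1, p2 - p1
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    c = float(np.clip(uh @ vh, -1.0, 1.0))
    theta = np.arccos(c)
    s = np.sqrt(max(1.0 - c * c, 1e-12))
    g0 = (c * uh - vh) / (nu * s)
    g2 = (c * vh - uh) / (nv * s)
    return theta, g0, -(g0 + g2), g2


@dataclass(frozen=True)
class TorsionParams:
    """Parameters of the toy torsional chain.

    ``terms`` is a cosine series Σ_m k_m·(1 + cos(n_m·φ − φ0_m)) applied to
    every dihedral.  Bonds are unit length and angles tetrahedral by default;
    the harmonic restraints on them are stiff relative to the torsion
    amplitudes so the conformational search effectively happens in dihedral
    space, mirroring searches that move dihedrals while keeping bonded
    distances fixed.
    """

    terms: tuple[tuple[float, int, float], ...] = ((1.0, 3, 0.0),)  # (k, n, phi0)
    k_bond: float = 100.0
    r0: float = 1.0
    k_angle: float = 50.0
    theta0: float = float(np.deg2rad(109.4712206))
    k_rep: float = 1.0
    r_rep: float = 1.0  # soft-sphere radius for pairs > 3 bonds apart


class TorsionChain(PotentialModel):
    """Linear chain (atom i bonded to i+1) with torsional conformational energy."""

    name = "torsion_chain"
    units = "model units"

    def __init__(self, n_atoms: int, params: TorsionParams | None = None):
        if n_atoms < 4:
            raise ValueError("a torsional chain needs at least 4 atoms (one dihedral)")
        self.n_atoms = int(n_atoms)
        self.params = params or TorsionParams()

    def _check(self, g: Geometry) -> None:
        if g.n_atoms != self.n_atoms:
            raise ValueError(f"model is for {self.n_atoms}-atom chains, got {g.n_atoms}")

    def _nonbonded_pairs(self):
        n = self.n_atoms
        return [(i, j) for i in range(n) for j in range(i + 4, n)]

    def torsion_energy(self, g: Geometry) -> float:
        self._check(g)
        p = self.params
        e = 0.0
        for i in range(self.n_atoms - 3):
            phi = dihedral_angle(*g.coords[i : i + 4])
            for k, n, phi0 in p.terms:
                e += k * (1.0 + np.cos(n * phi - phi0))
        return float(e)

    def repulsion_energy(self, g: Geometry) -> float:
        self._check(g)
        p = self.params
        e = 0.0
        for i, j in self._nonbonded_pairs():
            r = np.linalg.norm(g.coords[i] - g.coords[j])
            if r < 1e-8:
                raise CoincidentAtomsError("coincident nonbonded atoms in torsion chain")
            e += p.k_rep * (p.r_rep / r) ** 12
        return float(e)

    def restraint_energy(self, g: Geometry) -> float:
        self._check(g)
        p = self.params
        e = 0.0
        for i in range(self.n_atoms - 1):
            r = np.linalg.norm(g.coords[i + 1] - g.coords[i])
            e += p.k_bond * (r - p.r0) ** 2
        for i in range(self.n_atoms - 2):
            theta, *_ = _angle_and_gradient(*g.coords[i : i + 3])
            e += p.k_angle * (theta - p.theta0) ** 2
        return float(e)

    def energy(self, g: Geometry) -> float:
        return self.torsion_energy(g) + self.repulsion_energy(g) + self.restraint_energy(g)

    def gradient(self, g: Geometry) -> np.ndarray:
        self._check(g)
        p = self.params
        grad = np.zeros_like(g.coords)
        for i in range(self.n_atoms - 1):  # bonds
            d = g.coords[i + 1] - g.coords[i]
            r = np.linalg.norm(d)
            f = 2.0 * p.k_bond * (r - p.r0) * d / r
            grad[i + 1] += f
            grad[i] -= f
        for i in range(self.n_atoms - 2):  # angles
            theta, ga, gb, gc = _angle_and_gradient(*g.coords[i : i + 3])
            pref = 2.0 * p.k_angle * (theta - p.theta0)
            grad[i] += pref * ga
            grad[i + 1] += pref * gb
            grad[i + 2] += pref * gc
        for i in range(self.n_atoms - 3):  # torsions
            phi = dihedral_angle(*g.coords[i : i + 4])
            dEdphi = sum(-k * n * np.sin(n * phi - phi0) for k, n, phi0 in p.terms)
            for off, gph in zip(range(4), _dihedral_gradient(*g.coords[i : i + 4])):
                grad[i + off] += dEdphi * gph
        for i, j in self._nonbonded_pairs():  # soft-sphere repulsion
            d = g.coords[i] - g.coords[j]
            r = np.linalg.norm(d)
            f = -12.0 * p.k_rep * (p.r_rep / r) ** 12 / (r * r) * d
            grad[i] += f
            grad[j] -= f
        return grad

    def topology(self, g: Geometry) -> Topology:
        n = self.n_atoms
        bonds = tuple((i, i + 1) for i in range(n - 1))
        dihedrals = tuple((i, i + 1, i + 2, i + 3) for i in range(n - 3))
        rotating = tuple(tuple(range(i + 3, n)) for i in range(n - 3))
        return Topology(bonds=bonds, dihedrals=dihedrals, rotating_sets=rotating,
                        moieties=((tuple(range(n)),)))

    def dihedrals(self, g: Geometry) -> np.ndarray:
        self._check(g)
        return np.array(
            [dihedral_angle(*g.coords[i : i + 4]) for i in range(self.n_atoms - 3)]
        )


# ---------------------------------------------------------------------------
# Artificial interpolation force field


class ArtificialFF(PotentialModel):
    """Harmonic distance-targeting force field V = χ·Σ_{i<j} (D_ij − r̄_ij)²/r̄_ij."""

    name = "artificial_ff"
    units = "chi units"

    def __init__(self, rbar: np.ndarray, chi: float = 1.0):
        rbar = np.asarray(rbar, dtype=float)
        if rbar.ndim != 2 or rbar.shape[0] != rbar.shape[1]:
            raise ValueError("rbar must be square")
        if not np.allclose(rbar, rbar.T):
            raise ValueError("rbar must be symmetric")
        iu = np.triu_indices(rbar.shape[0], k=1)
        if np.any(rbar[iu] <= 0):
            raise ValueError("ill-posed target: off-diagonal r̄ entries must be positive")
        if chi <= 0:
            raise ValueError("chi must be positive")
        self.rbar = rbar
        self.chi = float(chi)

    @property
    def n_atoms(self) -> int:
        return self.rbar.shape[0]

    def _check(self, g: Geometry) -> None:
        if g.n_atoms != self.n_atoms:
            raise ValueError(f"force field is {self.n_atoms}-atom, geometry has {g.n_atoms}")

    def energy(self, g: Geometry) -> float:
        self._check(g)
        D = distance_matrix(g).D
        iu = np.triu_indices(self.n_atoms, k=1)
        dev = D[iu] - self.rbar[iu]
        return float(self.chi * np.sum(dev * dev / self.rbar[iu]))

    def gradient(self, g: Geometry) -> np.ndarray:
        self._check(g)
        diff = g.coords[:, None, :] - g.coords[None, :, :]
        D = np.linalg.norm(diff, axis=-1)
        if np.any(D[np.triu_indices(self.n_atoms, k=1)] < 1e-10):
            raise CoincidentAtomsError("coincident atoms in artificial force field")
        np.fill_diagonal(D, 1.0)  # placeholder; diagonal coefficient zeroed below
        coef = 2.0 * self.chi * (D - self.rbar) / (self.rbar + np.eye(self.n_atoms)) / D
        np.fill_diagonal(coef, 0.0)
        return np.einsum("ij,ijk->ik", coef, diff)


def artificial_ff_build(
    da: DistanceMatrixRep, db: DistanceMatrixRep, lam: float, chi: float = 1.0
) -> ArtificialFF:
    """Blend two endpoint distance matrices: r̄ = λ·D_A + (1−λ)·D_B."""
    if da.n_atoms != db.n_atoms:
        raise ValueError("endpoint distance matrices differ in size")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"interpolation factor must lie in [0, 1], got {lam}")
    return ArtificialFF(lam * da.D + (1.0 - lam) * db.D, chi=chi)


def artificial_ff_energy(ff: ArtificialFF, g: Geometry) -> float:
    return ff.energy(g)


# ---------------------------------------------------------------------------
# Local minimisation


def local_minimize(
    model: PotentialModel,
    g: Geometry,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> tuple[Geometry, float, bool]:
    """Quasi-Newton (L-BFGS-B) local minimisation with analytic gradients.

    Returns ``(geometry, energy, converged)``; ``converged`` means the
    gradient max-norm at the result is at most ``tol``.  A non-finite energy
    encountered during the search raises :class:`DivergenceError` carrying
    the last finite iterate.
    """
    shape = g.coords.shape
    last_good: list = [g.coords.copy(), None]

    def objective(x: np.ndarray):
        gg = g.with_coords(x.reshape(shape))
        try:
            e = model.energy(gg)
            grad = model.gradient(gg)
        except CoincidentAtomsError as exc:
            raise DivergenceError(
                f"non-finite energy during minimisation: {exc}",
                last_geometry=g.with_coords(last_good[0], energy=last_good[1]),
            ) from exc
        if not np.isfinite(e) or not np.all(np.isfinite(grad)):
            raise DivergenceError(
                "non-finite energy during minimisation",
                last_geometry=g.with_coords(last_good[0], energy=last_good[1]),
            )
        last_good[0], last_good[1] = x.reshape(shape).copy(), float(e)
        return float(e), grad.ravel()

    # L-BFGS-B sometimes halts on function-reduction round-off before the
    # gradient criterion is met; restarting from the iterate (fresh curvature
    # memory) reliably finishes the descent.
    x = g.coords.ravel()
    for _attempt in range(3):
        res = _scipy_minimize(
            objective,
            x,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": tol, "ftol": 0.0},
        )
        x = res.x
        if np.max(np.abs(res.jac)) <= tol:
            break
    coords = x.reshape(shape)
    out = g.with_coords(coords)
    energy = float(model.energy(out))
    converged = bool(np.max(np.abs(model.gradient(out))) <= tol)
    out = out.with_coords(coords, energy=energy)
    return out, energy, converged
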