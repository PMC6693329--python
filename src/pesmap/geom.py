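"""Molecular geometries, XYZ I/O, and conformational similarity functions.

A molecular configuration is represented in one of two reduced forms for
similarity comparison:

* the *Euclidean distance matrix*: the symmetric matrix of all interatomic
  distances.  Translation- and rotation-invariant, but not permutation
  invariant, and its memory footprint grows quadratically with atom count.
* the *mass-weighted distance vector*: per atom, mass times the distance to
  the molecular centre of mass.  Linear in atom count; optionally sorted to
  gain permutational invariance for low-symmetry species.

On top of these, two similarity indices are defined: the elementwise
absolute-difference sum over distance matrices (units: Å) and the angular
cosine distance between mass-weighted vectors (dimensionless, in [0, 1]).
Both are non-negative, symmetric, and zero on identical structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ATOMIC_MASSES",
    "Geometry",
    "DistanceMatrixRep",
    "MassWeightedVector",
    "XYZParseError",
    "CompositionError",
    "DimensionError",
    "ZeroNormError",
    "read_xyz",
    "write_xyz",
    "distance_matrix",
    "dm_similarity",
    "mass_weighted_vector",
    "cosine_distance",
    "element_constrained_mapping",
    "center_of_mass",
]

# Most-abundant-isotope masses (u), 4-decimal precision.  "X" is a unit-mass
# model particle used by toy potentials (Lennard-Jones reduced units).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.0078,
    "He": 4.0026,
    "Li": 7.0160,
    "Be": 9.0122,
    "B": 11.0093,
    "C": 12.0000,
    "N": 14.0031,
    "O": 15.9949,
    "F": 18.9984,
    "Ne": 19.9924,
    "Na": 22.9898,
    "Mg": 23.9850,
    "Al": 26.9815,
    "Si": 27.9769,
    "P": 30.9738,
    "S": 31.9721,
    "Cl": 34.9689,
    "Ar": 39.9624,
    "K": 38.9637,
    "Ca": 39.9626,
    "Fe": 55.9349,
    "Ni": 57.9353,
    "Cu": 62.9296,
    "Zn": 63.9291,
    "Br": 78.9183,
    "I": 126.9045,
    "X": 1.0000,
}


class XYZParseError(ValueError):
    """Malformed XYZ content; message carries the offending line number."""


class CompositionError(ValueError):
    """Two structures do not share the same element composition."""


class DimensionError(ValueError):
    """Two representations have incompatible sizes."""


class ZeroNormError(ValueError):
    """A zero-norm vector has no direction; cosine distance is undefined."""


@dataclass
class Geometry:
    """A labelled molecular geometry: element symbols + Cartesian coordinates (Å).

    Masses are resolved from the built-in most-abundant-isotope table unless
    given explicitly.  ``energy`` is an optional scalar in whatever units the
    producing potential model declares.
    """

    elements: list[str]
    coords: np.ndarray
    masses: np.ndarray | None = None
    label: str = ""
    energy: float | None = None

    def __post_init__(self) -> None:
        self.elements = list(self.elements)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coords) or len(self.elements) < 1:
            raise ValueError(
                f"need matching non-empty elements/coords, got "
                f"{len(self.elements)} symbols and {len(self.coords)} coordinates"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.masses is None:
            try:
                self.masses = np.array([ATOMIC_MASSES[e] for e in self.elements])
            except KeyError as exc:
                raise KeyError(f"unknown element symbol {exc.args[0]!r}") from exc
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (len(self.elements),):
                raise ValueError("masses must match atom count")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def with_coords(self, coords: np.ndarray, **kw) -> "Geometry":
        """Copy of this geometry with new coordinates (and optional field overrides)."""
        g = replace(self, coords=np.array(coords, dtype=float), **kw)
        return g

    def translated(self, shift: Sequence[float]) -> "Geometry":
        return self.with_coords(self.coords + np.asarray(shift, dtype=float))

    def rotated(self, R: np.ndarray, about: Sequence[float] | None = None) -> "Geometry":
        """Rigid rotation by matrix ``R`` about ``about`` (default: centre of mass)."""
        pivot = center_of_mass(self) if about is None else np.asarray(about, float)
        return self.with_coords((self.coords - pivot) @ np.asarray(R).T + pivot)

    def same_composition(self, other: "Geometry") -> bool:
        return sorted(self.elements) == sorted(other.elements)


@dataclass(frozen=True)
class DistanceMatrixRep:
    """Symmetric interatomic distance matrix with a zero diagonal (Å)."""

    n_atoms: int
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.shape != (self.n_atoms, self.n_atoms):
            raise DimensionError(f"expected {self.n_atoms}x{self.n_atoms} matrix")
        if not np.allclose(D, D.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(D) != 0.0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any(D < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "D", D)


@dataclass(frozen=True)
class MassWeightedVector:
    """Per-atom mass × distance-to-centre-of-mass values (u·Å)."""

    values: np.ndarray
    sorted_flag: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("values must be a non-empty 1-D vector")
        if np.any(v < 0):
            raise ValueError("mass-weighted distances are non-negative")
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------------------
# XYZ I/O


def _parse_energy_token(comment: str) -> float | None:
    for token in comment.split():
        if token.startswith("E=") and len(token) > 2:
            try:
                return float(token[2:])
            except ValueError:
                return None
    return None


def read_xyz(path: str | Path) -> list[Geometry]:
    """Read a (possibly multi-frame) XYZ file.

    The comment line is stored as ``label``; a token ``E=<float>`` in the
    comment is parsed into ``energy``.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Geometry] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(f"line {i + 1}: expected an atom count, got {lines[i]!r}")
        if n < 1:
            raise XYZParseError(f"line {i + 1}: invalid atom count {n}")
        if i + 2 + n > len(lines):
            raise XYZParseError(f"line {i + 1}: frame declares {n} atoms but file ends early")
        comment = lines[i + 1]
        elements: list[str] = []
        coords = np.empty((n, 3))
        for k in range(n):
            ln = i + 2 + k
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(f"line {ln + 1}: expected 'symbol x y z'")
            sym = parts[0]
            if sym not in ATOMIC_MASSES:
                raise XYZParseError(f"line {ln + 1}: unknown element symbol {sym!r}")
            try:
                coords[k] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise XYZParseError(f"line {ln + 1}: non-numeric coordinate")
            elements.append(sym)
        frames.append(
            Geometry(elements, coords, label=comment, energy=_parse_energy_token(comment))
        )
        i += 2 + n
    if not frames:
        raise XYZParseError("line 1: empty XYZ file")
    return frames


def write_xyz(geometries: Geometry | Iterable[Geometry], path: str | Path) -> None:
    """Write one or more geometries as a multi-frame XYZ file (8-decimal coords)."""
    if isinstance(geometries, Geometry):
        geometries = [geometries]
    out = []
    for g in geometries:
        comment = g.label
        if g.energy is not None and "E=" not in comment:
            comment = (comment + " " if comment else "") + f"E={g.energy:.10g}"
        out.append(f"{g.n_atoms}")
        out.append(comment)
        for sym, (x, y, z) in zip(g.elements, g.coords):
            out.append(f"{sym:<3s} {x: .8f} {y: .8f} {z: .8f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Representations


def center_of_mass(g: Geometry) -> np.ndarray:
    return g.masses @ g.coords / g.masses.sum()


def distance_matrix(g: Geometry) -> DistanceMatrixRep:
    """Euclidean distance matrix of all interatomic distances (Å)."""
    return DistanceMatrixRep(g.n_atoms, squareform(pdist(g.coords)))


def mass_weighted_vector(g: Geometry, sorted: bool = False) -> MassWeightedVector:
    """Per-atom mass-weighted distance to the centre of mass.

    With ``sorted=True`` the entries are put in ascending order, which makes
    the representation invariant to atom relabelling (the convention for
    comparing structures whose atom ordering is not tracked).
    """
    r = np.linalg.norm(g.coords - center_of_mass(g), axis=1)
    v = g.masses * r
    if sorted:
        v = np.sort(v)
    return MassWeightedVector(v, sorted_flag=sorted)


# ---------------------------------------------------------------------------
# Similarity functions


def _dm_sum(DA: np.ndarray, DB: np.ndarray) -> float:
    iu = np.triu_indices(DA.shape[0], k=1)
    return float(np.abs(DA[iu] - DB[iu]).sum())


def dm_similarity(
    a: DistanceMatrixRep | Geometry,
    b: DistanceMatrixRep | Geometry,
    mapping: Literal["identity", "element"] = "identity",
) -> float:
    """Distance-matrix similarity index: Σ_{i<j} |D_A,ij − D_B,ij| (Å).

    ``mapping="element"`` first relabels ``b``'s atoms with
    :func:`element_constrained_mapping` to approximately minimise the index;
    the result is never worse than the identity labelling.  Geometries are
    accepted directly for convenience (``mapping="element"`` requires them,
    since the relabelling uses masses and coordinates).
    """
    if mapping == "element":
        if not (isinstance(a, Geometry) and isinstance(b, Geometry)):
            raise TypeError("mapping='element' requires Geometry inputs")
        perm = element_constrained_mapping(a, b)
        DB = distance_matrix(b).D[np.ix_(perm, perm)]
        DA = distance_matrix(a).D
        return min(_dm_sum(DA, DB), _dm_sum(DA, distance_matrix(b).D))
    DA = distance_matrix(a).D if isinstance(a, Geometry) else a.D
    DB = distance_matrix(b).D if isinstance(b, Geometry) else b.D
    if DA.shape != DB.shape:
        raise DimensionError(
            f"cannot compare structures of different size ({DA.shape[0]} vs {DB.shape[0]} atoms)"
        )
    return _dm_sum(DA, DB)


def cosine_distance(ra: MassWeightedVector, rb: MassWeightedVector) -> float:
    """Angular cosine distance arccos(s)/π between two mass-weighted vectors.

    ``s`` is the normalised dot product; for the non-negative vectors produced
    by :func:`mass_weighted_vector` the result lies in [0, 0.5], and it is 0
    exactly when the vectors are parallel.
    """
    va, vb = ra.values, rb.values
    if va.shape != vb.shape:
        raise DimensionError(f"vector lengths differ ({va.size} vs {vb.size})")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ZeroNormError("zero-norm mass-weighted vector has undefined direction")
    s = float(np.clip(va @ vb / (na * nb), -1.0, 1.0))
    return float(np.arccos(s) / np.pi)


def _refine_permutation(DA: np.ndarray, DB: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Greedy pairwise-swap (2-opt) descent on the Σ|ΔD| objective."""
    perm = perm.copy()
    n = len(perm)
    best = _dm_sum(DA, DB[np.ix_(perm, perm)])
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                trial = perm.copy()
                trial[i], trial[j] = trial[j], trial[i]
                val = _dm_sum(DA, DB[np.ix_(trial, trial)])
                if val < best - 1e-12:
                    best, perm, improved = val, trial, True
    return perm


def element_constrained_mapping(a: Geometry, b: Geometry) -> np.ndarray:
    """Permutation of ``b``'s atom indices that approximately minimises the
    distance-matrix similarity index to ``a``, mapping like elements only.

    Exact minimisation over atom labellings is combinatorial; this heuristic
    solves one linear assignment per element with mass-weighted
    centre-of-mass distances as cost, then refines with pairwise-swap descent
    on the actual index.  ``perm[i]`` is the atom of ``b`` assigned to atom
    ``i`` of ``a``.
    """
    if sorted(a.elements) != sorted(b.elements):
        raise CompositionError("structures differ in element composition")
    Ra = mass_weighted_vector(a).values
    Rb = mass_weighted_vector(b).values
    n = a.n_atoms
    perm = np.empty(n, dtype=int)
    for elem in set(a.elements):
        ia = np.flatnonzero([e == elem for e in a.elements])
        ib = np.flatnonzero([e == elem for e in b.elements])
        cost = np.abs(Ra[ia, None] - Rb[None, ib])
        rows, cols = linear_sum_assignment(cost)
        perm[ia[rows]] = ib[cols]
    DA, DB = distance_matrix(a).D, distance_matrix(b).D
    # element-preserving swaps only, so restrict descent per element block
    perm = _refine_elementwise(DA, DB, perm, a.elements)
    return perm


def _refine_elementwise(
    DA: np.ndarray, DB: np.ndarray, perm: np.ndarray, elements: Sequence[str]
) -> np.ndarray:
    perm = perm.copy()
    n = len(perm)
    best = _dm_sum(DA, DB[np.ix_(perm, perm)])
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                if elements[i] != elements[j]:
                    continue
                trial = perm.copy()
                trial[i], trial[j] = trial[j], trial[i]
                val = _dm_sum(DA, DB[np.ix_(trial, trial)])
                if val < best - 1e-12:
                    best, perm, improved = val, trial, True
    return perm


def export_distance_matrix(rep: DistanceMatrixRep, labels: Sequence[str], path: str | Path) -> None:
    """Write a distance matrix as a whitespace-delimited table with a label header."""
    if len(labels) != rep.n_atoms:
        raise DimensionError("label count must match matrix size")
    lines = [" ".join(labels)]
    for row in rep.D:
        lines.append(" ".join(f"{x:.8f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")
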