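"""Ensemble ion-mobility analysis: Boltzmann populations, Mason-Schamp
mobility, projection-approximation collision cross sections, and
temperature-dependent Boltzmann-weighted CCS curves.

A conformer ensemble carries, per conformer, a relative Gibbs energy curve
ΔG_rel(T) — either analytic (ΔH − T·ΔS) or tabulated — and a collision cross
section Ω.  Relative populations follow N_i = exp(−ΔG_rel,i/RT) with the
reference (lowest-energy) conformer at N_0 = 1; Gibbs energies are molar
(kJ·mol⁻¹), so the gas constant R is used.  The ensemble CCS at temperature
T is the population-weighted average Ω_B(T) = Σ_i f_i(T)·Ω_i, which for an
ensemble whose extended conformers are entropy-favoured increases with
temperature (the structural origin of dynamic, field-dependent mobility).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import constants
from scipy.spatial.transform import Rotation

from .geom import Geometry

__all__ = [
    "R_GAS",
    "DEFAULT_VDW_RADII",
    "DEFAULT_PROBE_RADIUS",
    "Conformer",
    "ConformerEnsemble",
    "MobilityParams",
    "CCSResult",
    "ExtrapolationError",
    "NoCrossoverError",
    "populations",
    "crossover_temperature",
    "pa_ccs",
    "mason_schamp",
    "weighted_ccs_curve",
]

R_GAS = constants.R  # J·mol⁻¹·K⁻¹

# van der Waals radii (Å) for the projection approximation
DEFAULT_VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "X": 1.00,
}
# effective probe radius of an N₂ collision partner (Å)
DEFAULT_PROBE_RADIUS = 1.55


class ExtrapolationError(ValueError):
    """Requested temperature lies outside a conformer's tabulated ΔG range."""


class NoCrossoverError(ValueError):
    """Two conformers with equal entropy never exchange stability."""


@dataclass(frozen=True)
class Conformer:
    """One conformer: label, CCS Ω (Å²), and a ΔG_rel(T) description.

    Either (``dH`` kJ·mol⁻¹, ``dS`` J·mol⁻¹·K⁻¹) for analytic
    ΔG(T) = ΔH − T·ΔS/1000, or a table of (temperatures K, ΔG_rel kJ·mol⁻¹)
    interpolated linearly.
    """

    label: str
    omega: float
    dH: float | None = None
    dS: float | None = None
    dG_table: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("CCS must be positive")
        analytic = self.dH is not None and self.dS is not None
        if analytic == (self.dG_table is not None):
            raise ValueError("give either (dH, dS) or a dG_table, not both/neither")
        if self.dG_table is not None:
            T, dG = (np.asarray(a, dtype=float) for a in self.dG_table)
            if T.ndim != 1 or T.shape != dG.shape or np.any(np.diff(T) <= 0) or np.any(T <= 0):
                raise ValueError("dG_table needs increasing positive temperatures")
            object.__setattr__(self, "dG_table", (T, dG))

    def dG(self, T: float) -> float:
        """Relative Gibbs energy at T (kJ·mol⁻¹)."""
        if self.dG_table is None:
            return self.dH - T * self.dS / 1000.0
        Ts, dGs = self.dG_table
        if not Ts[0] <= T <= Ts[-1]:
            raise ExtrapolationError(
                f"{self.label}: T = {T} K outside tabulated range [{Ts[0]}, {Ts[-1]}] K"
            )
        return float(np.interp(T, Ts, dGs))


@dataclass
class ConformerEnsemble:
    """A set of conformers sharing a temperature grid (K)."""

    conformers: list[Conformer]
    temperatures: np.ndarray = field(
        default_factory=lambda: np.arange(300.0, 801.0, 10.0)
    )
    reference_temperature: float = 300.0

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("ensemble needs at least one conformer")
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if np.any(self.temperatures <= 0) or np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperature grid must be positive and increasing")
        ref = [c.dG(self.reference_temperature) for c in self.conformers]
        if not np.isclose(min(ref), 0.0, atol=1e-9):
            raise ValueError(
                "one conformer must sit at ΔG_rel = 0 at the reference temperature"
            )

    def omegas(self) -> np.ndarray:
        return np.array([c.omega for c in self.conformers])


def populations(ens: ConformerEnsemble, T: float) -> np.ndarray:
    """Normalised Boltzmann population fractions at temperature T.

    Relative populations are exp(−ΔG_rel·1000/RT) with the reference
    conformer at 1; the returned fractions sum to 1.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    dG = np.array([c.dG(T) for c in ens.conformers])
    # shifting by the minimum guards against overflow and cancels on normalisation
    rel = np.exp(-(dG - dG.min()) * 1000.0 / (R_GAS * T))
    return rel / rel.sum()


def crossover_temperature(c1: Conformer, c2: Conformer) -> float:
    """Temperature at which two analytic-ΔG conformers are equally populated.

    T_cross = ΔΔH/ΔΔS; requires ΔΔS ≠ 0 and a physically positive result.
    """
    if c1.dH is None or c2.dH is None:
        raise ValueError("crossover requires analytic (dH, dS) conformers")
    ddH = (c2.dH - c1.dH) * 1000.0  # J/mol
    ddS = c2.dS - c1.dS  # J/mol/K
    if ddS == 0.0:
        raise NoCrossoverError("equal entropies: the Gibbs curves never cross")
    T = ddH / ddS
    if T <= 0:
        raise NoCrossoverError(f"Gibbs curves cross only at unphysical T = {T:.1f} K")
    return T


@dataclass(frozen=True)
class CCSResult:
    omega: float  # Å²
    stderr: float  # Monte Carlo standard error of the orientation average
    n_orientations: int
    n_rays: int

    def __float__(self) -> float:
        return self.omega


def pa_ccs(
    g: Geometry,
    radii: dict[str, float] | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_orientations: int = 64,
    n_rays: int = 4096,
    seed: int = 0,
) -> CCSResult:
    """Projection-approximation collision cross section (Å²).

    The orientationally averaged projected area of the union of atom-centred
    disks of radius (van der Waals + probe), estimated by Monte Carlo: for
    each of ``n_orientations`` seeded random rotations, ``n_rays`` sample
    points are thrown uniformly over the projection's bounding box.  This is
    a hard-disk geometric estimate — it carries no long-range ion–neutral
    interaction physics and systematically undershoots trajectory-method CCS
    for large ions.
    """
    if n_orientations < 1 or n_rays < 1:
        raise ValueError("counts must be positive")
    table = radii if radii is not None else DEFAULT_VDW_RADII
    try:
        rad = np.array([table[e] for e in g.elements]) + probe_radius
    except KeyError as exc:
        raise KeyError(f"no radius for element {exc.args[0]!r}") from exc
    rng = np.random.default_rng(seed)
    areas = np.empty(n_orientations)
    for k in range(n_orientations):
        R = Rotation.random(rng=rng).as_matrix()
        xy = (g.coords @ R.T)[:, :2]
        lo = (xy - rad[:, None]).min(axis=0)
        hi = (xy + rad[:, None]).max(axis=0)
        box_area = np.prod(hi - lo)
        pts = rng.uniform(lo, hi, size=(n_rays, 2))
        d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1)
        hit = np.any(d2 <= rad[None, :] ** 2, axis=1)
        areas[k] = hit.mean() * box_area
    stderr = (
        float(areas.std(ddof=1) / np.sqrt(n_orientations))
        if n_orientations > 1
        else float("nan")
    )
    return CCSResult(float(areas.mean()), stderr, n_orientations, n_rays)


@dataclass(frozen=True)
class MobilityParams:
    """Inputs to the Mason-Schamp relation (SI conversions handled internally)."""

    m_ion: float  # amu
    m_gas: float  # amu
    z: int = 1
    temperature: float = 298.15  # K
    number_density: float | None = None  # m⁻³
    pressure: float | None = None  # Pa, used with temperature if N not given

    def __post_init__(self) -> None:
        if min(self.m_ion, self.m_gas, self.temperature) <= 0:
            raise ValueError("masses and temperature must be positive")
        if self.z < 1 or int(self.z) != self.z:
            raise ValueError("charge state must be a positive integer")
        if self.number_density is None and self.pressure is None:
            raise ValueError("give number_density or pressure")

    @property
    def N(self) -> float:
        if self.number_density is not None:
            return self.number_density
        return self.pressure / (constants.k * self.temperature)


def mason_schamp(p: MobilityParams, omega: float) -> float:
    """Low-field Mason-Schamp ion mobility K (m²·V⁻¹·s⁻¹).

    K = (3/16)·(z·e/N)·√(2π/(μ·k_B·T))·(1/Ω) with the reduced mass
    1/μ = 1/m_ion + 1/m_gas; Ω is given in Å² and converted to m².
    """
    if omega <= 0:
        raise ValueError("CCS must be positive")
    mu = (p.m_ion * p.m_gas) / (p.m_ion + p.m_gas) * constants.atomic_mass  # kg
    omega_m2 = omega * 1e-20
    return (
        (3.0 / 16.0)
        * (p.z * constants.e / p.N)
        * np.sqrt(2.0 * np.pi / (mu * constants.k * p.temperature))
        / omega_m2
    )


def weighted_ccs_curve(
    ens: ConformerEnsemble, temperatures: np.ndarray | None = None
) -> pd.DataFrame:
    """Boltzmann-weighted ensemble CCS over a temperature grid.

    Returns a table (T, ccs) with Ω_B(T) = Σ_i f_i(T)·Ω_i; the curve is
    bounded by the smallest and largest conformer CCS at every temperature.
    """
    Ts = np.asarray(temperatures, dtype=float) if temperatures is not None else ens.temperatures
    omegas = ens.omegas()
    ccs = np.array([float(populations(ens, T) @ omegas) for T in Ts])
    return pd.DataFrame({"T": Ts, "ccs": ccs})
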