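"""Seeded synthetic-data generators.

Every generator is a pure function of its parameters and a seed, so all
pipelines in the package can be exercised end-to-end without external data
or an electronic-structure engine: random Lennard-Jones clusters for
basin-hopping, torsional chains for dihedral searches, idealised
difluoroethene-like isomer sets for clustering, planted-carrier stick-spectrum
ensembles for the spectral pipeline, and analytic two-state conformer
ensembles for mobility analysis.
"""

from __future__ import annotations

import numpy as np

from .geom import Geometry
from .mobility import Conformer, ConformerEnsemble
from .potentials import TorsionChain, TorsionParams, Topology
from .spectra import GridSpectrum, LineSpectrum, SpectralRegion, broaden, concat_regions, scale_lines

__all__ = [
    "make_lj_cluster",
    "make_torsion_chain",
    "make_difluoroethene_like",
    "make_spectra_set",
    "make_two_state_ensemble",
]


def make_lj_cluster(
    n: int, seed: int = 0, box: float | None = None, min_separation: float = 0.7
) -> Geometry:
    """Random Lennard-Jones cluster: n unit-mass atoms uniform in a cubic box.

    Pairs closer than ``min_separation`` (σ units) are resampled.  The default
    box edge 1.3·n^(1/3) keeps the density near that of a condensed cluster.
    """
    if n < 2:
        raise ValueError("need at least two atoms")
    if box is None:
        box = 1.3 * n ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)
    coords = np.empty((n, 3))
    placed = 0
    while placed < n:
        trial = rng.uniform(0.0, box, 3)
        if placed == 0 or np.all(np.linalg.norm(coords[:placed] - trial, axis=1) >= min_separation):
            coords[placed] = trial
            placed += 1
    return Geometry(["X"] * n, coords, label=f"lj{n} seed={seed}")


def make_torsion_chain(
    n_atoms: int,
    torsion_params: TorsionParams | None = None,
    seed: int = 0,
    dihedrals_deg: np.ndarray | None = None,
) -> tuple[Geometry, TorsionChain]:
    """Chain with unit bonds, tetrahedral angles, and random (or given) dihedrals.

    Returns the geometry together with the :class:`TorsionChain` model that
    owns its topology (bonds i—i+1, one rotatable dihedral per consecutive
    atom quadruple).
    """
    if n_atoms < 4:
        raise ValueError("a chain needs at least 4 atoms")
    params = torsion_params or TorsionParams()
    rng = np.random.default_rng(seed)
    if dihedrals_deg is None:
        dihedrals_deg = rng.uniform(-180.0, 180.0, n_atoms - 3)
    dihedrals = np.deg2rad(np.asarray(dihedrals_deg, float))
    if dihedrals.shape != (n_atoms - 3,):
        raise ValueError(f"need {n_atoms - 3} dihedral angles")
    theta = params.theta0
    coords = _chain_coords(n_atoms, params.r0, theta, dihedrals)
    g = Geometry(["C"] * n_atoms, coords, label=f"torsion chain n={n_atoms} seed={seed}")
    return g, TorsionChain(n_atoms, params)


def _chain_coords(n: int, r0: float, theta: float, dihedrals: np.ndarray) -> np.ndarray:
    """Build Cartesian chain coordinates from internal coordinates (NeRF-style)."""
    coords = np.zeros((n, 3))
    coords[1] = [r0, 0.0, 0.0]
    if n > 2:
        coords[2] = coords[1] + r0 * np.array([-np.cos(theta), np.sin(theta), 0.0])
    for i in range(3, n):
        phi = dihedrals[i - 3]
        a, b, c = coords[i - 3], coords[i - 2], coords[i - 1]
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - a
        nrm = np.cross(ab, bc)
        nrm /= np.linalg.norm(nrm)
        m = np.cross(nrm, bc)
        d_local = np.array(
            [
                -r0 * np.cos(theta),
                r0 * np.sin(theta) * np.cos(phi),
                -r0 * np.sin(theta) * np.sin(phi),  # sign fixes the dihedral convention
            ]
        )
        coords[i] = c + d_local[0] * bc + d_local[1] * m + d_local[2] * nrm
    return coords


def make_difluoroethene_like(which: str = "all") -> list[Geometry]:
    """Idealised cis-, trans-, and 1,1-difluoroethene geometries.

    Built from textbook sp² geometry (C=C 1.33 Å, C–F 1.35 Å, C–H 1.09 Å,
    120° angles), not quantum-chemically optimised: suitable for qualitative
    similarity/clustering behaviour (the 1,2-isomers resemble each other more
    than either resembles the 1,1-isomer), not for reproducing published
    distance values.
    """
    rcc, rcf, rch = 1.33, 1.35, 1.09
    c, s = np.cos(np.pi / 3), np.sin(np.pi / 3)
    c1 = np.array([0.0, 0.0, 0.0])
    c2 = np.array([rcc, 0.0, 0.0])

    def sub(center: np.ndarray, other: np.ndarray, r: float, side: float) -> np.ndarray:
        # substituent at 120° from the C=C axis, in-plane, side = ±1
        axis = (center - other) / np.linalg.norm(center - other)
        perp = np.array([-axis[1], axis[0], 0.0])
        return center + r * (c * axis + side * s * perp)

    def build(name: str, subs: list[tuple[np.ndarray, np.ndarray, float, str]]) -> Geometry:
        elements = ["C", "C"]
        coords = [c1, c2]
        for center, other, side, elem in subs:
            r = rcf if elem == "F" else rch
            elements.append(elem)
            coords.append(sub(center, other, r, side))
        return Geometry(elements, np.array(coords), label=name)

    cis = build("cis-1,2-difluoroethene",
                [(c1, c2, 1.0, "F"), (c2, c1, -1.0, "F"),
                 (c1, c2, -1.0, "H"), (c2, c1, 1.0, "H")])
    trans = build("trans-1,2-difluoroethene",
                  [(c1, c2, 1.0, "F"), (c2, c1, 1.0, "F"),
                   (c1, c2, -1.0, "H"), (c2, c1, -1.0, "H")])
    geminal = build("1,1-difluoroethene",
                    [(c1, c2, 1.0, "F"), (c1, c2, -1.0, "F"),
                     (c2, c1, 1.0, "H"), (c2, c1, -1.0, "H")])
    table = {"cis": cis, "trans": trans, "1,1": geminal}
    if which == "all":
        return [cis, trans, geminal]
    return [table[which]]


def make_spectra_set(
    n_isomers: int = 10,
    lines_per_isomer: int = 15,
    regions: list[SpectralRegion] | None = None,
    noise: float = 0.05,
    seed: int = 0,
    fwhm: float = 15.0,
) -> tuple[list[LineSpectrum], GridSpectrum, int]:
    """Random stick spectra with one planted experimental carrier.

    One isomer is designated the carrier; the "experiment" is its fully
    processed spectrum (scale → broaden → concatenate) with multiplicative
    intensity noise of relative level ``noise``.  Returns
    ``(spectra, experiment, carrier_index)``.
    """
    if n_isomers < 1 or lines_per_isomer < 1:
        raise ValueError("counts must be at least 1")
    regions = regions or [
        SpectralRegion(1000.0, 1900.0, scale_factor=0.9679),
        SpectralRegion(3200.0, 3800.0, scale_factor=0.95),
    ]
    rng = np.random.default_rng(seed)
    spectra = []
    for i in range(n_isomers):
        lines = []
        for region in regions:
            k = max(1, lines_per_isomer // len(regions))
            # draw unscaled frequencies that stay inside the window after scaling
            lo, hi = region.lo / region.scale_factor, region.hi
            freqs = rng.uniform(lo, hi, k)
            intens = rng.uniform(0.05, 1.0, k)
            lines.extend(zip(freqs, intens))
        spectra.append(LineSpectrum(tuple(lines), label=f"isomer {i}"))
    carrier = int(rng.integers(n_isomers))
    processed = concat_regions(
        [broaden(scale_lines(spectra[carrier], regions), fwhm=fwhm, region=r) for r in regions]
    )
    noisy = np.clip(
        processed.intensities
        * (1.0 + noise * rng.standard_normal(processed.intensities.size)),
        0.0,
        None,
    )
    # re-normalise per region, as a digitised experiment would be
    for bounds in processed.region_bounds:
        mask = processed.region_mask(bounds)
        peak = noisy[mask].max()
        if peak > 0:
            noisy[mask] = noisy[mask] / peak
    experiment = GridSpectrum(processed.grid, noisy, region_bounds=processed.region_bounds)
    return spectra, experiment, carrier


def make_two_state_ensemble(
    dH: float = 10.0, dS: float = 25.0, omegas: tuple[float, float] = (148.0, 160.0)
) -> ConformerEnsemble:
    """Two-conformer ensemble with analytic ΔG(T) = ΔH − T·ΔS.

    The reference conformer sits at ΔG = 0; the second at ΔH (kJ·mol⁻¹) with
    entropy gain ΔS (J·mol⁻¹·K⁻¹), so the population crossover temperature is
    T = 1000·ΔH/ΔS.  Defaults emulate a compact conformer (smaller collision
    cross section) giving way to an entropy-favoured extended one.
    """
    if dS == 0:
        raise ValueError("a zero entropy difference gives no crossover")
    return ConformerEnsemble(
        [
            Conformer("compact", omega=omegas[0], dH=0.0, dS=0.0),
            Conformer("extended", omega=omegas[1], dH=dH, dS=dS),
        ]
    )
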