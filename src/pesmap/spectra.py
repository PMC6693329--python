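"""Spectral-carrier assignment pipeline for harmonic IR spectra.

Computed stick spectra are compared to a digitised experimental spectrum by:

1. scaling harmonic frequencies with per-region empirical factors,
2. broadening each stick with a Lorentzian line shape (intensity-scaled unit
   peak height; only relative shape matters after normalisation),
3. resampling on a regular grid (default 2 cm⁻¹) per spectral region and
   max-normalising each region to 1,
4. concatenating the regions into a single intensity vector, and
5. ranking isomers by Euclidean distance to the experiment, mapped onto a
   scaled similarity index in [0, 1] (1 = best match, 0 = worst).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LineSpectrum",
    "SpectralRegion",
    "GridSpectrum",
    "AlignmentError",
    "DegenerateDistanceSetError",
    "DEFAULT_REGIONS",
    "scale_lines",
    "broaden",
    "concat_regions",
    "euclid",
    "scaled_similarity",
    "rank_carriers",
    "process_spectrum",
    "load_sticks",
    "load_experiment",
]


class AlignmentError(ValueError):
    """Two grid spectra are not on the same frequency grid."""


class DegenerateDistanceSetError(ValueError):
    """All Euclidean distances equal; the scaled similarity is undefined."""


@dataclass(frozen=True)
class LineSpectrum:
    """A stick spectrum: (frequency cm⁻¹, intensity) pairs for one isomer."""

    lines: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        lines = tuple((float(f), float(a)) for f, a in self.lines)
        for f, a in lines:
            if f <= 0:
                raise ValueError(f"frequencies must be positive, got {f}")
            if not np.isfinite(a) or a < 0:
                raise ValueError(f"intensities must be finite and non-negative, got {a}")
        object.__setattr__(self, "lines", lines)


@dataclass(frozen=True)
class SpectralRegion:
    """A frequency window with its grid step and harmonic scaling factor."""

    lo: float
    hi: float
    grid_step: float = 2.0
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("region requires lo < hi")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if not 0.0 < self.scale_factor <= 1.2:
            raise ValueError("scale_factor must lie in (0, 1.2]")

    def grid(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + self.grid_step / 2, self.grid_step)

    def contains(self, freq: float) -> bool:
        return self.lo <= freq <= self.hi


# Case-study defaults: scale factors 0.9679 / 0.95 on the fingerprint and
# X–H stretch windows of the concatenated experimental spectrum.
DEFAULT_REGIONS: list[SpectralRegion] = [
    SpectralRegion(1000.0, 1900.0, scale_factor=0.9679),
    SpectralRegion(3200.0, 3800.0, scale_factor=0.95),
]


@dataclass(frozen=True)
class GridSpectrum:
    """Regularly gridded, per-region max-normalised intensity vector."""

    grid: np.ndarray
    intensities: np.ndarray
    region_bounds: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if grid.shape != inten.shape or grid.ndim != 1:
            raise ValueError("grid and intensities must be matching 1-D arrays")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "region_bounds", tuple(tuple(b) for b in self.region_bounds))

    def region_mask(self, bounds: tuple[float, float]) -> np.ndarray:
        lo, hi = bounds
        return (self.grid >= lo) & (self.grid <= hi)


def scale_lines(s: LineSpectrum, regions: Sequence[SpectralRegion]) -> LineSpectrum:
    """Multiply each line frequency by its region's scale factor.

    Region assignment is by unscaled frequency; a line outside every region
    is dropped with a warning.
    """
    out = []
    for f, a in s.lines:
        region = next((r for r in regions if r.contains(f)), None)
        if region is None:
            warnings.warn(
                f"{s.label or 'spectrum'}: line at {f:.1f} cm⁻¹ falls outside all "
                f"regions and was dropped", stacklevel=2,
            )
            continue
        out.append((f * region.scale_factor, a))
    return LineSpectrum(tuple(out), label=s.label)


def broaden(s: LineSpectrum, fwhm: float, region: SpectralRegion) -> GridSpectrum:
    """Lorentzian-broaden sticks onto one region's grid and max-normalise.

    Each line contributes A_k·γ²/((ν−ν_k)² + γ²) with γ = fwhm/2 (unit peak
    height scaled by the stick intensity).  A region with zero total
    intensity is returned as an all-zero vector (empty-region marker).
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    grid = region.grid()
    gamma = fwhm / 2.0
    inten = np.zeros_like(grid)
    for f, a in s.lines:
        inten += a * gamma**2 / ((grid - f) ** 2 + gamma**2)
    peak = inten.max() if inten.size else 0.0
    if peak > 0:
        inten = inten / peak
    return GridSpectrum(grid, inten, region_bounds=((region.lo, region.hi),))


def concat_regions(parts: Sequence[GridSpectrum]) -> GridSpectrum:
    """Concatenate per-region spectra in frequency order.

    Each region keeps its own normalisation; regions must not overlap.
    """
    parts = sorted(parts, key=lambda p: p.grid[0] if p.grid.size else np.inf)
    bounds: list[tuple[float, float]] = []
    for p in parts:
        bounds.extend(p.region_bounds)
    for (l1, h1), (l2, h2) in zip(bounds, bounds[1:]):
        if h1 >= l2:
            raise ValueError(f"regions [{l1}, {h1}] and [{l2}, {h2}] overlap")
    return GridSpectrum(
        np.concatenate([p.grid for p in parts]),
        np.concatenate([p.intensities for p in parts]),
        region_bounds=tuple(bounds),
    )


def euclid(a: GridSpectrum, b: GridSpectrum) -> float:
    """Euclidean distance between two intensity vectors on identical grids."""
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise AlignmentError("spectra are not on the same frequency grid")
    return float(np.linalg.norm(a.intensities - b.intensities))


def scaled_similarity(distances: Sequence[float]) -> np.ndarray:
    """Scaled similarity index: 1 − (d − d_min)/max(d − d_min).

    Maps the best-matching isomer (smallest distance) to exactly 1 and the
    worst to exactly 0; invariant under affine rescaling of the distances.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two isomers to scale similarities")
    shifted = d - d.min()
    denom = shifted.max()
    if denom == 0.0:
        raise DegenerateDistanceSetError("all distances equal; scores are undefined")
    return 1.0 - shifted / denom


def process_spectrum(
    s: LineSpectrum,
    regions: Sequence[SpectralRegion],
    fwhm: float = 15.0,
    target: GridSpectrum | None = None,
) -> GridSpectrum:
    """Full per-isomer processing: scale → broaden per region → concatenate.

    When ``target`` is given, the result is linearly resampled onto the
    target's grid so Euclidean comparison is well-defined.
    """
    scaled = scale_lines(s, regions)
    out = concat_regions([broaden(scaled, fwhm=fwhm, region=r) for r in regions])
    if target is not None and (
        out.grid.shape != target.grid.shape or not np.allclose(out.grid, target.grid)
    ):
        inten = np.interp(target.grid, out.grid, out.intensities)
        out = GridSpectrum(target.grid.copy(), inten, region_bounds=target.region_bounds)
    return out


def rank_carriers(
    computed: Sequence[LineSpectrum],
    experiment: GridSpectrum,
    regions: Sequence[SpectralRegion] | None = None,
    fwhm: float = 15.0,
) -> pd.DataFrame:
    """Rank candidate spectral carriers against an experimental spectrum.

    Runs the full pipeline for each isomer, computes Euclidean distances to
    the experiment, and assigns scaled similarity scores.  Returns a table
    (isomer, d_euc, score, rank) sorted best-first.
    """
    regions = list(regions) if regions is not None else list(DEFAULT_REGIONS)
    labels, dists = [], []
    for i, s in enumerate(computed):
        proc = process_spectrum(s, regions, fwhm=fwhm, target=experiment)
        labels.append(s.label or f"isomer {i}")
        dists.append(euclid(proc, experiment))
    scores = scaled_similarity(dists)
    df = pd.DataFrame({"isomer": labels, "d_euc": dists, "score": scores})
    df = df.sort_values(["score", "isomer"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Plain-text I/O


def load_sticks(path: str | Path, label: str = "") -> LineSpectrum:
    """Read a two-column (frequency, intensity) whitespace/CSV stick table."""
    data = _read_two_column(path)
    return LineSpectrum(tuple(map(tuple, data)), label=label or Path(path).stem)


def load_experiment(
    path: str | Path, regions: Sequence[SpectralRegion] | None = None
) -> GridSpectrum:
    """Read a digitised experimental spectrum and regrid it per region.

    The two-column input is linearly interpolated onto each region's grid and
    max-normalised per region, then the regions are concatenated.
    """
    regions = list(regions) if regions is not None else list(DEFAULT_REGIONS)
    data = _read_two_column(path)
    order = np.argsort(data[:, 0])
    freq, inten = data[order, 0], data[order, 1]
    parts = []
    for r in regions:
        grid = r.grid()
        vals = np.interp(grid, freq, inten, left=0.0, right=0.0)
        peak = vals.max()
        if peak > 0:
            vals = vals / peak
        parts.append(GridSpectrum(grid, vals, region_bounds=((r.lo, r.hi),)))
    return concat_regions(parts)


def _read_two_column(path: str | Path) -> np.ndarray:
    text = Path(path).read_text()
    first = text.splitlines()[0]
    delim = "," if "," in first else None
    try:
        data = np.loadtxt(path, delimiter=delim, comments="#")
    except ValueError:
        # tolerate a header row of column names
        data = np.loadtxt(path, delimiter=delim, comments="#", skiprows=1)
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (frequency, intensity)")
    return data[:, :2]
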