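"""Peak-intensity extraction: full spectra → the 43-variable table.

The model variable for each emission line is its observed peak intensity:
the maximum spectral value on grid points within a small window around the
nominal wavelength. No baseline subtraction or line-shape fitting is
applied — the raw observed height is the variable.
"""

from __future__ import annotations

import numpy as np

from .lines import EmissionLine
from .spectra_io import PeakTable
from .synthetic import Spectrum

__all__ = ["DEFAULT_HALF_WINDOW_NM", "peak_intensity", "build_peak_table"]

# Separates the Na I 589.03/589.64 doublet while tolerating a couple of
# grid steps of line-position mismatch.
DEFAULT_HALF_WINDOW_NM = 0.25


def peak_intensity(
    spectrum: Spectrum, line: EmissionLine, half_window_nm: float = DEFAULT_HALF_WINDOW_NM
) -> float:
    """Maximum intensity within ±half_window of the line's nominal wavelength."""
    if half_window_nm <= 0:
        raise ValueError("half_window_nm must be positive")
    grid = spectrum.grid_nm
    if not grid[0] <= line.wavelength_nm <= grid[-1]:
        raise ValueError(
            f"line {line.species} {line.wavelength_nm} nm outside grid "
            f"[{grid[0]}, {grid[-1]}]"
        )
    lo = np.searchsorted(grid, line.wavelength_nm - half_window_nm)
    hi = np.searchsorted(grid, line.wavelength_nm + half_window_nm, side="right")
    if hi <= lo:
        raise ValueError(
            f"no grid points within ±{half_window_nm} nm of {line.wavelength_nm} nm"
        )
    return float(spectrum.intensity[lo:hi].max())


def build_peak_table(
    spectra: list[Spectrum],
    lines: tuple[EmissionLine, ...] | list[EmissionLine],
    half_window_nm: float = DEFAULT_HALF_WINDOW_NM,
) -> PeakTable:
    """Assemble the samples × lines intensity matrix, preserving input order."""
    if not spectra:
        raise ValueError("no spectra given")
    grid = spectra[0].grid_nm
    for i, s in enumerate(spectra[1:], start=2):
        if s.grid_nm.shape != grid.shape or not np.array_equal(s.grid_nm, grid):
            raise ValueError(f"spectrum {i} is on a different wavelength grid")
    lines = tuple(lines)

    # window bounds are shared across samples, so locate them once
    bounds = []
    for line in lines:
        if not grid[0] <= line.wavelength_nm <= grid[-1]:
            raise ValueError(f"line {line.wavelength_nm} nm outside the shared grid")
        lo = np.searchsorted(grid, line.wavelength_nm - half_window_nm)
        hi = np.searchsorted(grid, line.wavelength_nm + half_window_nm, side="right")
        if hi <= lo:
            raise ValueError(f"no grid points in window of line {line.wavelength_nm} nm")
        bounds.append((lo, hi))

    intensities = np.empty((len(spectra), len(lines)))
    for r, s in enumerate(spectra):
        for c, (lo, hi) in enumerate(bounds):
            intensities[r, c] = s.intensity[lo:hi].max()
    fractions = np.array(
        [np.nan if s.fraction is None else s.fraction for s in spectra], dtype=float
    )
    if np.any(np.isnan(fractions)):
        raise ValueError("every spectrum must carry its adulterant fraction")
    return PeakTable(
        sample_ids=[s.sample_id for s in spectra],
        fractions=fractions,
        intensities=intensities,
        lines=lines,
    )
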