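"""On-disk formats: wide spectral CSVs, peak tables, selection masks, reports.

All files are plain comma-separated UTF-8 with a mandatory header row and
``.`` decimals. Data values are written with repr-shortest float formatting
so a write/read round trip is lossless; wavelength headers carry two
decimals (the library's printed precision).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .lines import EmissionLine, line_column_label
from .synthetic import Spectrum

__all__ = [
    "PeakTable",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_peak_table_csv",
    "write_peak_table_csv",
    "write_selection_csv",
    "write_report_json",
]


@dataclass
class PeakTable:
    """Samples × emission-lines intensity matrix with aligned fraction targets."""

    sample_ids: list[str]
    fractions: np.ndarray
    intensities: np.ndarray  # (n_samples, n_lines), non-negative
    lines: tuple[EmissionLine, ...]

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        n, p = self.intensities.shape
        if len(self.sample_ids) != n or self.fractions.shape != (n,):
            raise ValueError("sample_ids, fractions and intensity rows must align")
        if p != len(self.lines):
            raise ValueError(
                f"intensity matrix has {p} columns but the line library has {len(self.lines)}"
            )
        if np.any(~np.isfinite(self.intensities)) or np.any(~np.isfinite(self.fractions)):
            raise ValueError("peak table must not contain missing values")
        if np.any(self.intensities < 0):
            raise ValueError("peak intensities must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_lines(self) -> int:
        return self.intensities.shape[1]

    def subset(self, mask: np.ndarray) -> "PeakTable":
        """Column subset by boolean mask over lines."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_lines,):
            raise ValueError("mask length must equal number of lines")
        return PeakTable(
            sample_ids=list(self.sample_ids),
            fractions=self.fractions.copy(),
            intensities=self.intensities[:, mask].copy(),
            lines=tuple(ln for ln, m in zip(self.lines, mask) if m),
        )


def write_spectra_csv(spectra: list[Spectrum], path: str | Path) -> None:
    """Wide CSV: sample_id, fraction, then one column per grid wavelength."""
    if not spectra:
        raise ValueError("no spectra to write")
    grid = spectra[0].grid_nm
    for i, s in enumerate(spectra[1:], start=2):
        if s.grid_nm.shape != grid.shape or not np.allclose(s.grid_nm, grid, rtol=0, atol=1e-9):
            raise ValueError(f"spectrum {i} is on a different wavelength grid")
    cols = [f"{w:.2f}" for w in grid]
    df = pd.DataFrame(
        np.vstack([s.intensity for s in spectra]), columns=cols
    )
    df.insert(0, "fraction", [np.nan if s.fraction is None else s.fraction for s in spectra])
    df.insert(0, "sample_id", [s.sample_id for s in spectra])
    df.to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> list[Spectrum]:
    """Read a wide spectral CSV, validating the wavelength header."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no samples (empty file)") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no samples")
    if list(df.columns[:2]) != ["sample_id", "fraction"]:
        raise ValueError(f"{path}: first two columns must be sample_id, fraction")
    wl_cols = list(df.columns[2:])
    try:
        grid = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavelength column: {exc}") from None
    bad = np.nonzero(np.diff(grid) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: wavelength header not strictly ascending at column "
            f"{wl_cols[bad[0] + 1]!r} (position {bad[0] + 3})"
        )
    inten = df[wl_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(inten)):
        r, c = np.argwhere(~np.isfinite(inten))[0]
        raise ValueError(
            f"{path}: non-numeric or missing intensity in row {r + 1}, column {wl_cols[c]!r}"
        )
    out = []
    for i in range(df.shape[0]):
        frac = df["fraction"].iloc[i]
        out.append(
            Spectrum(
                grid_nm=grid.copy(),
                intensity=inten[i],
                sample_id=str(df["sample_id"].iloc[i]),
                fraction=None if pd.isna(frac) else float(frac),
            )
        )
    return out


def write_peak_table_csv(table: PeakTable, path: str | Path) -> None:
    """CSV with columns sample_id, fraction, then ``<wavelength>_<species>``."""
    df = pd.DataFrame(table.intensities, columns=[line_column_label(ln) for ln in table.lines])
    df.insert(0, "fraction", table.fractions)
    df.insert(0, "sample_id", table.sample_ids)
    df.to_csv(path, index=False)


def _parse_line_label(label: str, index: int) -> EmissionLine:
    wl_str, _, species = label.partition("_")
    return EmissionLine(
        wavelength_nm=float(wl_str), species=species.replace("_", " "), index=index
    )


def read_peak_table_csv(
    path: str | Path, lines: tuple[EmissionLine, ...] | list[EmissionLine] | None = None
) -> PeakTable:
    """Read a peak-table CSV; if ``lines`` is given, validate against it."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no samples (empty file)") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no samples")
    if "fraction" not in df.columns or "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required sample_id/fraction column")
    value_cols = [c for c in df.columns if c not in ("sample_id", "fraction")]
    try:
        parsed = tuple(_parse_line_label(c, i + 1) for i, c in enumerate(value_cols))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed line column label: {exc}") from None
    if lines is not None:
        lines = tuple(lines)
        if len(parsed) != len(lines):
            raise ValueError(
                f"{path}: table has {len(parsed)} line columns but the library has {len(lines)}"
            )
        for got, want in zip(parsed, lines):
            if abs(got.wavelength_nm - want.wavelength_nm) > 5e-3 or got.species != want.species:
                raise ValueError(
                    f"{path}: column {line_column_label(got)!r} does not match "
                    f"library line {line_column_label(want)!r}"
                )
        parsed = lines
    return PeakTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        fractions=df["fraction"].to_numpy(dtype=float),
        intensities=df[value_cols].to_numpy(dtype=float),
        lines=parsed,
    )


def write_selection_csv(selection, lines, path: str | Path) -> None:
    """Per-line selection mask export: wavelength, species, score, selected."""
    df = pd.DataFrame(
        {
            "wavelength_nm": [ln.wavelength_nm for ln in lines],
            "species": [ln.species for ln in lines],
            "score": np.asarray(selection.scores, dtype=float),
            "selected": np.asarray(selection.mask, dtype=int),
        }
    )
    df.to_csv(path, index=False)


def write_report_json(reports, path: str | Path) -> None:
    """Serialize evaluation reports (dataclasses or dicts) as a JSON list."""
    payload = []
    for r in reports:
        d = r if isinstance(r, dict) else asdict(r)
        payload.append(_jsonable(d))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
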