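"""The 43-line LIBS emission library used as the variable set.

Each variable in the chemometric models is the observed peak intensity of
one emission line (atomic line such as Mg II 279.58 nm, or a molecular CN
violet-band head). Four lines could not be assigned to a species and are
labelled "Unknown".
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EmissionLine", "make_line_library", "line_column_label"]


@dataclass(frozen=True, slots=True)
class EmissionLine:
    """One emission line: nominal wavelength (nm), species label, 1-based index."""

    wavelength_nm: float
    species: str
    index: int

    def __post_init__(self) -> None:
        if not 240.0 <= self.wavelength_nm <= 860.0:
            raise ValueError(
                f"line {self.index}: wavelength {self.wavelength_nm} nm outside [240, 860]"
            )


# (wavelength nm, species). Order is ascending wavelength; index is position + 1.
_LINE_DATA: tuple[tuple[float, str], ...] = (
    (247.88, "C I"),
    (250.72, "Si I"),
    (251.45, "Si I"),
    (251.64, "Si I"),
    (251.94, "Si I"),
    (252.44, "Si I"),
    (252.88, "Si I"),
    (279.58, "Mg II"),
    (280.30, "Mg II"),
    (285.25, "Mg I"),
    (288.20, "Si I"),
    (385.07, "CN 4-4"),
    (385.49, "CN 3-3"),
    (386.17, "CN 2-2"),
    (387.13, "CN 1-1"),
    (388.33, "CN 0-0"),
    (393.37, "Ca II"),
    (396.89, "Ca II"),
    (422.70, "Ca I"),
    (589.03, "Na I"),
    (589.64, "Na I"),
    (656.33, "Hα"),
    (715.77, "O I"),
    (742.45, "N I"),
    (744.30, "N I"),
    (746.92, "N I"),
    (748.47, "Unknown"),
    (766.57, "K I"),
    (769.97, "K I"),
    (777.47, "O I"),
    (794.83, "Unknown"),
    (795.17, "Unknown"),
    (818.57, "N I"),
    (818.86, "N I"),
    (820.10, "N I"),
    (821.14, "N I"),
    (821.68, "N I"),
    (822.28, "N I"),
    (822.43, "Unknown"),
    (824.32, "N I"),
    (844.73, "O I"),
    (856.86, "N I"),
    (859.49, "N I"),
)


def make_line_library() -> list[EmissionLine]:
    """Return the 43 emission lines in ascending wavelength order."""
    lib = [
        EmissionLine(wavelength_nm=wl, species=sp, index=i + 1)
        for i, (wl, sp) in enumerate(_LINE_DATA)
    ]
    assert all(a.wavelength_nm < b.wavelength_nm for a, b in zip(lib, lib[1:]))
    return lib


def line_column_label(line: EmissionLine) -> str:
    """Column label for peak tables, e.g. ``279.58_Mg_II``."""
    return f"{line.wavelength_nm:.2f}_{line.species.replace(' ', '_')}"
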