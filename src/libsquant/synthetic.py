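"""Synthetic LIBS spectra of honey/adulterant binary mixtures.

The study system is acacia honey (the "pure" endmember) adulterated with
HFCS F55, HFCS F90, or rape honey. No measured spectra are distributed, so
this module emulates them: each endmember is a vector of non-negative
emission-line amplitudes over the 43-line library, mixtures combine the two
endmember amplitude vectors linearly in the adulterant mass fraction, and a
measurement is the shot-averaged spectrum (Gaussian peaks on a flat
baseline plus averaged shot noise).

The encoded spectral contrasts follow the qualitative elemental picture of
the real samples: Mg, Ca and K emissions are present in both honeys and
absent from HFCS; Na emission is markedly stronger in acacia than in rape
honey and weak in HFCS; C/H/O/N and the CN violet bands appear in all four
endmembers, with HFCS F90 departing further from acacia than F55 does; the
Si and unassigned lines are essentially identical across endmembers and
act as uninformative variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lines import EmissionLine, make_line_library

__all__ = [
    "ENDMEMBER_KINDS",
    "EndmemberProfile",
    "MixtureDesign",
    "Spectrum",
    "NoiseConfig",
    "AmplitudeConfig",
    "make_endmember_profile",
    "mix_profiles",
    "render_spectrum",
    "simulate_measurement",
    "generate_dataset",
    "Dataset",
    "child_seed",
]

ENDMEMBER_KINDS = ("acacia", "rape", "hfcs55", "hfcs90")

GRID_MIN_NM = 240.0
GRID_MAX_NM = 860.0

# Fixed stream tags so different random purposes never share a substream.
_TAG_AMPLITUDE = 101
_TAG_MEASUREMENT = 202


def child_seed(master: int, *path: int) -> int:
    """Derive a 31-bit child seed from a master seed and an integer path.

    Counter-style fan-out: each (master, path) pair maps to an independent
    stream, so adding a new consumer with a fresh path tag never shifts the
    randomness of existing ones.
    """
    ss = np.random.SeedSequence([int(master), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _element_of(line: EmissionLine) -> str:
    species = line.species
    if species == "Unknown":
        return "Unknown"
    if species.startswith("Hα"):
        return "H"
    return species.split(" ")[0].split("-")[0].rstrip("αβ") or species


@dataclass(frozen=True)
class AmplitudeConfig:
    """Amplitude ranges (arbitrary intensity units) for the endmember profiles.

    ``*_base`` ranges feed one shared per-line draw (common to all
    endmembers); per-kind multiplicative factor ranges then set the
    between-endmember contrast of each species group. Na lines are drawn
    directly from per-kind ranges so the acacia > rape ordering is strict.
    """

    mineral_base: tuple[float, float] = (40.0, 70.0)
    organic_base: tuple[float, float] = (20.0, 50.0)
    inert_base: tuple[float, float] = (10.0, 30.0)
    na_range: dict = field(
        default_factory=lambda: {
            "acacia": (70.0, 90.0),
            "rape": (20.0, 30.0),
            "hfcs55": (2.0, 5.0),
            "hfcs90": (2.0, 5.0),
        }
    )
    # multiplicative factors applied to the shared base draw
    mineral_factor: dict = field(
        default_factory=lambda: {
            "acacia": (0.99, 1.01),
            "rape": (0.60, 0.80),
            "hfcs55": None,  # None -> amplitude exactly 0
            "hfcs90": None,
        }
    )
    # C and CN: carbon backbone, strongest compositional contrast vs HFCS
    carbon_factor: dict = field(
        default_factory=lambda: {
            "acacia": (0.99, 1.01),
            "rape": (0.95, 1.05),
            "hfcs55": (1.04, 1.10),
            "hfcs90": (1.18, 1.32),
        }
    )
    # H, O, N: weak contrast for F55, moderate for F90
    organic_factor: dict = field(
        default_factory=lambda: {
            "acacia": (0.99, 1.01),
            "rape": (0.97, 1.03),
            "hfcs55": (0.97, 1.03),
            "hfcs90": (1.10, 1.20),
        }
    )
    # Si and unassigned lines: same in every endmember up to ~1% jitter
    inert_factor: dict = field(
        default_factory=lambda: {
            "acacia": (0.99, 1.01),
            "rape": (0.99, 1.01),
            "hfcs55": (0.99, 1.01),
            "hfcs90": (0.99, 1.01),
        }
    )


@dataclass(frozen=True)
class EndmemberProfile:
    """Per-line emission amplitudes of one endmember (or mixture thereof)."""

    kind: str
    amplitudes: np.ndarray  # aligned with the line library, non-negative
    lines: tuple[EmissionLine, ...]

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.shape != (len(self.lines),):
            raise ValueError("amplitudes must align with the line library")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(self, "amplitudes", amps)

    def amplitude_at(self, wavelength_nm: float, species: str | None = None) -> float:
        for i, ln in enumerate(self.lines):
            if abs(ln.wavelength_nm - wavelength_nm) < 1e-9 and (
                species is None or ln.species == species
            ):
                return float(self.amplitudes[i])
        raise KeyError(f"no library line at {wavelength_nm} nm")


def make_endmember_profile(
    kind: str, seed: int, config: AmplitudeConfig | None = None
) -> EndmemberProfile:
    """Draw a reproducible amplitude profile for one endmember.

    The same ``seed`` yields the same shared per-line base levels for every
    kind, so cross-endmember contrasts are controlled by the factor ranges
    alone; calling twice with identical arguments is bit-identical.
    """
    if kind not in ENDMEMBER_KINDS:
        raise ValueError(f"unknown endmember kind {kind!r}; expected one of {ENDMEMBER_KINDS}")
    cfg = config or AmplitudeConfig()
    lib = tuple(make_line_library())

    base_rng = np.random.default_rng(
        np.random.SeedSequence([_TAG_AMPLITUDE, int(seed)])
    )
    kind_rng = np.random.default_rng(
        np.random.SeedSequence([_TAG_AMPLITUDE, int(seed), ENDMEMBER_KINDS.index(kind)])
    )

    amps = np.empty(len(lib))
    for i, line in enumerate(lib):
        elem = _element_of(line)
        if elem in ("Mg", "Ca", "K"):
            base = base_rng.uniform(*cfg.mineral_base)
            factor_range = cfg.mineral_factor[kind]
        elif elem == "Na":
            base = base_rng.uniform(*cfg.mineral_base)  # consumed for alignment
            lo, hi = cfg.na_range[kind]
            amps[i] = kind_rng.uniform(lo, hi)
            continue
        elif elem in ("C", "CN"):
            base = base_rng.uniform(*cfg.organic_base)
            factor_range = cfg.carbon_factor[kind]
        elif elem in ("H", "O", "N"):
            base = base_rng.uniform(*cfg.organic_base)
            factor_range = cfg.organic_factor[kind]
        else:  # Si, Unknown
            base = base_rng.uniform(*cfg.inert_base)
            factor_range = cfg.inert_factor[kind]

        if factor_range is None:
            kind_rng.uniform(0.0, 1.0)  # keep the per-kind stream aligned
            amps[i] = 0.0
        else:
            amps[i] = base * kind_rng.uniform(*factor_range)

    return EndmemberProfile(kind=kind, amplitudes=amps, lines=lib)


def mix_profiles(
    pure: EndmemberProfile, adulterant: EndmemberProfile, fraction: float
) -> EndmemberProfile:
    """Linear binary mixture: (1 − fraction)·pure + fraction·adulterant."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    if pure.lines != adulterant.lines:
        raise ValueError("profiles must share one line library")
    amps = (1.0 - fraction) * pure.amplitudes + fraction * adulterant.amplitudes
    return EndmemberProfile(
        kind=f"mix({pure.kind}+{adulterant.kind})", amplitudes=amps, lines=pure.lines
    )


@dataclass
class Spectrum:
    """One sample's wavelength grid and (shot-averaged) intensities."""

    grid_nm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    fraction: float | None = None

    def __post_init__(self) -> None:
        self.grid_nm = np.asarray(self.grid_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid_nm.shape != self.intensity.shape:
            raise ValueError("grid and intensity must have equal length")
        if self.grid_nm.size >= 2 and np.any(np.diff(self.grid_nm) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if self.fraction is not None and not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseConfig:
    """Shot-noise model: per-shot additive Gaussian SD, averaged over shots."""

    sigma_shot: float = 20.0
    n_shots: int = 100
    baseline_level: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_shot < 0:
            raise ValueError("sigma_shot must be >= 0")
        if self.n_shots < 1:
            raise ValueError("n_shots must be >= 1")
        if self.baseline_level < 0:
            raise ValueError("baseline_level must be >= 0")


def render_spectrum(
    profile: EndmemberProfile,
    grid_step_nm: float = 0.05,
    peak_fwhm_nm: float = 0.30,
    baseline: float = 1.0,
    sample_id: str = "",
    fraction: float | None = None,
) -> Spectrum:
    """Render the noiseless spectrum: baseline plus one Gaussian peak per line.

    Peak height equals the line amplitude; peaks are evaluated only within
    ±6 FWHM of their centre (the Gaussian is < 1e-43 of peak height beyond
    that, far under the 0.1 % centre-value tolerance).
    """
    if grid_step_nm <= 0 or peak_fwhm_nm <= 0:
        raise ValueError("grid step and FWHM must be positive")
    if grid_step_nm > peak_fwhm_nm / 2:
        raise ValueError(
            f"grid step {grid_step_nm} too coarse for FWHM {peak_fwhm_nm}; "
            "need step <= FWHM/2 so peaks are resolvable"
        )
    n_points = int(round((GRID_MAX_NM - GRID_MIN_NM) / grid_step_nm)) + 1
    grid = np.linspace(GRID_MIN_NM, GRID_MAX_NM, n_points)
    intensity = np.full(n_points, float(baseline))
    four_ln2 = 4.0 * math.log(2.0)
    halfspan = 6.0 * peak_fwhm_nm
    for amp, line in zip(profile.amplitudes, profile.lines):
        if amp == 0.0:
            continue
        lo = np.searchsorted(grid, line.wavelength_nm - halfspan)
        hi = np.searchsorted(grid, line.wavelength_nm + halfspan, side="right")
        d = (grid[lo:hi] - line.wavelength_nm) / peak_fwhm_nm
        intensity[lo:hi] += amp * np.exp(-four_ln2 * d * d)
    return Spectrum(grid_nm=grid, intensity=intensity, sample_id=sample_id, fraction=fraction)


def simulate_measurement(spectrum: Spectrum, noise: NoiseConfig) -> Spectrum:
    """Shot-averaged noisy measurement of a noiseless spectrum.

    The average of ``n_shots`` independent additive N(0, sigma_shot) shot
    noises is N(0, sigma_shot/sqrt(n_shots)) at each pixel, and is drawn as
    such in a single step. Negative averaged intensities are clipped to 0
    (physical non-negativity, applied after averaging).
    """
    if noise.sigma_shot == 0.0:
        return Spectrum(
            grid_nm=spectrum.grid_nm.copy(),
            intensity=spectrum.intensity.copy(),
            sample_id=spectrum.sample_id,
            fraction=spectrum.fraction,
        )
    rng = np.random.default_rng(np.random.SeedSequence([_TAG_MEASUREMENT, int(noise.seed)]))
    sigma_avg = noise.sigma_shot / math.sqrt(noise.n_shots)
    noisy = spectrum.intensity + rng.normal(0.0, sigma_avg, size=spectrum.intensity.shape)
    np.clip(noisy, 0.0, None, out=noisy)
    return Spectrum(
        grid_nm=spectrum.grid_nm.copy(),
        intensity=noisy,
        sample_id=spectrum.sample_id,
        fraction=spectrum.fraction,
    )


def _default_calibration_levels() -> list[float]:
    return [round(0.05 * i, 10) for i in range(21)]


def _default_prediction_levels() -> list[float]:
    return [round(0.08 * i, 10) for i in range(13)]


@dataclass(frozen=True)
class MixtureDesign:
    """Adulteration design: 21 calibration levels (5 % steps, 0–100 %) and
    13 prediction levels (8 % steps, 0–96 %), three replicates each —
    63 calibration and 39 prediction samples."""

    calibration_levels: tuple = field(default_factory=lambda: tuple(_default_calibration_levels()))
    prediction_levels: tuple = field(default_factory=lambda: tuple(_default_prediction_levels()))
    replicates: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "calibration_levels", tuple(self.calibration_levels))
        object.__setattr__(self, "prediction_levels", tuple(self.prediction_levels))
        for lv in (*self.calibration_levels, *self.prediction_levels):
            if not 0.0 <= lv <= 1.0:
                raise ValueError(f"design fraction {lv} outside [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class Dataset:
    """Calibration and prediction spectra with their true adulterant fractions."""

    calibration: list[Spectrum]
    prediction: list[Spectrum]

    @property
    def calibration_fractions(self) -> np.ndarray:
        return np.array([s.fraction for s in self.calibration])

    @property
    def prediction_fractions(self) -> np.ndarray:
        return np.array([s.fraction for s in self.prediction])


def generate_dataset(
    pure_kind: str,
    adulterant_kind: str,
    design: MixtureDesign | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    amplitude_config: AmplitudeConfig | None = None,
    grid_step_nm: float = 0.05,
    peak_fwhm_nm: float = 0.30,
) -> Dataset:
    """Simulate the full calibration + prediction measurement campaign.

    Replicates at the same level receive independent shot noise; all
    randomness fans out from ``seed`` by a fixed counter scheme.
    """
    if pure_kind not in ENDMEMBER_KINDS or adulterant_kind not in ENDMEMBER_KINDS:
        raise ValueError(f"kinds must be in {ENDMEMBER_KINDS}")
    if pure_kind == adulterant_kind:
        raise ValueError("pure and adulterant kinds must be distinct")
    design = design or MixtureDesign()
    noise = noise or NoiseConfig()
    if not design.calibration_levels or not design.prediction_levels:
        raise ValueError("design level lists must be non-empty")

    pure = make_endmember_profile(pure_kind, seed, amplitude_config)
    adulterant = make_endmember_profile(adulterant_kind, seed, amplitude_config)

    def one_set(levels, set_tag: int, set_name: str) -> list[Spectrum]:
        out = []
        for li, frac in enumerate(levels):
            mixed = mix_profiles(pure, adulterant, frac)
            clean = render_spectrum(
                mixed,
                grid_step_nm=grid_step_nm,
                peak_fwhm_nm=peak_fwhm_nm,
                baseline=noise.baseline_level,
                fraction=frac,
            )
            for rep in range(design.replicates):
                rep_noise = NoiseConfig(
                    sigma_shot=noise.sigma_shot,
                    n_shots=noise.n_shots,
                    baseline_level=noise.baseline_level,
                    seed=child_seed(seed, noise.seed, set_tag, li, rep),
                )
                meas = simulate_measurement(clean, rep_noise)
                meas.sample_id = f"{adulterant_kind}_{set_name}_L{li:02d}_r{rep + 1}"
                out.append(meas)
        return out

    return Dataset(
        calibration=one_set(design.calibration_levels, 0, "cal"),
        prediction=one_set(design.prediction_levels, 1, "pred"),
    )
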