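import numpy as np
import pytest

import libsquant as lq


@pytest.fixture(scope="session")
def library():
    return tuple(lq.make_line_library())


@pytest.fixture(scope="session")
def noiseless_hfcs55(library):
    """Noiseless default-design HFCS F55 series with its peak tables."""
    ds = lq.generate_dataset(
        "acacia", "hfcs55", noise=lq.NoiseConfig(sigma_shot=0.0), seed=11
    )
    cal = lq.build_peak_table(ds.calibration, library)
    pred = lq.build_peak_table(ds.prediction, library)
    return ds, cal, pred


@pytest.fixture(scope="session")
def noisy_rape(library):
    """Default-noise rape-honey series with its peak tables."""
    ds = lq.generate_dataset("acacia", "rape", noise=lq.NoiseConfig(sigma_shot=20.0), seed=5)
    cal = lq.build_peak_table(ds.calibration, library)
    pred = lq.build_peak_table(ds.prediction, library)
    return ds, cal, pred


def amplitude_peak_table(pure_kind, adulterant_kind, seed, levels=None, replicates=3):
    """Peak table built directly from mixed profile amplitudes.

    Bypasses rendering and windowed extraction, so every column is exactly
    affine in the adulterant fraction (an exact one-factor system).
    """
    lib = tuple(lq.make_line_library())
    pure = lq.make_endmember_profile(pure_kind, seed)
    adult = lq.make_endmember_profile(adulterant_kind, seed)
    if levels is None:
        levels = np.linspace(0, 1, 21)
    rows, fracs, ids = [], [], []
    for li, f in enumerate(levels):
        amps = lq.mix_profiles(pure, adult, float(f)).amplitudes
        for rep in range(replicates):
            rows.append(amps + 1.0)  # constant baseline offset
            fracs.append(float(f))
            ids.append(f"amp_L{li:02d}_r{rep}")
    return lq.PeakTable(
        sample_ids=ids,
        fractions=np.array(fracs),
        intensities=np.vstack(rows),
        lines=lib,
    )


def random_regression(seed, n=30, p=8, noise=0.1):
    """A generic random (X, y) instance with a linear signal plus noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p)) * rng.uniform(0.5, 3.0, size=p) + rng.normal(size=p)
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y
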