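"""Shared fixtures: mass lists, small phantoms, constructed spectra."""

from __future__ import annotations

import numpy as np
import pytest

from abmsi import phantom as ph
from abmsi.masslist import MassListConfig, enumerate_variants, make_variant
from abmsi.spectral import ProcessingConfig

#: The 24 species reported in human plaque tissue (start, end, pyroglu).
REPORTED_PLAQUE_SPECIES = [
    # C-terminally truncated block incl. canonical full-length species
    (1, 42, False), (1, 40, False), (1, 39, False), (1, 38, False),
    (1, 37, False), (1, 36, False),
    # N-terminally truncated
    (2, 42, False), (3, 42, True), (4, 42, False), (8, 42, False),
    (10, 42, False), (11, 42, True),
    (2, 40, False), (3, 40, False), (3, 40, True), (4, 40, False),
    (5, 40, False), (7, 40, False), (8, 40, False), (9, 40, False),
    (11, 40, True),
    # bi-terminally truncated
    (2, 39, False), (2, 37, False), (9, 38, False),
]


@pytest.fixture(scope="session")
def masslist():
    return enumerate_variants(MassListConfig())


@pytest.fixture(scope="session")
def reported_variants():
    return [make_variant(s, e, p) for s, e, p in REPORTED_PLAQUE_SPECIES]


@pytest.fixture(scope="session")
def narrow_masslist():
    """Variants in a narrow window around the canonical species, for fast
    annotation tests."""
    return enumerate_variants(MassListConfig(mz_window=(3950.0, 4600.0)))


@pytest.fixture(scope="session")
def proc_cfg():
    return ProcessingConfig()


@pytest.fixture(scope="session")
def small_phantom():
    """40x40 sAD phantom with 6 plaques and 3 tangles (narrow m/z window)."""
    cfg = ph.PhantomConfig(
        group=ph.sad_group(n_plaques=6, n_tangles=3), grid=(40, 40), seed=42
    )
    dataset, truth = ph.generate_phantom(cfg)
    return cfg, dataset, truth


def gaussian_peak(mz, center, fwhm, height):
    sd = fwhm / 2.354820045
    return height * np.exp(-0.5 * ((mz - center) / sd) ** 2)
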