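"""Shared fixtures: small phantoms and helper constructors.

Phantom geometry scales with the grid, so most unit tests run on 48³
phantoms; the acceptance tests use the full 96³ study conditions.
"""

from __future__ import annotations

import numpy as np
import pytest

from lungquant import (
    ImageVolume,
    LungMask,
    MaskProvenance,
    PhantomSpec,
    Unit,
    build_phantom,
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(shape=(48, 48, 48), seed=1)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """(grey volume, truth, calibration) of a healthy 48³ phantom."""
    return build_phantom(small_spec)


@pytest.fixture(scope="session")
def small_fibrotic_phantom():
    # 64³: smallest grid whose lung depth fits lesion + halo + parenchyma rim
    spec = PhantomSpec(shape=(64, 64, 64), seed=2, lesion_fraction=0.05)
    return spec, build_phantom(spec)


def make_hu_volume(data, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    return ImageVolume(np.asarray(data, dtype=np.float64), spacing, Unit.HU)


def full_mask(vol: ImageVolume) -> LungMask:
    return LungMask(np.ones(vol.shape, dtype=bool), MaskProvenance.MANUAL,
                    vol.spacing)
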