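"""Shared fixtures: fast low-resolution phantoms for module tests.

Module tests run on coarse isotropic voxels to stay quick; resolution- and
accuracy-sensitive checks live in the acceptance suite, which uses the
clinical voxel spacings.
"""

from __future__ import annotations

import numpy as np
import pytest

from cobbmri.mask_io import LabelScheme
from cobbmri.phantom import PhantomConfig, generate_phantom

FAST_SPACING = (1.2, 1.2, 1.2)
HIGH_RES = (0.47, 0.47, 0.90)   # sagittal acquisition: fine in-plane, coarse LR
STANDARD_RES = (0.59, 0.59, 3.29)


@pytest.fixture(scope="session")
def scheme() -> LabelScheme:
    return LabelScheme.default()


@pytest.fixture(scope="session")
def flat_phantom():
    """Five flat vertebrae, no curve: truth max Cobb is 0."""
    cfg = PhantomConfig(spacing=FAST_SPACING, seed=11)
    return cfg, *generate_phantom(cfg)


@pytest.fixture(scope="session")
def curved_phantom():
    """A 18 deg single curve with apex between L2 and L4."""
    cfg = PhantomConfig.from_disc_tilts([-10.0, -3.0, 2.0, 8.0], spacing=FAST_SPACING, seed=7)
    return cfg, *generate_phantom(cfg)


def random_curve_config(
    rng: np.random.Generator,
    spacing=HIGH_RES,
    target_range=(5.0, 40.0),
    n_discs: int = 4,
    monotone: bool = False,
    **kwargs,
) -> PhantomConfig:
    """Random scoliotic curve with true max Cobb uniform in ``target_range``.

    Disc tilts are drawn freely and rescaled so the largest pairwise spread
    hits the target; the resulting curve may be C- or S-shaped.  With
    ``monotone=True`` the tilts progress monotonically cranio-caudally — the
    single C-curve morphology typical of degenerative scoliosis, where
    measuring one level off the apex pair changes the angle only gradually.
    """
    while True:
        tilts = rng.uniform(-1.0, 1.0, size=n_discs)
        spread = tilts.max() - tilts.min()
        if spread > 0.3:
            break
    if monotone:
        tilts = np.sort(tilts)
        if rng.random() < 0.5:
            tilts = tilts[::-1]
    target = rng.uniform(*target_range)
    tilts = tilts - (tilts.max() + tilts.min()) / 2  # center so |tilt| <= target/2
    tilts = tilts * (target / spread)
    kwargs.setdefault("seed", int(rng.integers(0, 2**31 - 1)))
    return PhantomConfig.from_disc_tilts(tilts.tolist(), spacing=spacing, **kwargs)
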