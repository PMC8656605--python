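"""Shared fixtures: seeded phantoms and small cohorts.

Everything is generated programmatically; no fixture data lives on disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from autoprostate import LesionSpec, PhantomSpec, generate_phantom, make_phantom_cohort


@pytest.fixture(scope="session")
def plain_phantom():
    """Lesion-free phantom at the standard in-plane resolution."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def lesion_phantom():
    """Two-lesion phantom: one CSPCa (CG), one non-significant (PZ)."""
    spec = PhantomSpec(
        lesions=(
            LesionSpec(center_mm=(4.0, 2.0, 3.0), semi_axes_mm=(5.0, 4.0, 4.0),
                       adc=0.8e-3, is_cspca=True),
            LesionSpec(center_mm=(-14.0, 0.0, -5.0), semi_axes_mm=(4.0, 3.5, 3.5),
                       adc=1.05e-3, is_cspca=False),
        ),
        seed=23,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def fine_phantom():
    """0.5 mm isotropic phantom for volume-accuracy checks."""
    spec = PhantomSpec(
        grid_shape=(96, 80, 112),
        spacing=(0.5, 0.5, 0.5),
        wp_semi_axes=(20.0, 15.0, 25.0),
        cg_semi_axes=(12.0, 9.0, 15.0),
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Six mixed positive/negative cases for detection bookkeeping."""
    return make_phantom_cohort(6, seed=101, negative_fraction=0.34)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
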