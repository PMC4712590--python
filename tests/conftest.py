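"""Shared fixtures: phantoms and a preprocessed study-sized cohort.

The cohort fixture mirrors the study conditions (15 non-sparse + 8 sparse
subjects) and is session-scoped because generating and reorienting 23
volumes dominates suite runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from rgfbreast import PhantomSpec, generate_cohort, generate_phantom, preprocess
from rgfbreast.features import cohort_feature_table

COHORT_SEED = 7


@pytest.fixture(scope="session")
def cohort():
    """23 labelled phantom volumes: 15 non-sparse, 8 sparse."""
    return generate_cohort(15, 8, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def oriented_cohort(cohort):
    """The cohort after the full resample + rotate pipeline."""
    oriented = []
    for i, (vol, _) in enumerate(cohort):
        vol.meta["subject"] = f"S{i:03d}"
        oriented.append(preprocess(vol, nipple=None))
    return oriented


@pytest.fixture(scope="session")
def cohort_table(cohort, oriented_cohort):
    """Cohort feature table: 23 subjects x 3 regions."""
    labels = [label for _, label in cohort]
    return cohort_feature_table(oriented_cohort, labels)


@pytest.fixture(scope="session")
def uniform_phantom_1mm():
    """Rotationally symmetric (circular cross-section) uniform-FT phantom at
    native 1 mm isotropic voxels."""
    spec = PhantomSpec(
        shape=(110, 124, 130),
        voxel_spacing_mm=(1.0, 1.0, 1.0),
        breast_halfaxes_mm=(45.0, 60.0, 45.0),
        ft_mode="uniform",
        ft_fraction=0.3,
        posterior_margin_mm=40.0,     # room to rotate the volume in place
        seed=5,
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
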