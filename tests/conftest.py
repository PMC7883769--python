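"""Shared fixtures: session-scoped synthetic cohorts and tables.

The expensive artifacts (phantom cohorts and their extracted feature
tables) are built once per session and shared by the unit and acceptance
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from radstruct.extraction import extract_table
from radstruct.synthetic import (
    PhantomSpec,
    PlantedTableSpec,
    gen_cohort,
    gen_planted_table,
    reduced_registry,
)

TEST_PHANTOM_SPEC = PhantomSpec(shape=(32, 32, 32), halo_axes=(11.0, 9.0, 8.0))


@pytest.fixture(scope="session")
def small_registry():
    return reduced_registry()


@pytest.fixture(scope="session")
def planted():
    """Default planted-signal table (46 subjects, 1,440 features) + truth."""
    return gen_planted_table(PlantedTableSpec(), seed=42)


@pytest.fixture(scope="session")
def phantom_subject():
    """One noise-free sharp phantom and its BraTS mask."""
    from radstruct.synthetic import gen_phantom_subject

    spec = PhantomSpec(shape=(32, 32, 32), halo_axes=(11.0, 9.0, 8.0), noise_sd=0.0)
    return gen_phantom_subject(spec, 0, seed=4)


@pytest.fixture(scope="session")
def phantom_cohort_table(small_registry):
    """Sharp-vs-diffuse phantom cohort (20+20 at 32^3) extracted to a table."""
    subjects, labels, _ = gen_cohort((20, 20), TEST_PHANTOM_SPEC, seed=9)
    return extract_table(subjects, labels, small_registry)


@pytest.fixture(scope="session")
def phantom_null_table(small_registry):
    """Cohort whose two classes share the same (diffuse) halo profile."""
    spec = PhantomSpec(
        shape=(32, 32, 32), halo_axes=(11.0, 9.0, 8.0),
        sharp_width_mm=3.0, diffuse_width_mm=3.0,
    )
    subjects, labels, _ = gen_cohort((20, 20), spec, seed=9)
    return extract_table(subjects, labels, small_registry)
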