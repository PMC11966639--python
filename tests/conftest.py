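"""Shared fixtures: synthetic geometries and their solved field sets.

Session-scoped because the harmonic solves are the expensive step; every
test treats them as read-only.
"""

import numpy as np
import pytest

import atriafiber as af
from atriafiber.pipeline import run_fibers


@pytest.fixture(scope="session")
def slab():
    return af.make_slab(af.SlabSpec())


@pytest.fixture(scope="session")
def la_dome():
    return af.make_idealized_atrium(side="la")


@pytest.fixture(scope="session")
def ra_dome():
    return af.make_idealized_atrium(side="ra")


@pytest.fixture(scope="session")
def biatrial():
    return af.make_biatrial()


@pytest.fixture(scope="session")
def la_fields(la_dome):
    return af.solve_distance_set(la_dome, "la")


@pytest.fixture(scope="session")
def ra_fields(ra_dome):
    return af.solve_distance_set(ra_dome, "ra")


@pytest.fixture(scope="session")
def bia_fields(biatrial):
    return af.solve_distance_set(biatrial, "biatrial")


@pytest.fixture(scope="session")
def la_run(la_dome):
    """(fields, bundlemap, frames, report) for the idealized left atrium."""
    return run_fibers(la_dome, "la")


@pytest.fixture(scope="session")
def ra_run(ra_dome):
    return run_fibers(ra_dome, "ra")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
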