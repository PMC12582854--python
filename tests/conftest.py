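"""Shared fixtures: demographic models and Monte-Carlo lookup tables.

The session-scoped two-locus table is the expensive shared resource; its
replicate count trades accuracy against runtime and is reused by every
estimator test.
"""

import numpy as np
import pytest

from ratemaps.demography import bottleneck_decline, equilibrium
from ratemaps.twolocus import build_two_locus_table

AYE_N = 11_695


@pytest.fixture(scope="session")
def eq_model():
    return equilibrium(AYE_N)


@pytest.fixture(scope="session")
def decline_model():
    return bottleneck_decline()


@pytest.fixture(scope="session")
def eq_table(eq_model):
    """Two-locus table, 10 haplotypes, equilibrium aye-aye size."""
    return build_two_locus_table(10, eq_model, reps=4000, seed=42)


@pytest.fixture(scope="session")
def small_table(eq_model):
    """Cheap 6-haplotype table for oracle-equivalence tests."""
    return build_two_locus_table(
        6, eq_model, grid=(0.0, 1.0, 5.0, 20.0, 100.0), reps=1500, seed=43
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
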