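"""Shared fixtures: synthetic structures generated at test time."""

import numpy as np
import pytest

from bendkit.annotation import SSERegistry
from bendkit.conformation import analyze_model
from bendkit.synthetic import make_bent_dimer, make_toy_lattice


@pytest.fixture(scope="session")
def registry():
    return SSERegistry.default()


@pytest.fixture(scope="session")
def dimer12():
    """Bent dimer with 12° ground truth and a lateral binder chain."""
    return make_bent_dimer(12.0, with_binder=True)


@pytest.fixture(scope="session")
def dimer12_analyzed(dimer12, registry):
    return analyze_model(dimer12, registry)


@pytest.fixture(scope="session")
def lattice3():
    return make_toy_lattice(3)


@pytest.fixture(scope="session")
def lattice3_analyzed(lattice3, registry):
    return analyze_model(lattice3, registry)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
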