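"""Shared fixtures: synthetic structures and maps, generated at test time."""

import numpy as np
import pytest

from foldfit import fixtures as fx


@pytest.fixture(scope="session")
def single_domain():
    """Three-helix bundle ground truth with its noiseless 3 Å map."""
    spec, truth, dmap = fx.single_domain_case(seed=0)
    return spec, truth, dmap


@pytest.fixture(scope="session")
def two_domain():
    """Standard two-bundle fixture: (spec, truth, predicted, map)."""
    return fx.two_domain_3a(seed=0)


@pytest.fixture(scope="session")
def helix12():
    """Ideal 12-residue helix model."""
    return fx.make_toy_fold(fx.FixtureSpec(topology=[("helix", 12)], seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def ca_rmsd(a, b):
    """CA r.m.s.d. between two models of identical length."""
    d = a.ca_coords() - b.ca_coords()
    return float(np.sqrt(np.nanmean(np.sum(d * d, axis=1))))
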