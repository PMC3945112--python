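"""Shared fixtures: small simulated datasets and session-scoped fits.

The expensive log-concave fits are computed once per session at reduced
problem sizes (n = 3e4 bases, K = 512 quadrature points) -- ample for the
qualitative properties the unit tests check; the acceptance tests run the
full-size configurations themselves.
"""

import numpy as np
import pytest
from hypothesis import settings

import fixcount as fc

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def small_hist():
    """Tiny hand-checkable histogram: counts [1, 1, 2] on 10 bases."""
    return fc.CountHistogram.from_levels({1: 2, 2: 1}, total_bases=10)


@pytest.fixture(scope="session")
def poisson_sim():
    """Poisson(2) counts on 3e4 bases (degenerate latent at log 2)."""
    spec = fc.LatentSpec(family="degenerate", n_bases=30000, seed=5,
                         log_rate=float(np.log(2.0)))
    counts, rates = fc.simulate(spec)
    return counts, rates, fc.histogram(counts)


@pytest.fixture(scope="session")
def gamma_sim():
    """Overdispersed gamma-latent counts: shape 0.5, scale 4 (index ~5)."""
    spec = fc.LatentSpec(family="gamma", n_bases=30000, seed=7,
                         shape=0.5, scale=4.0)
    counts, rates = fc.simulate(spec)
    return counts, rates, fc.histogram(counts)


@pytest.fixture(scope="session")
def gamma_fit(gamma_sim):
    """Log-concave fit of the gamma-latent histogram (K=512)."""
    _, _, hist = gamma_sim
    res = fc.fit_logconcave(hist, K=512)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def gamma_tmap(gamma_fit):
    """Transform map built from the gamma-latent fit (default target rate)."""
    return fc.build_transform_map(gamma_fit.density)


@pytest.fixture(scope="session")
def heavy_sim_fit():
    """Very overdispersed DNase-like data (gamma shape .25, scale 16) + fit."""
    spec = fc.LatentSpec(family="gamma", n_bases=30000, seed=8,
                         shape=0.25, scale=16.0)
    counts, _ = fc.simulate(spec)
    hist = fc.histogram(counts)
    res = fc.fit_logconcave(hist, K=512)
    return counts, hist, res
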