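"""Synthetic compound-Poisson per-base counts with known latent truth.

Every base i draws a rate r_i from a chosen latent family (optionally scaled
by a depth factor, emulating deeper sequencing of the same library) and a
count ``Poisson(r_i)``.  Families:

``degenerate(log_rate)``
    all bases share one rate -- the data are exactly Poisson;
``gamma(shape, scale)``
    rates are gamma -- the marginal counts are negative binomial with
    variance/mean = 1 + scale * depth_factor;
``lognormal(mu_ln, sigma_ln)``
    log-rates are normal;
``tabulated``
    log-rates are drawn from a gridded :class:`LogConcaveDensity` (uniform
    jitter within a grid cell).

All of these have concave latent log-densities on the log-rate axis, so the
log-concave fit is correctly specified for each and recovery can be tested
end to end.  Simulated positions sit on a single chromosome ``chrSim`` at
0..n_bases-1, with zero-count bases materialised explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts import PerBaseCounts
from .logconcave import LogConcaveDensity

__all__ = ["LatentSpec", "simulate", "simulate_dedup_degenerate", "dispersion_index"]

_FAMILIES = ("degenerate", "gamma", "lognormal", "tabulated")


@dataclass
class LatentSpec:
    """Parameters of a simulated compound-Poisson dataset."""

    family: str
    n_bases: int
    seed: int
    depth_factor: float = 1.0
    log_rate: float | None = None        # degenerate
    shape: float | None = None           # gamma
    scale: float | None = None           # gamma
    mu_ln: float | None = None           # lognormal
    sigma_ln: float | None = None        # lognormal
    density: LogConcaveDensity | None = None  # tabulated

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown latent family {self.family!r}")
        if self.n_bases < 1:
            raise ValueError("n_bases must be >= 1")
        if self.depth_factor <= 0:
            raise ValueError("depth_factor must be > 0")
        if self.family == "degenerate" and self.log_rate is None:
            raise ValueError("degenerate family needs log_rate")
        if self.family == "gamma":
            if self.shape is None or self.scale is None or self.shape <= 0 or self.scale <= 0:
                raise ValueError("gamma family needs shape > 0 and scale > 0")
        if self.family == "lognormal":
            if self.mu_ln is None or self.sigma_ln is None or self.sigma_ln <= 0:
                raise ValueError("lognormal family needs mu_ln and sigma_ln > 0")
        if self.family == "tabulated" and self.density is None:
            raise ValueError("tabulated family needs a density")


def _dense_counts(values: np.ndarray) -> PerBaseCounts:
    n = values.size
    return PerBaseCounts(np.full(n, "chrSim"),
                         np.arange(n, dtype=np.int64),
                         values.astype(np.float64), n)


def simulate(spec: LatentSpec) -> tuple[PerBaseCounts, np.ndarray]:
    """Draw per-base counts; returns ``(counts, effective_rates)``.

    ``effective_rates`` are the per-base Poisson rates after the depth
    factor, enabling latent-recovery tests.
    """
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(int(spec.seed))))
    n = spec.n_bases
    if spec.family == "degenerate":
        rates = np.full(n, np.exp(spec.log_rate))
    elif spec.family == "gamma":
        rates = rng.gamma(spec.shape, spec.scale, size=n)
    elif spec.family == "lognormal":
        rates = np.exp(rng.normal(spec.mu_ln, spec.sigma_ln, size=n))
    else:  # tabulated
        dens = spec.density
        cells = rng.choice(dens.grid.K, size=n, p=dens.weights())
        jitter = rng.uniform(-0.5, 0.5, size=n) * dens.grid.delta
        rates = np.exp(dens.grid.points[cells] + jitter)
    rates = rates * spec.depth_factor
    counts = rng.poisson(rates).astype(np.float64)
    return _dense_counts(counts), rates


def simulate_dedup_degenerate(p_nonzero: float, max_count: int, n_bases: int,
                              seed: int) -> PerBaseCounts:
    """The degenerate model under which de-duplication is the exact transform.

    Each base is nonzero with probability ``p_nonzero`` (binomial across the
    genome); a nonzero base carries a count uniform on 1..max_count, so all
    nonzero levels are equally probable.
    """
    if not 0.0 < p_nonzero < 1.0:
        raise ValueError("p_nonzero must be in (0, 1)")
    if max_count < 1:
        raise ValueError("max_count must be >= 1")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(int(seed))))
    nonzero = rng.random(n_bases) < p_nonzero
    levels = rng.integers(1, max_count + 1, size=n_bases)
    return _dense_counts(np.where(nonzero, levels, 0).astype(np.float64))


def dispersion_index(counts: PerBaseCounts) -> float:
    """Sample variance / sample mean over all bases (zeros included); 1 under Poisson."""
    n = counts.total_bases
    if n < 2:
        raise ValueError("dispersion index needs at least 2 bases")
    s1 = float(counts.value.sum())
    s2 = float(np.dot(counts.value, counts.value))
    mean = s1 / n
    if mean <= 0:
        raise ValueError("dispersion index undefined for zero mean")
    var = (s2 - n * mean * mean) / (n - 1)
    return var / mean
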