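"""Poissonization: map raw counts onto a Poisson reference by quantile.

Given a fitted latent density, the compound model's CDF evaluated at an
integer count k equals the discrete compound CDF ``P(X <= k)``.  The
transform sends k to the value t at which the *continuous extension* of the
Poisson CDF with target rate ``mu`` attains the same probability:

    t_k = F_cPois^{-1}( F_compound(k) ; mu )

where ``F_cPois(x; mu) = Q(x + 1, mu)`` is the regularised upper incomplete
gamma function (at integer x this is the ordinary Poisson CDF).  The map is
strictly increasing in k, so rank order among bases is preserved; a
downstream tool that assumes Poisson counts then sees calibrated data.

The free target rate ``mu`` defaults to the median of the fitted latent rate
distribution; any fixed choice gives an equivalent monotone re-weighting, so
``mu`` can be overridden (e.g. to put several samples on a common scale).

The probability integral transform is applied deterministically through the
continuous CDF evaluated at the integer count.  A randomized variant that
draws u uniformly from ``[F(k-1), F(k)]`` is available for completeness; the
deterministic map is the default because it is reproducible and rank
preserving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammainc, gammaincc, gammaln, logsumexp

from .counts import PerBaseCounts
from .logconcave import LogConcaveDensity

__all__ = [
    "poisson_cpdf",
    "poisson_ccdf",
    "poisson_csf",
    "poisson_cinv",
    "compound_ccdf",
    "compound_csf",
    "target_rate",
    "TransformMap",
    "build_transform_map",
    "fix_transform",
    "apply_transform",
]


def _check_mu(mu: float) -> float:
    mu = float(mu)
    if not (mu > 0 and math.isfinite(mu)):
        raise ValueError("target rate mu must be positive and finite")
    return mu


def poisson_cpdf(x, mu: float):
    """Continuous extension of the Poisson pmf: ``mu^x e^-mu / Gamma(x+1)``."""
    mu = _check_mu(mu)
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    out = np.exp(x * math.log(mu) - mu - gammaln(x + 1.0))
    return out if out.ndim else float(out)


def poisson_ccdf(x, mu: float):
    """Continuous Poisson CDF ``Q(x+1, mu)``; at integer x, ``P(N <= x)``."""
    mu = _check_mu(mu)
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    out = gammaincc(x + 1.0, mu)
    return out if out.ndim else float(out)


def poisson_csf(x, mu: float):
    """Continuous Poisson survival ``P(N > x) = P(x+1, mu)`` (lower gamma)."""
    mu = _check_mu(mu)
    x = np.asarray(x, dtype=np.float64)
    out = gammainc(x + 1.0, mu)
    return out if out.ndim else float(out)


def _invert_monotone(fun, target: float, lo: float, hi: float,
                     increasing: bool) -> float:
    """Bracketed root of ``fun(x) = target`` for a monotone fun on [lo, hi]."""
    f = (lambda x: fun(x) - target) if increasing else (lambda x: target - fun(x))
    flo, fhi = f(lo), f(hi)
    guard = 0
    while fhi < 0 and guard < 200:
        hi = 2.0 * hi + 50.0
        fhi = f(hi)
        guard += 1
    if flo > 0:
        return lo
    if fhi < 0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=300))


def poisson_cinv(u: float, mu: float) -> float:
    """Inverse of :func:`poisson_ccdf` in x for ``u in (0, 1)``.

    The continuous CDF is increasing in x with range ``(F(-1)=0, 1)``; the
    inverse is solved on ``x >= 0`` by bracketed root-finding (values of u
    below ``F(0) = e^-mu`` clamp to 0, keeping adjusted counts
    non-negative).
    """
    mu = _check_mu(mu)
    u = float(u)
    if not 0.0 < u < 1.0:
        raise ValueError("u must be in (0, 1)")
    hi = mu + 20.0 * math.sqrt(mu) + 20.0
    if u >= 0.5:
        # near 1, invert the survival function instead (better conditioning)
        s = 1.0 - u
        return _invert_monotone(lambda x: gammainc(x + 1.0, mu), s, 0.0, hi,
                                increasing=False)
    return _invert_monotone(lambda x: gammaincc(x + 1.0, mu), u, 0.0, hi,
                            increasing=True)


def _log_poisson_cinv_sf(log_s: float, mu: float) -> float:
    """Solve ``log P(N > x) = log_s`` -- the log-survival branch for u near 1."""
    hi = mu + 20.0 * math.sqrt(mu) + 20.0

    def logsf(x: float) -> float:
        s = gammainc(x + 1.0, mu)
        return math.log(s) if s > 0 else -1e30

    return _invert_monotone(logsf, log_s, 0.0, hi, increasing=False)


def _log_mix(log_w: np.ndarray, vals: np.ndarray) -> float:
    """log( sum_j w_j vals_j ) with vals in [0, 1], robust to underflow."""
    with np.errstate(divide="ignore"):
        lv = np.log(vals)
    return float(logsumexp(log_w + lv))


def compound_ccdf(x, density: LogConcaveDensity):
    """CDF of the compound (latent-mixture) model's continuous extension.

    ``F(x) = sum_j w_j Q(x+1, e^{x_j})`` with ``w`` the latent cell masses;
    at integer x this equals the discrete compound CDF.  Monotone in x and
    tends to 1.
    """
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    w = density.weights()
    rates = density.grid.rates
    out = np.array([float(w @ gammaincc(xi + 1.0, rates)) for xi in x])
    return out if np.ndim(x) and out.size > 1 else float(out[0])


def compound_csf(x, density: LogConcaveDensity):
    """Survival ``P(X > x)`` of the compound model's continuous extension."""
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    w = density.weights()
    rates = density.grid.rates
    out = np.array([float(w @ gammainc(xi + 1.0, rates)) for xi in x])
    return out if np.ndim(x) and out.size > 1 else float(out[0])


def target_rate(density: LogConcaveDensity) -> float:
    """Default transform target: the median of the latent rate distribution.

    The median log-rate is interpolated linearly within its grid cell and
    exponentiated (exp is monotone, so this is the median rate).
    """
    return math.exp(density.median())


@dataclass
class TransformMap:
    """Precomputed monotone map from raw count k to adjusted value t_k.

    Strictly increasing in k wherever the compound quantile exceeds the
    continuous Poisson CDF at 0; quantiles below that would map into
    ``(-1, 0)`` under the continuous extension and are clamped at the zero
    floor (adjusted counts are non-negative), which can tie whole low count
    levels at 0 -- exactly full de-duplication in the degenerate limit.
    """

    density: LogConcaveDensity
    mu: float
    table: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.mu = _check_mu(self.mu)
        self.table = np.asarray(self.table, dtype=np.float64)

    @property
    def k_max(self) -> int:
        return self.table.size - 1

    def extend_to(self, k_max: int) -> None:
        """Grow the k -> t_k table on demand."""
        if k_max < self.k_max:
            return
        ks = np.arange(self.table.size, k_max + 1)
        w = self.density.weights()
        log_w = self.density.g - logsumexp(self.density.g)
        rates = self.density.grid.rates
        new = np.empty(ks.size)
        hi0 = self.mu + 20.0 * math.sqrt(self.mu) + 20.0
        for i, k in enumerate(ks):
            F = float(w @ gammaincc(k + 1.0, rates))
            S = float(w @ gammainc(k + 1.0, rates))
            if S <= 1e-14:
                # deep tail: work entirely on the log-survival scale
                log_s = _log_mix(log_w, gammainc(k + 1.0, rates))
                t = _log_poisson_cinv_sf(log_s, self.mu)
            elif S < 0.5:
                t = _invert_monotone(lambda x: gammainc(x + 1.0, self.mu), S,
                                     0.0, hi0, increasing=False)
            else:
                t = _invert_monotone(lambda x: gammaincc(x + 1.0, self.mu), F,
                                     0.0, hi0, increasing=True)
            new[i] = max(t, 0.0)
        self.table = np.concatenate([self.table, new])

    def __call__(self, k):
        karr = np.atleast_1d(np.asarray(k))
        if np.any(karr < 0) or not np.allclose(karr, np.rint(karr)):
            raise ValueError("raw counts must be non-negative integers")
        ki = np.rint(karr).astype(np.int64)
        if ki.size and ki.max() > self.k_max:
            self.extend_to(int(ki.max()))
        out = self.table[ki]
        return out if np.ndim(k) else float(out[0])


def build_transform_map(density: LogConcaveDensity, mu: float | None = None,
                        k_max: int = 64) -> TransformMap:
    """Construct the count-adjustment map for a fitted latent density."""
    tmap = TransformMap(density=density,
                        mu=target_rate(density) if mu is None else mu)
    tmap.extend_to(k_max)
    return tmap


def fix_transform(k, tmap: TransformMap):
    """Adjusted value of raw count k under the map (table lookup, extending)."""
    return tmap(k)


def apply_transform(counts: PerBaseCounts, tmap: TransformMap) -> PerBaseCounts:
    """Apply the k -> t_k map positionwise; positions and order untouched.

    Only materialised positions are transformed; a position absent from the
    records has raw count 0 and implicitly maps to ``tmap(0)``.
    """
    vals = counts.value
    if vals.size and not np.allclose(vals, np.rint(vals), atol=1e-9):
        raise ValueError("transform expects raw integer counts")
    adjusted = tmap(np.rint(vals).astype(np.int64)) if vals.size else vals.copy()
    return counts.with_values(np.atleast_1d(adjusted))
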