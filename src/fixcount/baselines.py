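"""Parametric baselines and the per-level log-likelihood error diagnostic.

Maximum-likelihood fits of the classical count families -- Poisson,
negative binomial (gamma-mixed Poisson), log-normal-Poisson -- plus the
"de-duplicated Poisson" (a Poisson fit after collapsing every positive
count to 1).  The overdispersion diagnostic compares, level by level, the
empirical log-frequency with the fitted log-probability:

    e_k = log(c_k / N) - log P_model(k)            (for levels with c_k > 0)

so a perfectly fitting model has e_k = 0 everywhere and the mean per-base
error ``(1/N) sum_k c_k e_k`` equals KL(empirical || model).  Errors in the
log-likelihood propagate directly into Poisson-based test statistics, which
is what makes this the relevant scale for downstream callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln, logsumexp

from .counts import CountHistogram

__all__ = [
    "ParametricFit",
    "LoglikErrorProfile",
    "fit_poisson",
    "fit_negbin",
    "fit_lognormal_poisson",
    "fit_dedup_poisson",
    "dedup",
    "loglik_error",
]

#: size above which the negative binomial is reported as at the Poisson boundary
_NB_SIZE_CEILING = 1e8


@dataclass
class ParametricFit:
    """A fitted parametric count model."""

    family: str
    params: dict[str, float]
    loglik: float
    at_boundary: bool = False
    converged: bool = True
    _quad_points: int = field(default=61, repr=False)

    def pmf(self, k) -> np.ndarray:
        """Model probability of count level(s) k."""
        k = np.atleast_1d(np.asarray(k, dtype=np.float64))
        if self.family in ("poisson", "dedup_poisson"):
            rate = self.params["rate"]
            if rate == 0.0:
                return np.where(k == 0, 1.0, 0.0)
            return np.exp(k * math.log(rate) - rate - gammaln(k + 1.0))
        if self.family == "negbin":
            return np.exp(_nb_logpmf(k, self.params["size"], self.params["mean"]))
        if self.family == "lognormal_poisson":
            return np.exp(_lnp_logpmf(k, self.params["mu_ln"],
                                      self.params["sigma_ln"], self._quad_points))
        raise ValueError(f"unknown family {self.family!r}")


@dataclass
class LoglikErrorProfile:
    """Per-level log-likelihood errors e_k and their per-base average."""

    levels: np.ndarray
    e: np.ndarray
    mean_error: float


def _hist_loglik(hist: CountHistogram, logpmf: np.ndarray,
                 levels: np.ndarray) -> float:
    return float(hist.counts[levels] @ logpmf)


def fit_poisson(hist: CountHistogram) -> ParametricFit:
    """Poisson MLE: the rate is the per-base mean count."""
    rate = hist.mean
    ks, cs = hist.nonzero_levels()
    if rate == 0.0:
        return ParametricFit("poisson", {"rate": 0.0}, 0.0, at_boundary=True)
    k = ks.astype(np.float64)
    ll = float(cs @ (k * math.log(rate) - rate - gammaln(k + 1.0)))
    return ParametricFit("poisson", {"rate": rate}, ll)


def _nb_logpmf(k: np.ndarray, size: float, mean: float) -> np.ndarray:
    logp = math.log(size) - math.log(size + mean)
    log1mp = math.log(mean) - math.log(size + mean)
    return (gammaln(k + size) - gammaln(size) - gammaln(k + 1.0)
            + size * logp + k * log1mp)


def fit_negbin(hist: CountHistogram, restarts: int = 10,
               seed: int = 0) -> ParametricFit:
    """Negative binomial MLE in the (size, mean) parameterisation.

    The MLE of the mean is the sample mean, so only log-size is optimised
    (coarse grid plus seeded random starts, then Brent polish).  Data with
    sample variance <= mean sit at the Poisson boundary (size -> infinity)
    and are returned flagged ``at_boundary`` with the Poisson likelihood.
    Also reports the success probability ``prob = size / (size + mean)``.
    """
    m = hist.mean
    pois = fit_poisson(hist)
    if m == 0.0 or hist.variance <= m:
        params = {"size": math.inf, "mean": m, "prob": 1.0}
        return ParametricFit("negbin", params, pois.loglik, at_boundary=True)

    ks, cs = hist.nonzero_levels()
    kf = ks.astype(np.float64)

    def nll(log_size: float) -> float:
        return -float(cs @ _nb_logpmf(kf, math.exp(log_size), m))

    # method-of-moments start: var = m + m^2/size
    mom = math.log(m * m / max(hist.variance - m, 1e-12))
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(int(seed))))
    starts = np.concatenate([np.linspace(-8.0, 12.0, 21), [mom],
                             mom + rng.normal(0.0, 2.0, size=max(restarts - 1, 0))])
    best = min(starts, key=nll)
    res = minimize_scalar(nll, bounds=(best - 4.0, best + 4.0), method="bounded",
                          options={"xatol": 1e-10})
    log_size = float(res.x) if res.fun <= nll(best) else float(best)
    size = math.exp(log_size)
    ll = -nll(log_size)
    at_boundary = size >= _NB_SIZE_CEILING or ll < pois.loglik
    if at_boundary and ll < pois.loglik:
        size, ll = math.inf, pois.loglik
    params = {"size": size, "mean": m,
              "prob": 1.0 if math.isinf(size) else size / (size + m)}
    return ParametricFit("negbin", params, ll, at_boundary=at_boundary)


def _lnp_logpmf(k: np.ndarray, mu_ln: float, sigma_ln: float,
                quad_points: int = 61) -> np.ndarray:
    """Gauss-Hermite quadrature of the log-normal-Poisson marginal log-pmf."""
    h, om = np.polynomial.hermite.hermgauss(quad_points)
    x = mu_ln + math.sqrt(2.0) * sigma_ln * h          # latent log-rates
    log_w = np.log(om) - 0.5 * math.log(math.pi)
    kf = np.asarray(k, dtype=np.float64)
    logpois = np.outer(kf, x) - np.exp(x)[None, :] - gammaln(kf + 1.0)[:, None]
    return logsumexp(logpois + log_w[None, :], axis=1)


def fit_lognormal_poisson(hist: CountHistogram, restarts: int = 10,
                          quad_points: int = 61, seed: int = 0) -> ParametricFit:
    """Log-normal-Poisson MLE via quadrature and randomized multistart.

    The latent log-rate is N(mu_ln, sigma_ln^2); the marginal likelihood is
    approximated by ``quad_points`` Gauss-Hermite nodes and maximised over
    (mu_ln, log sigma_ln) by Nelder-Mead from a moment-matched start plus
    ``restarts - 1`` seeded random perturbations; the best optimum is kept.
    """
    if hist.N < 1:
        raise ValueError("histogram must contain at least one base")
    m = hist.mean
    if m == 0.0:
        return ParametricFit("lognormal_poisson",
                             {"mu_ln": -math.inf, "sigma_ln": 0.0}, 0.0,
                             at_boundary=True, _quad_points=quad_points)
    ks, cs = hist.nonzero_levels()
    kf = ks.astype(np.float64)

    def nll(theta: np.ndarray) -> float:
        mu, log_sig = theta
        sig = math.exp(min(max(log_sig, -6.0), 3.0))
        return -float(cs @ _lnp_logpmf(kf, mu, sig, quad_points))

    v = hist.variance
    sig2 = math.log1p(max(v - m, 1e-6) / (m * m))
    sig2 = max(sig2, 1e-4)
    theta0 = np.array([math.log(m) - 0.5 * sig2, 0.5 * math.log(sig2)])
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(int(seed))))
    best_theta, best_val, ok = None, math.inf, False
    for r in range(max(restarts, 1)):
        start = theta0 if r == 0 else theta0 + rng.normal(0.0, 0.5, size=2)
        res = minimize(nll, start, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if res.fun < best_val:
            best_val, best_theta, ok = float(res.fun), res.x, bool(res.success)
    mu_ln = float(best_theta[0])
    sigma_ln = float(math.exp(min(max(best_theta[1], -6.0), 3.0)))
    return ParametricFit("lognormal_poisson",
                         {"mu_ln": mu_ln, "sigma_ln": sigma_ln}, -best_val,
                         converged=ok, _quad_points=quad_points)


def dedup(hist: CountHistogram) -> CountHistogram:
    """Collapse every positive count level to 1 (read de-duplication)."""
    c0 = int(hist.counts[0])
    rest = int(hist.counts[1:].sum())
    return CountHistogram(np.array([c0, rest], dtype=np.int64))


def fit_dedup_poisson(hist: CountHistogram) -> ParametricFit:
    """Poisson fit to the de-duplicated histogram.

    The returned log-likelihood and error profile refer to the de-duplicated
    data, matching how de-duplicating pipelines actually model their input.
    """
    fit = fit_poisson(dedup(hist))
    return ParametricFit("dedup_poisson", fit.params, fit.loglik,
                         at_boundary=fit.at_boundary)


def loglik_error(hist: CountHistogram, model_pmf) -> LoglikErrorProfile:
    """Per-level error profile of a model pmf against the histogram.

    ``model_pmf`` maps an integer array of levels to probabilities (e.g.
    ``fit.pmf`` or ``lambda k: marginal_pmf(density, k)``).  A level to
    which the model assigns probability 0 is reported as ``e_k = +inf``
    rather than raising.
    """
    ks, cs = hist.nonzero_levels()
    p = np.asarray(model_pmf(ks), dtype=np.float64)
    emp = cs / hist.N
    with np.errstate(divide="ignore"):
        e = np.log(emp) - np.log(p)
    e = np.where(p > 0.0, e, np.inf)
    mean_error = float(np.dot(cs, e) / hist.N) if np.all(np.isfinite(e)) else math.inf
    return LoglikErrorProfile(levels=ks, e=e, mean_error=mean_error)
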