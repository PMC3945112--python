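"""Latent log-concave Poisson model: grid, likelihood, projection, fit.

Model
-----
Each base carries a latent log-rate ``lambda`` drawn from a distribution
whose log-density ``g`` is concave; the observed count is
``Poisson(exp(lambda))``.  The latent density is represented by its values
``g_j`` on a uniform grid of K quadrature points ``x_1 < ... < x_K`` and the
marginal log-likelihood of a count histogram ``{c_k}`` with ``N`` bases is

    L(g) = sum_k c_k * log( sum_j Pois(k | e^{x_j}) e^{g_j} )
           - N * log( sum_j e^{g_j} )

where the second term normalises the latent density (rectangle quadrature
weights cancel between the two terms, so L is invariant under adding a
constant to g).  The mixture likelihood is concave in the latent cell
masses ``w propto e^g`` -- which is what makes the estimation problem well
posed -- and the feasible set in g, sequences with non-positive second
differences, is an intersection of halfspaces.  The MLE is computed by
accelerated proximal gradient ascent in g whose proximal step is Euclidean
projection onto concave sequences (concave regression); the solution
quality is validated in the tests against embedded parametric optima
(gamma and log-normal latents are themselves log-concave).

The objective depends on the data only through the distinct observed count
levels, so the cost per iteration is O(L * K) with L the number of distinct
levels, independent of genome size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .counts import CountHistogram

__all__ = [
    "LatentGrid",
    "LogConcaveDensity",
    "FitResult",
    "make_grid",
    "poisson_kernel",
    "poisson_log_kernel",
    "marginal_loglik",
    "gradient",
    "project_concave",
    "fit_logconcave",
    "marginal_pmf",
    "kernel_truncation_level",
    "save_model",
    "load_model",
]

#: tolerance on second differences accepted as "concave"
CONCAVITY_TOL = 1e-8


@dataclass(frozen=True)
class LatentGrid:
    """Uniform quadrature grid on the log-rate axis."""

    lo: float
    hi: float
    K: int

    def __post_init__(self) -> None:
        if self.K < 3:
            raise ValueError("grid needs at least 3 quadrature points")
        if not (math.isfinite(self.lo) and math.isfinite(self.hi) and self.hi > self.lo):
            raise ValueError("grid bounds must be finite with hi > lo")

    @property
    def delta(self) -> float:
        return (self.hi - self.lo) / (self.K - 1)

    @property
    def points(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.K)

    @property
    def rates(self) -> np.ndarray:
        return np.exp(self.points)


@dataclass
class LogConcaveDensity:
    """A concave log-density sampled on a :class:`LatentGrid`.

    ``g`` is pinned so that ``max_j g_j = 0`` (adding a constant changes
    nothing) and ``logZ = log(sum_j e^{g_j} * delta)`` normalises the
    rectangle-rule quadrature of ``exp(g)``.
    """

    grid: LatentGrid
    g: np.ndarray
    logZ: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=np.float64)
        if g.shape != (self.grid.K,):
            raise ValueError("g must have one value per grid point")
        if not np.all(np.isfinite(g)):
            raise ValueError("g must be finite (the grid span is the support)")
        d2 = g[:-2] - 2.0 * g[1:-1] + g[2:]
        if d2.size and d2.max() > CONCAVITY_TOL * max(1.0, np.abs(g).max()):
            raise ValueError("g is not concave within tolerance")
        g = g - g.max()
        self.g = g
        self.logZ = float(logsumexp(g) + math.log(self.grid.delta))

    def weights(self) -> np.ndarray:
        """Normalised probability mass of each grid cell."""
        return np.exp(self.g - logsumexp(self.g))

    def latent_cdf(self) -> np.ndarray:
        """CDF of the latent log-rate at the right edge of each grid cell."""
        return np.cumsum(self.weights())

    def quantile(self, q: float) -> float:
        """Latent log-rate quantile, linearly interpolated within a cell."""
        if not 0.0 < q < 1.0:
            raise ValueError("q must be in (0, 1)")
        w = self.weights()
        cum = np.cumsum(w)
        j = int(np.searchsorted(cum, q))
        j = min(j, self.grid.K - 1)
        prev = cum[j - 1] if j > 0 else 0.0
        frac = (q - prev) / max(w[j], 1e-300)
        frac = min(max(frac, 0.0), 1.0)
        x = self.grid.points[j]
        return float(x + (frac - 0.5) * self.grid.delta)

    def median(self) -> float:
        return self.quantile(0.5)

    @classmethod
    def from_log_density(cls, grid: LatentGrid, log_density) -> "LogConcaveDensity":
        """Tabulate an analytic concave log-density on the grid."""
        g = np.asarray(log_density(grid.points), dtype=np.float64)
        return cls(grid, g - g.max())

    @classmethod
    def degenerate(cls, grid: LatentGrid, log_rate: float,
                   slope: float = 40.0) -> "LogConcaveDensity":
        """A near point-mass at ``log_rate``: a concave tent with steep sides.

        The neighbours of the peak sit ``slope`` log-units lower, so their
        relative mass is ``e^-slope`` (~4e-18 at the default) -- negligible
        for every purpose while keeping g finite and concave.
        """
        x = grid.points
        j0 = int(np.argmin(np.abs(x - log_rate)))
        g = -slope * np.abs(np.arange(grid.K, dtype=np.float64) - j0)
        return cls(grid, g)


@dataclass
class FitResult:
    """Outcome of :func:`fit_logconcave`."""

    density: LogConcaveDensity
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def make_grid(hist: CountHistogram, K: int = 4096, *,
              lo: float | None = None, hi: float | None = None) -> LatentGrid:
    """Build the default quadrature grid for a histogram.

    The default span ``[log(0.5/N), log(max(k_max, 1)) + 3]`` reaches from
    rates at which less than half a read is expected anywhere in the dataset
    up to well above the largest observed count.
    """
    if hist.N < 1:
        raise ValueError("histogram must contain at least one base")
    if lo is None:
        lo = math.log(0.5 / hist.N)
    if hi is None:
        hi = math.log(max(hist.max_level, 1)) + 3.0
    return LatentGrid(float(lo), float(hi), int(K))


def kernel_truncation_level(hist: CountHistogram) -> int:
    """Count level beyond which Poisson mass is negligible for grid rates."""
    kmax = hist.max_level
    return int(kmax + math.ceil(10.0 * math.sqrt(max(kmax, 1))))


def poisson_log_kernel(levels: np.ndarray, grid: LatentGrid) -> np.ndarray:
    """``log Pois(k | e^{x_j})`` for the given count levels (rows) and grid."""
    k = np.asarray(levels, dtype=np.float64)
    x = grid.points
    lam = np.exp(x)
    return np.outer(k, x) - lam[None, :] - gammaln(k + 1.0)[:, None]


def poisson_kernel(hist: CountHistogram, grid: LatentGrid,
                   levels: np.ndarray | None = None) -> np.ndarray:
    """Poisson kernel matrix ``P[k][j] = Pois(k | e^{x_j})``.

    Rows run over ``levels`` (default: 0 .. max observed level); computed in
    log space to avoid underflow.
    """
    if levels is None:
        levels = np.arange(hist.max_level + 1)
    return np.exp(poisson_log_kernel(levels, grid))


def _check_g(g: np.ndarray, grid: LatentGrid) -> np.ndarray:
    g = np.asarray(g, dtype=np.float64)
    if g.shape != (grid.K,):
        raise ValueError("g must have one value per grid point")
    if not np.all(np.isfinite(g)):
        raise ValueError("g must be finite")
    return g


def marginal_loglik(g: np.ndarray, grid: LatentGrid, hist: CountHistogram) -> float:
    """Marginal log-likelihood ``L(g)`` of the histogram (see module docstring)."""
    g = _check_g(g, grid)
    ks, cs = hist.nonzero_levels()
    logP = poisson_log_kernel(ks, grid)
    mix = logsumexp(logP + g[None, :], axis=1)
    return float(cs @ mix - hist.N * logsumexp(g))


def gradient(g: np.ndarray, grid: LatentGrid, hist: CountHistogram) -> np.ndarray:
    """Gradient of :func:`marginal_loglik` in ``g``.

    Component j is the expected number of bases whose latent log-rate falls
    in cell j under the count-conditional posterior, minus the same
    expectation under the latent density alone; the components sum to zero.
    """
    g = _check_g(g, grid)
    ks, cs = hist.nonzero_levels()
    logP = poisson_log_kernel(ks, grid)
    A = logP + g[None, :]
    A -= logsumexp(A, axis=1, keepdims=True)
    post = cs @ np.exp(A)
    prior = hist.N * np.exp(g - logsumexp(g))
    return post - prior


# ---------------------------------------------------------------------------
# projection onto concave sequences (concave regression)
# ---------------------------------------------------------------------------

def _second_diff(u: np.ndarray) -> np.ndarray:
    return u[:-2] - 2.0 * u[1:-1] + u[2:]


def _apply_Dt(lam: np.ndarray, n: int) -> np.ndarray:
    """Adjoint of the second-difference operator."""
    out = np.zeros(n)
    out[:-2] += lam
    out[1:-1] -= 2.0 * lam
    out[2:] += lam
    return out


def _solve_active_banded(idx: np.ndarray, winv: np.ndarray,
                         rhs: np.ndarray) -> np.ndarray:
    """Solve ``(D W^-1 D^T)[idx, idx] mu = rhs`` exploiting bandedness.

    Rows i, i' of the second-difference operator D interact only when
    ``|i - i'| <= 2``, so in the sorted active ordering the Gram matrix is
    symmetric positive definite with bandwidth 2.
    """
    from scipy.linalg import solveh_banded

    m = idx.size
    ab = np.zeros((3, m))
    ab[0] = winv[idx] + 4.0 * winv[idx + 1] + winv[idx + 2]
    if m >= 2:
        gap = idx[1:] - idx[:-1]
        b1 = np.zeros(m - 1)
        m1 = gap == 1
        i1 = idx[:-1][m1]
        b1[m1] = -2.0 * winv[i1 + 1] - 2.0 * winv[i1 + 2]
        m2 = gap == 2
        b1[m2] = winv[idx[:-1][m2] + 2]
        ab[1, : m - 1] = b1
    if m >= 3:
        gap2 = idx[2:] - idx[:-2]
        b2 = np.zeros(m - 2)
        mg = gap2 == 2
        b2[mg] = winv[idx[:-2][mg] + 2]
        ab[2, : m - 2] = b2
    return solveh_banded(ab, rhs, lower=True)


def _pdas(v: np.ndarray, winv: np.ndarray, active: np.ndarray,
          feas_tol: float, max_rounds: int = 60):
    """Primal-dual active-set pass over the tight-constraint set.

    Solves the projection exactly on a candidate set of tight constraints
    (banded Cholesky), then swaps constraints in/out until the KKT
    conditions hold; cheap whenever the tight set is close to correct, but
    not guaranteed to settle, so callers must be ready for ``ok=False``.
    Returns ``(ok, u, lam)``.
    """
    n = v.size
    Dv = _second_diff(v)
    u = v.copy()
    lam_full = np.zeros(n - 2)
    for _ in range(max_rounds):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            r = _second_diff(v)
            if r.max(initial=-np.inf) <= feas_tol:
                return True, v.copy(), np.zeros(n - 2)
            active[r > feas_tol] = True
            continue
        try:
            mu = _solve_active_banded(idx, winv, Dv[idx])
        except np.linalg.LinAlgError:  # pragma: no cover - D_A has full rank
            return False, u, lam_full
        lam_full = np.zeros(n - 2)
        lam_full[idx] = mu
        u = v - winv * _apply_Dt(lam_full, n)
        r = _second_diff(u)
        neg = mu < -feas_tol
        viol = (~active) & (r > feas_tol)
        if not neg.any() and not viol.any():
            np.clip(lam_full, 0.0, None, out=lam_full)
            return True, u, lam_full
        active[idx[neg]] = False
        active[viol] = True
    return False, u, lam_full


def _hinge_ls(v: np.ndarray, sqrt_w: np.ndarray | None,
              knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of an affine part plus negative hinges at ``knots``.

    Column m is ``-(j - m)_+``; the fit is the best piecewise-linear
    sequence with those knots.  Returns ``(theta, u)`` where theta holds
    (intercept, slope, hinge coefficients).
    """
    n = v.size
    j = np.arange(n, dtype=np.float64)
    B = np.empty((n, 2 + knots.size))
    B[:, 0] = 1.0
    B[:, 1] = j
    if knots.size:
        B[:, 2:] = -np.maximum(j[:, None] - knots[None, :], 0.0)
    if sqrt_w is not None:
        theta, *_ = np.linalg.lstsq(B * sqrt_w[:, None], v * sqrt_w, rcond=None)
    else:
        theta, *_ = np.linalg.lstsq(B, v, rcond=None)
    return theta, B @ theta


def _hinge_duals(resid_w: np.ndarray) -> np.ndarray:
    """Gradients ``h_m^T W (v - u)`` of the objective in each hinge direction.

    ``d_m = -sum_{j > m} (j - m) resid_j`` for interior knots m = 1..n-2,
    computed with two reverse cumulative sums.
    """
    n = resid_w.size
    j = np.arange(n, dtype=np.float64)
    t0 = np.concatenate([np.cumsum(resid_w[::-1])[::-1], [0.0]])
    t1 = np.concatenate([np.cumsum((j * resid_w)[::-1])[::-1], [0.0]])
    m = np.arange(1, n - 1, dtype=np.float64)
    return -(t1[2:n] - m * t0[2:n])


def _lawson_hanson_hinge(v: np.ndarray, sqrt_w: np.ndarray | None,
                         wvec: np.ndarray | None, scale: float,
                         max_knots: int, P: np.ndarray):
    """Exact projection via non-negative least squares in the hinge basis.

    A concave sequence is an affine part plus a non-negative combination of
    negative hinges ``-(j - m)_+``, so the projection is an NNLS problem
    over the hinge coefficients (affine part free), solved by the classic
    Lawson-Hanson active-set method; the working set is the knot set of the
    piecewise-linear solution.  Efficient only while that set stays small,
    so the search aborts (``ok=False``) once it exceeds ``max_knots``.
    Feasibility of the result is automatic: the solution's second
    differences are the negated hinge coefficients.
    """
    n = v.size
    dual_tol = 1e-11 * scale * n * n
    theta, u = _hinge_ls(v, sqrt_w, P)
    x = theta[2:]
    guard = 0
    while P.size and x.size and x.min() < 0.0 and guard <= n:
        keep = x > 0.0
        P = P[keep]
        theta, u = _hinge_ls(v, sqrt_w, P)
        x = theta[2:]
        guard += 1

    for _ in range(4 * max_knots + 20):
        if P.size > max_knots:
            return False, u, P
        resid = v - u if wvec is None else wvec * (v - u)
        d = _hinge_duals(resid)
        if P.size:
            d[P - 1] = -np.inf
        m_new = int(np.argmax(d)) + 1
        if d[m_new - 1] <= dual_tol:
            return True, u, P  # KKT satisfied
        ins = int(np.searchsorted(P, m_new))
        P = np.insert(P, ins, m_new)
        x = np.insert(x, ins, 0.0)
        # inner loop: step toward the working-set solution, backing off to
        # the boundary and dropping hinges that hit zero
        for _inner in range(n):
            theta_new, u_new = _hinge_ls(v, sqrt_w, P)
            xn = theta_new[2:]
            if not xn.size or xn.min() >= 0.0:
                x, u = xn, u_new
                break
            neg = xn < 0.0
            alpha = float(np.min(x[neg] / (x[neg] - xn[neg])))
            x = x + alpha * (xn - x)
            drop = x <= 1e-13 * scale
            drop[np.flatnonzero(neg)[np.argmin(x[neg])]] = True  # the blocker
            P, x = P[~drop], x[~drop]
        else:  # pragma: no cover - Lawson-Hanson terminates finitely
            return False, u, P
    return False, u, P


def _dual_qp_lbfgsb(v: np.ndarray, winv: np.ndarray, lam0: np.ndarray,
                    scale: float):
    """Refine the constraint multipliers by L-BFGS-B on the dual QP.

    The dual of the projection is ``min 0.5 lam' D W^-1 D' lam - lam' D v``
    over ``lam >= 0``; its negative gradient is the second difference of the
    current primal iterate, so a box-constrained quasi-Newton solve handles
    the ill-conditioning (the Gram matrix is a squared Laplacian) far better
    than first-order dual ascent.
    """
    from scipy.optimize import minimize

    n = v.size
    Dv = _second_diff(v)

    def fun_grad(lam):
        dt = _apply_Dt(lam, n)
        f = 0.5 * float(dt @ (winv * dt)) - float(lam @ Dv)
        grad = -_second_diff(v - winv * dt)
        return f, grad

    res = minimize(fun_grad, lam0, jac=True, method="L-BFGS-B",
                   bounds=[(0.0, None)] * (n - 2),
                   options={"maxiter": 200, "ftol": 1e-18,
                            "gtol": 1e-14 * scale, "maxcor": 20})
    lam = np.maximum(res.x, 0.0)
    return lam, v - winv * _apply_Dt(lam, n)


def _concave_majorant(u: np.ndarray) -> np.ndarray:
    """Least concave majorant of the sequence (emergency feasibility net)."""
    n = u.size
    hull: list[int] = []
    for j in range(n):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # keep upper hull: slope must be decreasing
            if (u[i2] - u[i1]) * (j - i2) <= (u[j] - u[i2]) * (i2 - i1):
                hull.pop()
            else:
                break
        hull.append(j)
    out = np.empty(n)
    for a, b in zip(hull[:-1], hull[1:]):
        out[a : b + 1] = np.linspace(u[a], u[b], b - a + 1)
    out[hull[-1]] = u[hull[-1]]
    return out


def project_concave(v: np.ndarray, weights: np.ndarray | None = None, *,
                    warm_start: np.ndarray | None = None,
                    return_dual: bool = False):
    """Euclidean (optionally weighted) projection onto concave sequences.

    Minimises ``sum_j w_j (u_j - v_j)^2`` subject to
    ``u_{j+1} - 2 u_j + u_{j-1} <= 0`` for all interior j (concave
    regression).  Solved exactly by complementary active-set strategies,
    tried in order of expected cost:

    1. a primal-dual active-set pass over the *tight constraints* (banded
       Cholesky solves) -- cheap when few constraints bind or a warm start
       is close;
    2. L-BFGS-B on the box-constrained dual followed by another active-set
       pass -- handles ill-conditioned intermediate cases;
    3. Lawson-Hanson NNLS in the *hinge basis*, whose working set is the
       (usually small) knot set of the piecewise-linear solution;
    4. as a last resort, the least concave majorant of the best iterate,
       which is always feasible.

    The returned vector satisfies the constraints to ~1e-9 relative and is
    a fixed point on concave inputs.

    Parameters
    ----------
    warm_start
        Constraint multipliers returned by a previous call on a nearby
        vector; their support seeds the active set.
    return_dual
        Also return the multiplier vector for warm-starting the next call.
    """
    v = np.ascontiguousarray(v, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError("v must be 1-d")
    if not np.all(np.isfinite(v)):
        raise ValueError("v must be finite")
    n = v.size
    if n < 3:
        u = v.copy()
        return (u, np.zeros(0)) if return_dual else u
    if weights is None:
        wvec = None
        sqrt_w = None
        winv = np.ones(n)
    else:
        wvec = np.asarray(weights, dtype=np.float64)
        if wvec.shape != v.shape or np.any(wvec <= 0) or not np.all(np.isfinite(wvec)):
            raise ValueError("weights must be positive, finite, same shape as v")
        sqrt_w = np.sqrt(wvec)
        winv = 1.0 / wvec

    scale = max(1.0, float(np.abs(v).max()))
    feas_tol = 1e-12 * scale
    r0 = _second_diff(v)
    if r0.max(initial=-np.inf) <= feas_tol:  # already concave
        u = v.copy()
        return (u, np.zeros(n - 2)) if return_dual else u

    if warm_start is not None and np.size(warm_start) == n - 2:
        lam = np.maximum(np.asarray(warm_start, dtype=np.float64), 0.0)
    else:
        lam = np.zeros(n - 2)

    active = (lam > 1e-9 * scale) | (r0 > feas_tol)
    if active.sum() > 0.5 * n:  # distrust bloated warm starts
        active = r0 > feas_tol
    ok, u, lam_out = _pdas(v, winv, active, feas_tol)
    if not ok:
        lam_ref, u_ref = _dual_qp_lbfgsb(v, winv, lam, scale)
        r = _second_diff(u_ref)
        active = (lam_ref > 1e-9 * scale) | (r > -1e-7 * scale)
        ok, u, lam_out = _pdas(v, winv, active, feas_tol, max_rounds=120)
        if not ok:
            knots0 = np.flatnonzero(r < -1e-7 * scale) + 1
            hinge_ok, u_h = False, None
            if knots0.size <= 300:  # hinge basis pays off only for few knots
                hinge_ok, u_h, _ = _lawson_hanson_hinge(
                    v, sqrt_w, wvec, scale, 2 * knots0.size + 40, knots0)
            if hinge_ok:
                u = u_h
                lam_out = np.zeros(n - 2)  # multipliers unknown on this path
            else:
                # feasible, near-optimal fallback
                cand = [u_ref] if u_h is None else [u_ref, u_h]
                best = min(cand, key=lambda uu: float(
                    np.sum(((uu - v) ** 2) if wvec is None
                           else wvec * (uu - v) ** 2)))
                u = _concave_majorant(best)
                lam_out = np.zeros(n - 2)  # do not poison later warm starts

    return (u, lam_out) if return_dual else u


# ---------------------------------------------------------------------------
# maximum-likelihood fit
# ---------------------------------------------------------------------------

def _default_init(hist: CountHistogram, grid: LatentGrid) -> np.ndarray:
    """Moment-matched Gaussian (in log-rate) starting point; always concave."""
    x = grid.points
    m = hist.mean
    if m <= 0:
        return -2.0 * (x - grid.lo)
    v = hist.variance
    sig2 = math.log1p(max(v - m, 0.0) / (m * m)) if m > 0 else 0.0
    sig2 = max(sig2, 1e-2)
    center = math.log(m) - 0.5 * sig2
    return -0.5 * (x - center) ** 2 / sig2


def _g_from_hinge(theta: np.ndarray, n: int) -> np.ndarray:
    """Assemble ``g = a + b*j - sum_m theta_m (j - m)_+`` in O(n)."""
    a, b = theta[0], theta[1]
    cuts = np.zeros(n - 1)
    cuts[1:] = theta[2:]                  # kink at m lowers slopes beyond m
    slopes = b - np.cumsum(cuts)
    g = np.empty(n)
    g[0] = a
    g[1:] = a + np.cumsum(slopes)
    return g


def _warm_start_hinge(hist: CountHistogram, grid: LatentGrid,
                      logP: np.ndarray, cN: np.ndarray,
                      g0: np.ndarray) -> np.ndarray:
    """Near-optimal concave starting point by quasi-Newton in hinge space.

    In the hinge parameterisation (intercept, slope, kink magnitudes
    ``theta_m >= 0``) every feasible point is concave, so the MLE becomes a
    box-constrained smooth concave programme that L-BFGS-B handles without
    any projections; the subsequent proximal-gradient refinement then only
    ever sees mildly infeasible steps.
    """
    from scipy.optimize import minimize

    n = grid.K
    j = np.arange(n, dtype=np.float64)
    # precondition: normalise basis columns so L-BFGS-B sees balanced
    # curvature (hinge column norms grow like (n - m)^{3/2})
    m = np.arange(1, n - 1, dtype=np.float64)
    col_scale = np.concatenate([[math.sqrt(n), math.sqrt(float(j @ j))],
                                np.sqrt((n - m) ** 3 / 3.0)])

    def neg_obj_grad(phi):
        g = _g_from_hinge(phi * col_scale, n)
        A = logP + g[None, :]
        lse = logsumexp(A, axis=1)
        post = cN @ np.exp(A - lse[:, None])
        lg = logsumexp(g)
        grad_g = post - np.exp(g - lg)
        f = float(cN @ lse - lg)
        gr = np.empty(n)
        gr[0] = grad_g.sum()
        gr[1] = float(j @ grad_g)
        gr[2:] = _hinge_duals(grad_g)
        return -f, -(gr * col_scale)

    theta0 = np.zeros(n)
    theta0[0] = g0[0]
    theta0[1] = g0[1] - g0[0]
    theta0[2:] = np.maximum(-_second_diff(g0), 0.0)
    phi = theta0 / col_scale
    bounds = [(None, None), (None, None)] + [(0.0, None)] * (n - 2)
    prev = math.inf
    for _ in range(4):  # fresh curvature memory often escapes stalls
        res = minimize(neg_obj_grad, phi, jac=True, method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": 600, "ftol": 1e-16, "gtol": 1e-12,
                                "maxcor": 25})
        phi = np.asarray(res.x)
        if prev - float(res.fun) < 1e-8:
            break
        prev = float(res.fun)
    g = _g_from_hinge(phi * col_scale, n)
    return g - g.max()


def fit_logconcave(hist: CountHistogram, grid: LatentGrid | None = None, *,
                   K: int = 4096, max_iter: int = 2000, obj_tol: float = 1e-8,
                   g_tol: float = 1e-8, window: int = 50,
                   g0: np.ndarray | None = None) -> FitResult:
    """Maximum-likelihood latent log-concave density for a count histogram.

    Accelerated proximal gradient ascent (monotone Nesterov scheme with
    backtracking line search and adaptive restart); the proximal operator is
    :func:`project_concave`.  The run is deterministic: repeated calls with
    the same inputs return bit-identical densities.

    Convergence is judged over a trailing ``window`` of iterations, because
    per-iteration objective changes on this problem can be tiny long before
    the iterate has stopped moving: the fit stops when the mean per-base
    objective gain per iteration over the window falls below ``obj_tol``, or
    when the iterate has moved less than ``g_tol`` in sup-norm over the
    window.  Otherwise ``converged=False`` is returned (not an exception)
    after ``max_iter`` iterations.
    """
    if hist.N < 1:
        raise ValueError("histogram must contain at least one base")
    if grid is None:
        grid = make_grid(hist, K=K)

    ks, cs = hist.nonzero_levels()
    logP = poisson_log_kernel(ks, grid)
    cN = cs.astype(np.float64) / hist.N
    N = float(hist.N)

    def objective(g: np.ndarray) -> float:
        # per-base marginal log-likelihood
        mix = logsumexp(logP + g[None, :], axis=1)
        return float(cN @ mix - logsumexp(g))

    def obj_and_grad(g: np.ndarray):
        A = logP + g[None, :]
        lse = logsumexp(A, axis=1)
        post = cN @ np.exp(A - lse[:, None])
        lg = logsumexp(g)
        prior = np.exp(g - lg)
        return float(cN @ lse - lg), post - prior

    if g0 is None:
        g0 = _warm_start_hinge(hist, grid, logP, cN, _default_init(hist, grid))
    g = project_concave(g0)
    g -= g.max()
    z = g.copy()                 # monotone (best) iterate
    z_prev = g.copy()
    f_z = objective(z)
    y = g.copy()
    t = 1.0
    step = 4.0
    lam_warm: np.ndarray | None = None
    trace = [f_z]
    converged = False
    n_iter = 0
    z_snapshot = z.copy()   # iterate one window ago

    for n_iter in range(1, max_iter + 1):
        f_y, gr = obj_and_grad(y)
        s = step
        cand = z
        f_c = f_z
        while True:
            cand, lam_warm = project_concave(y + s * gr, warm_start=lam_warm,
                                             return_dual=True)
            cand = cand - cand.max()
            f_c = objective(cand)
            d = cand - y
            if f_c >= f_y + gr @ d - (0.5 / s) * (d @ d) - 1e-13 * max(1.0, abs(f_y)):
                break
            s *= 0.5
            if s < 1e-14:
                cand, f_c = z.copy(), f_z
                break
        step = min(s * 1.25, 1e4)

        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t * t))
        z_prev = z
        if f_c >= f_z:
            z, f_z = cand, f_c
        # monotone-FISTA momentum step
        y = z + (t / t_new) * (cand - z) + ((t - 1.0) / t_new) * (z - z_prev)
        t = t_new
        trace.append(f_z)

        if n_iter % window == 0:
            gain = (f_z - trace[n_iter - window]) / window
            moved = float(np.abs(z - z_snapshot).max())
            z_snapshot = z.copy()
            if gain < obj_tol * max(1.0, abs(f_z)) or moved < g_tol:
                converged = True
                break

    g_final = project_concave(z)
    g_final -= g_final.max()
    density = LogConcaveDensity(grid, g_final)
    return FitResult(density=density,
                     loglik_trace=np.asarray(trace) * N,
                     converged=converged, n_iter=n_iter)


def marginal_pmf(density: LogConcaveDensity, k) -> np.ndarray | float:
    """Marginal probability of observing count ``k`` under the fitted model."""
    karr = np.atleast_1d(np.asarray(k))
    if np.any(karr < 0) or not np.allclose(karr, np.rint(karr)):
        raise ValueError("k must be a non-negative integer")
    logP = poisson_log_kernel(karr.astype(np.float64), density.grid)
    lg = logsumexp(density.g)
    out = np.exp(logsumexp(logP + density.g[None, :], axis=1) - lg)
    return out if np.ndim(k) else float(out[0])


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def save_model(density: LogConcaveDensity, path, meta: dict | None = None) -> None:
    """Serialise a fitted density as JSON, loadable without refitting."""
    payload = {
        "grid": {"lo": density.grid.lo, "hi": density.grid.hi, "K": density.grid.K},
        "g": [float(x) for x in density.g],
        "logZ": density.logZ,
        "meta": meta or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)
        fh.write("\n")


def load_model(path) -> tuple[LogConcaveDensity, dict]:
    with open(path) as fh:
        payload = json.load(fh)
    grid = LatentGrid(payload["grid"]["lo"], payload["grid"]["hi"],
                      payload["grid"]["K"])
    density = LogConcaveDensity(grid, np.asarray(payload["g"], dtype=np.float64))
    return density, payload.get("meta", {})
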