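"""Smoothed age-specific hazard estimation via penalized Poisson B-splines.

The hazard is estimated from binned occurrence/exposure data: deaths ``d_j``
and person-time ``R_j`` per age bin. Conditionally on exposure, ``d_j`` is
modelled as Poisson with mean ``R_j * h_j`` and the log hazard expanded in a
uniform B-spline basis with a difference penalty on the coefficients
(a P-spline). The penalized log-likelihood

    sum_j [ d_j * log(R_j h_j) - R_j h_j ]  -  (lambda / 2) * || D_p theta ||^2

is maximized by penalized iteratively reweighted least squares. The
smoothing parameter can be fixed or selected by the variance-component
(mixed-model) iteration in which the penalized coefficients are treated as
random effects with variance ``phi / lambda``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .datasets import CohortTable

__all__ = [
    "ExposureTable",
    "HazardCurve",
    "SmootherSettings",
    "bin_exposure",
    "bspline_basis",
    "fit_smoothed_hazard",
    "select_smoothing",
]


class FitError(RuntimeError):
    """The penalized likelihood fit could not be completed."""


@dataclass(frozen=True)
class SmootherSettings:
    """Settings of the hazard smoother, shared across analyses.

    ``bin_width_days`` sets the occurrence/exposure binning (30 days matches
    the monthly scale of the data); ``n_knots`` is the number of interior
    knots of the uniform cubic B-spline basis; ``penalty_order`` the order of
    the difference penalty (2 shrinks toward a Gompertz, i.e. log-linear,
    hazard); ``lam`` is either a positive smoothing parameter or ``"auto"``
    for variance-component selection.
    """

    bin_width_days: float = 30.0
    n_knots: int = 12
    degree: int = 3
    penalty_order: int = 2
    lam: float | str = "auto"


@dataclass
class ExposureTable:
    """Binned events and person-time — the smoother's sufficient statistic."""

    bin_edges: np.ndarray  # length J+1, increasing
    events: np.ndarray  # d_j, ints, length J
    persontime: np.ndarray  # R_j, animal-days, length J
    n_animals: int = 0
    entry_age: float = 0.0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.events = np.asarray(self.events, dtype=float)
        self.persontime = np.asarray(self.persontime, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if len(self.events) != len(self.bin_edges) - 1 or len(self.persontime) != len(self.events):
            raise ValueError("events and persontime must have one entry per bin")
        if np.any((self.persontime == 0) & (self.events > 0)):
            raise ValueError("a bin with zero person-time cannot contain events")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


@dataclass
class HazardCurve:
    """A smoothed hazard on a daily age grid with pointwise 95% CIs."""

    age_grid: np.ndarray
    hazard: np.ndarray  # per day
    se_log_hazard: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    lam: float
    effective_df: float
    n_events: int
    n_animals: int
    # spline internals, kept so the curve can be re-evaluated elsewhere
    knots: np.ndarray = field(default=None, repr=False)
    degree: int = 3
    coef: np.ndarray = field(default=None, repr=False)

    def __call__(self, ages) -> np.ndarray:
        """Evaluate the fitted hazard at arbitrary ages within the knot span."""
        B = _design(np.asarray(ages, dtype=float), self.knots, self.degree)
        return np.exp(B @ self.coef)


# ---------------------------------------------------------------------------
# exposure binning


def bin_exposure(cohort: CohortTable, bin_width_days: float = 30.0,
                 entry_age: float | None = None,
                 bin_edges: np.ndarray | None = None) -> ExposureTable:
    """Aggregate a cohort into per-age-bin death counts and person-time.

    Each animal contributes person-time equal to the overlap of
    ``(entry_age, age_days]`` with each bin (animals enter observation at
    weaning: left truncation). A death increments the count of the bin
    containing its age; bins are half-open ``[e_j, e_{j+1})`` except the
    last, which is closed.
    """
    if bin_edges is None and not bin_width_days > 0:
        raise ValueError("bin_width_days must be positive")
    if entry_age is None:
        entry_age = cohort.weaning_age_days
    ages = cohort.table["age_days"].to_numpy(dtype=float)
    died = (cohort.table["status"] == "died").to_numpy()
    if np.any(ages < entry_age):
        raise ValueError("all ages must be at or after the entry age")

    if bin_edges is None:
        top = float(ages.max())
        edges = np.arange(entry_age, top, bin_width_days)
        edges = np.append(edges, edges[-1] + bin_width_days)  # last bin covers the max age
    else:
        edges = np.asarray(bin_edges, dtype=float)
        if float(ages.max()) > edges[-1]:
            raise ValueError("bin_edges must cover the largest observed age")

    # person-time: overlap of (entry, age] with [e_j, e_{j+1})
    lo = np.maximum(entry_age, edges[:-1][None, :])
    hi = np.minimum(ages[:, None], edges[1:][None, :])
    persontime = np.clip(hi - lo, 0.0, None).sum(axis=0)

    idx = np.searchsorted(edges, ages[died], side="right") - 1
    idx = np.minimum(idx, len(edges) - 2)  # deaths at the top edge: last bin is closed
    events = np.bincount(idx, minlength=len(edges) - 1).astype(float)

    return ExposureTable(bin_edges=edges, events=events, persontime=persontime,
                         n_animals=len(ages), entry_age=float(entry_age))


# ---------------------------------------------------------------------------
# B-spline basis (uniform, unclamped — the P-spline convention)


def _uniform_knots(lo: float, hi: float, n_knots: int, degree: int) -> np.ndarray:
    """Equally spaced knots with ``n_knots`` interior knots and ``degree``
    extension knots beyond each boundary (same spacing throughout, so the
    difference penalty's null space is exactly the low-order polynomials)."""
    if n_knots < 0:
        raise ValueError("n_knots must be non-negative")
    h = (hi - lo) / (n_knots + 1)
    return lo + h * np.arange(-degree, n_knots + 2 + degree)


def _design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo, hi = knots[degree], knots[len(knots) - degree - 1]
    if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
        raise ValueError("evaluation points outside the knot span")
    x = np.clip(x, lo, np.nextafter(hi, lo) if degree == 0 else hi)
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def bspline_basis(age_grid: np.ndarray, n_knots: int, degree: int,
                  lo: float | None = None, hi: float | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform B-spline design matrix over ``[lo, hi]`` (defaults to the grid
    range). Returns ``(matrix, knots)``; rows sum to one (partition of
    unity) and every basis function is non-negative with local support.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    age_grid = np.asarray(age_grid, dtype=float)
    lo = float(age_grid.min()) if lo is None else lo
    hi = float(age_grid.max()) if hi is None else hi
    knots = _uniform_knots(lo, hi, n_knots, degree)
    return _design(age_grid, knots, degree), knots


def _difference_matrix(k: int, order: int) -> np.ndarray:
    D = np.eye(k)
    for _ in range(order):
        D = np.diff(D, axis=0)
    return D


# ---------------------------------------------------------------------------
# penalized Poisson fit


def _pirls(B: np.ndarray, d: np.ndarray, R: np.ndarray, lam: float,
           P: np.ndarray, tol: float = 1e-8, max_iter: int = 100,
           theta0: np.ndarray | None = None
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Penalized IRLS for the Poisson log-link model with offset log R.

    Returns ``(theta, C, W)`` where ``C = (B'WB + lam P)^-1`` is the
    penalized-information covariance of the coefficients (for phi = 1) and
    ``W`` the final working weights (the fitted Poisson means).
    ``theta0`` warm-starts the iteration.
    """
    if theta0 is not None:
        theta = theta0.copy()
    else:
        rate0 = max(d.sum(), 0.5) / R.sum()
        theta = np.full(B.shape[1], np.log(rate0))

    def penalized_ll(th):
        eta = np.clip(B @ th, -300.0, 300.0)
        return float(d @ eta - R @ np.exp(eta) - 0.5 * lam * (th @ P @ th))

    ll = penalized_ll(theta)
    trace = []
    for it in range(max_iter):
        eta = B @ theta
        mu = R * np.exp(np.clip(eta, -300.0, 300.0))
        W = mu
        z = eta + (d - mu) / np.maximum(mu, 1e-300)
        BtW = B.T * W
        A = BtW @ B + lam * P
        try:
            theta_new = np.linalg.solve(A, BtW @ z)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise FitError(f"singular penalized system at iteration {it}") from exc
        # step-halving: IRLS can overshoot on sparse bins
        ll_new = penalized_ll(theta_new)
        halvings = 0
        while ll_new < ll - 1e-10 and halvings < 30:
            theta_new = 0.5 * (theta + theta_new)
            ll_new = penalized_ll(theta_new)
            halvings += 1
        ll_gain = ll_new - ll
        ll = ll_new
        delta = float(np.max(np.abs(theta_new - theta)))
        trace.append(delta)
        theta = theta_new
        if delta < tol:
            break
        # flat-likelihood plateau: coefficients in data-free regions can
        # dither without changing the fit
        if abs(ll_gain) < 1e-10 * (abs(ll) + 1.0) and delta < 1e-3:
            break
    else:
        # the iteration can plateau at float rounding level without ever
        # crossing the strict tolerance; only a genuine failure to settle
        # is an error
        if trace[-1] > 1e-4:
            raise FitError(
                f"IRLS did not converge in {max_iter} iterations; trace={trace[-5:]}")
    eta = B @ theta
    mu = R * np.exp(np.clip(eta, -300.0, 300.0))
    W = mu
    A = (B.T * W) @ B + lam * P
    C = np.linalg.inv(A)
    return theta, C, W


def _prepare(exposure: ExposureTable, n_knots: int, degree: int
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Design matrix at bin midpoints, restricted to bins with exposure."""
    keep = exposure.persontime > 0
    if exposure.n_events == 0:
        raise FitError("no events: the hazard is not estimable")
    if not np.any(keep):
        raise FitError("no bin has positive person-time")
    t = exposure.midpoints[keep]
    d = exposure.events[keep]
    R = exposure.persontime[keep]
    lo, hi = float(exposure.bin_edges[0]), float(exposure.bin_edges[-1])
    knots = _uniform_knots(lo, hi, n_knots, degree)
    B = _design(t, knots, degree)
    return B, d, R, knots, keep


def fit_smoothed_hazard(exposure: ExposureTable, lam: float | str = "auto",
                        n_knots: int = 12, degree: int = 3,
                        penalty_order: int = 2, phi: float | str = 1.0,
                        grid_step_days: float = 1.0) -> HazardCurve:
    """Fit the penalized Poisson B-spline hazard and return a daily curve.

    ``lam="auto"`` selects the smoothing parameter by the variance-component
    iteration of :func:`select_smoothing`. Pointwise 95% confidence
    intervals are ``exp(log h_hat +/- 1.96 se)`` with the standard error
    from the penalized-information covariance of the linear predictor.
    ``phi`` is the overdispersion: fixed at 1 by default, or ``"pearson"``
    to estimate it from the Pearson statistic of an initial fit.
    """
    if lam == "auto":
        lam, _ = select_smoothing(exposure, n_knots=n_knots, degree=degree,
                                  penalty_order=penalty_order, phi=phi)
    lam = float(lam)
    if lam < 0:
        raise ValueError("lam must be non-negative")

    B, d, R, knots, _ = _prepare(exposure, n_knots, degree)
    # lam = 0 needs no penalty matrix (and permits a one-basis fit)
    P = (np.zeros((B.shape[1],) * 2) if lam == 0.0
         else _penalty(B.shape[1], penalty_order))
    theta, C, W = _pirls(B, d, R, lam, P)

    phi_val = _resolve_phi(phi, B, d, R, theta, W, lam, P)

    edf = float(np.trace(C @ ((B.T * W) @ B)))

    lo, hi = float(exposure.bin_edges[0]), float(exposure.bin_edges[-1])
    grid = np.arange(lo, hi + 0.5 * grid_step_days, grid_step_days)
    Bg = _design(grid, knots, degree)
    eta = Bg @ theta
    se = np.sqrt(np.maximum(phi_val * np.einsum("ij,jk,ik->i", Bg, C, Bg), 0.0))
    h = np.exp(eta)
    return HazardCurve(
        age_grid=grid,
        hazard=h,
        se_log_hazard=se,
        ci_lower=np.exp(eta - 1.96 * se),
        ci_upper=np.exp(eta + 1.96 * se),
        lam=lam,
        effective_df=edf,
        n_events=exposure.n_events,
        n_animals=exposure.n_animals,
        knots=knots,
        degree=degree,
        coef=theta,
    )


def _penalty(k: int, order: int) -> np.ndarray:
    if order < 1 or order >= k:
        raise ValueError("penalty_order must be in [1, n_basis)")
    D = _difference_matrix(k, order)
    return D.T @ D


def _resolve_phi(phi, B, d, R, theta, W, lam, P) -> float:
    if phi == "pearson":
        mu = R * np.exp(B @ theta)
        C = np.linalg.inv((B.T * W) @ B + lam * P)
        edf = float(np.trace(C @ ((B.T * W) @ B)))
        dof = max(len(d) - edf, 1.0)
        return float(np.sum((d - mu) ** 2 / np.maximum(mu, 1e-300)) / dof)
    return float(phi)


def select_smoothing(exposure: ExposureTable, n_knots: int = 12, degree: int = 3,
                     penalty_order: int = 2, phi: float | str = 1.0,
                     lam_init: float = 1.0, tol: float = 1e-4,
                     max_iter: int = 50, lam_max: float = 1e8,
                     lam_min: float = 1e-8) -> tuple[float, dict]:
    """Variance-component selection of the smoothing parameter.

    The penalized coefficients are treated as random effects whose p-th
    differences have variance ``sigma^2 = phi / lambda``. Starting from
    ``lam_init`` the procedure alternates (i) a penalized fit given lambda
    with (ii) the variance update

        sigma^2 = ( ||D theta||^2 + tr(D C D') ) / rank(D),

    where ``C`` is the coefficient covariance of the current fit, until the
    relative change in lambda falls below ``tol``. Returns
    ``(lam, info)`` with the effective df and iteration diagnostics in
    ``info``; non-convergence yields a warning and the last iterate, flagged.
    """
    B, d, R, _, _ = _prepare(exposure, n_knots, degree)
    K = B.shape[1]
    D = _difference_matrix(K, penalty_order)
    P = D.T @ D
    rank = K - penalty_order

    theta_warm: np.ndarray | None = None

    def step(lam: float) -> tuple[float, np.ndarray]:
        """One variance-component update: lam -> phi / sigma^2(lam)."""
        nonlocal theta_warm
        theta, C, W = _pirls(B, d, R, lam, P, theta0=theta_warm)
        theta_warm = theta
        phi_val = _resolve_phi(phi, B, d, R, theta, W, lam, P)
        diffs = D @ theta
        sigma2 = (diffs @ diffs + np.trace(D @ (phi_val * C) @ D.T)) / rank
        return phi_val / max(sigma2, 1e-300), theta

    # Fixed-point iteration on log(lambda) with secant acceleration: solve
    # g(x) = log f(e^x) - x = 0. Plain iteration can crawl geometrically
    # when the optimum is at (or near) the lambda boundary, e.g. when the
    # true log hazard is exactly polynomial of degree < penalty_order.
    lo, hi = math.log(lam_min), math.log(lam_max)
    x_prev = math.log(max(min(lam_init, lam_max), lam_min))
    f_prev, _ = step(math.exp(x_prev))
    g_prev = math.log(f_prev) - x_prev
    history = [math.exp(x_prev), f_prev]
    converged = False
    x = min(max(math.log(f_prev), lo), hi)
    for _ in range(max_iter):
        f_x, _ = step(math.exp(x))
        g = math.log(f_x) - x
        history.append(f_x)
        if abs(g) <= tol or abs(math.exp(g) - 1.0) <= tol:
            converged = True
            break
        if (x >= hi and g > 0) or (x <= lo and g < 0):
            converged = True  # boundary solution: variance component pinned
            break
        if g != g_prev:
            x_new = x - g * (x - x_prev) / (g - g_prev)
        else:
            x_new = x + g
        x_prev, g_prev = x, g
        x = min(max(x_new, lo), hi)
    if not converged:
        warnings.warn(
            "smoothing-parameter iteration did not converge; returning last iterate",
            stacklevel=2,
        )
    lam = math.exp(x)
    theta, C, W = _pirls(B, d, R, lam, P, theta0=theta_warm)
    edf = float(np.trace(C @ ((B.T * W) @ B)))
    return lam, {"effective_df": edf, "converged": converged, "history": history}


def smoothed_hazard_from_cohort(cohort: CohortTable,
                                settings: SmootherSettings = SmootherSettings(),
                                bin_edges: np.ndarray | None = None) -> HazardCurve:
    """Convenience: bin a cohort and fit the smoother in one call."""
    exposure = bin_exposure(cohort, bin_width_days=settings.bin_width_days,
                            bin_edges=bin_edges)
    return fit_smoothed_hazard(exposure, lam=settings.lam, n_knots=settings.n_knots,
                               degree=settings.degree,
                               penalty_order=settings.penalty_order)
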