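"""Shared weighted least-squares estimation engine.

Both minimal models are fitted by minimising the normalised weighted
least-squares cost

    F(theta) = (z - g(theta))' W (z - g(theta)) / (z' z)

where ``z`` are the observations, ``g`` the model prediction at the sample
times, and ``W`` a diagonal weight matrix.  The scalar ``z'z`` normalisation
makes the cost dimensionless and scale-invariant; it does not move the
minimiser for a fixed ``W``.

The pipeline is: a deterministic fast-greedy initialisation (log-spaced
lattice search followed by one pass of step-halving coordinate refinement),
then a bound-constrained Levenberg-Marquardt-type trust-region descent in
log10-parameter space (which also enforces positivity), then standard
errors of the estimates by the linearisation method, reported as
per-parameter coefficients of variation (CV%).  Fits with any CV% at or
above 20% are flagged as low-quality.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import EstimationError, InitializationError, SingularityError

__all__ = [
    "WeightMode",
    "WeightSpec",
    "FitResult",
    "wls_cost",
    "fast_greedy_init",
    "greedy_candidates",
    "constrained_lm_fit",
    "linearized_cv",
    "CV_QUALITY_BAR",
]

#: CV% at or above this value marks a parameter estimate as low-quality.
CV_QUALITY_BAR = 20.0


class WeightMode(str, enum.Enum):
    CONSTANT_CV = "constant_cv"
    ABSOLUTE_SD = "absolute_sd"
    CUSTOM_DIAGONAL = "custom_diagonal"


@dataclass(frozen=True)
class WeightSpec:
    """Diagonal weights for the WLS cost.

    * ``constant_cv`` — measurement SD proportional to the observation:
      sd_i = cv * z_i, weight_i = 1/sd_i^2.
    * ``absolute_sd`` — per-sample SDs given explicitly.
    * ``custom_diagonal`` — weights given directly.
    """

    mode: WeightMode = WeightMode.CONSTANT_CV
    cv: float = 0.02
    sds: np.ndarray | None = None
    weights: np.ndarray | None = None

    def diagonal(self, z: np.ndarray) -> np.ndarray:
        """Return the strictly positive weight diagonal for observations z."""
        z = np.asarray(z, float)
        if self.mode == WeightMode.CONSTANT_CV:
            if self.cv <= 0:
                raise ValueError("constant_cv mode requires cv > 0")
            sd = self.cv * np.abs(z)
            if np.any(sd <= 0):
                raise ValueError("constant-CV weights undefined for zero observations")
            w = 1.0 / sd**2
        elif self.mode == WeightMode.ABSOLUTE_SD:
            if self.sds is None:
                raise ValueError("absolute_sd mode requires sds")
            sd = np.asarray(self.sds, float)
            if sd.shape != z.shape or np.any(sd <= 0):
                raise ValueError("sds must be positive and match z")
            w = 1.0 / sd**2
        elif self.mode == WeightMode.CUSTOM_DIAGONAL:
            if self.weights is None:
                raise ValueError("custom_diagonal mode requires weights")
            w = np.asarray(self.weights, float)
            if w.shape != z.shape:
                raise ValueError("weights must match z in length")
        else:  # pragma: no cover - closed enum
            raise ValueError(self.mode)
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weight diagonal must be strictly positive and finite")
        return w

def identity_weights(n: int) -> WeightSpec:
    """Unit diagonal weights of length n (ordinary least squares)."""
    return WeightSpec(mode=WeightMode.CUSTOM_DIAGONAL, weights=np.ones(n))


@dataclass
class FitResult:
    """Outcome of a constrained WLS fit.

    Attributes
    ----------
    theta : ndarray
        Estimates on the natural (positive) parameter scale.
    cost : float
        Normalised WLS cost at the optimum.
    cv_percent : ndarray
        Per-parameter coefficient of variation of the estimate, percent.
    covariance : ndarray
        Parameter covariance on the natural scale (linearisation method).
    n_iter : int
        Number of residual evaluations used by the descent.
    converged : bool
        Whether the descent met its gradient/step tolerances.
    cv_ok : bool
        True when every CV% is below the 20% quality bar.
    param_names : tuple of str
    message : str
    """

    theta: np.ndarray
    cost: float
    cv_percent: np.ndarray
    covariance: np.ndarray
    n_iter: int
    converged: bool
    cv_ok: bool = True
    param_names: tuple = ()
    message: str = ""


def wls_cost(theta, z, g, w: WeightSpec) -> float:
    """Normalised weighted least-squares cost F(theta).

    ``g`` is a callable mapping theta to the model prediction at the sample
    times of ``z``.  The cost is zero iff the fit is perfect, and invariant
    to a common rescaling of ``z`` and ``g`` under constant-CV weights.
    """
    z = np.asarray(z, float)
    pred = np.asarray(g(theta), float)
    if pred.shape != z.shape:
        raise ValueError(f"prediction shape {pred.shape} != data shape {z.shape}")
    r = z - pred
    W = w.diagonal(z)
    return float(r @ (W * r) / (z @ z))


def _log_lattice(bounds: np.ndarray, grid_points: int) -> list[np.ndarray]:
    return [np.geomspace(lo, hi, grid_points) for lo, hi in bounds]


def _refine_coordinatewise(cost, x, best_cost, lb, ub, cell):
    """One pass of greedy coordinate refinement in log10 space: per
    coordinate, a half-cell step is tried both ways and halved until it
    drops below 1/16 of a cell, accepting any improvement."""
    for i in range(len(x)):
        step = cell[i] / 2.0
        while step > cell[i] / 16.0:
            for sgn in (+1.0, -1.0):
                trial = x.copy()
                trial[i] = np.clip(trial[i] + sgn * step, lb[i], ub[i])
                c = cost(10.0**trial)
                if np.isfinite(c) and c < best_cost:
                    best_cost, x = c, trial
                    break
            else:
                step /= 2.0
    return x, best_cost


def greedy_candidates(cost, bounds, grid_points: int = 5,
                      n_candidates: int = 1) -> list[np.ndarray]:
    """Deterministic greedy starting points, best first.

    Evaluates ``cost`` on a log-spaced lattice with ``grid_points`` nodes
    per parameter, keeps the ``n_candidates`` best nodes (ties break to the
    first-found lowest cost in row-major iteration order), and refines each
    by one pass of step-halving coordinate descent.  Multiple candidates
    guard the subsequent local descent against secondary basins of weakly
    identified problems.
    """
    bounds = np.asarray(bounds, float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be a sequence of (lo, hi) pairs")
    if np.any(bounds <= 0) or np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("bounds must be positive with lo < hi")
    if grid_points < 3:
        raise ValueError("grid_points must be >= 3")

    axes = _log_lattice(bounds, grid_points)
    scored: list[tuple[float, int, np.ndarray]] = []
    for rank, combo in enumerate(itertools.product(*axes)):
        c = cost(np.asarray(combo))
        if np.isfinite(c):
            scored.append((c, rank, np.asarray(combo)))
    if not scored:
        raise InitializationError("cost non-finite over the entire lattice")
    scored.sort(key=lambda item: (item[0], item[1]))

    lb, ub = np.log10(bounds[:, 0]), np.log10(bounds[:, 1])
    cell = (ub - lb) / (grid_points - 1)
    out = []
    seen = set()
    for c, _, theta in scored[:max(1, n_candidates)]:
        x, cx = _refine_coordinatewise(cost, np.log10(theta), c, lb, ub, cell)
        key = tuple(np.round(x, 3))
        if key in seen:  # refined duplicates add no new basin
            continue
        seen.add(key)
        out.append((cx, 10.0**x))
    out.sort(key=lambda item: item[0])
    return [theta for _, theta in out]


def fast_greedy_init(cost, bounds, grid_points: int = 5):
    """Deterministic fast-greedy initialisation: the best point of
    :func:`greedy_candidates` (log-spaced lattice search plus one pass of
    step-halving coordinate refinement)."""
    return greedy_candidates(cost, bounds, grid_points, n_candidates=1)[0]


def constrained_lm_fit(residuals, theta0, bounds, *, xtol: float = 1e-10,
                       ftol: float = 1e-10, max_nfev: int = 500,
                       param_names: tuple = ()) -> FitResult:
    """Bound-constrained Levenberg-Marquardt-type descent.

    ``residuals(theta)`` must return the weighted residual vector
    sqrt(W_i) * (z_i - g_i(theta)) / sqrt(z'z), so that the summed squares
    equal the normalised WLS cost.  Optimisation runs in log10-parameter
    space, which enforces positivity; box bounds are mapped to the log
    scale and handled by a trust-region reflective LM step.  The final cost
    never exceeds the cost at ``theta0``.

    CV% and covariance are attached by :func:`linearized_cv`; a singular
    sensitivity matrix degrades gracefully to infinite CVs with
    ``converged`` unchanged but ``cv_ok`` False.
    """
    theta0 = np.asarray(theta0, float)
    bounds = np.asarray(bounds, float)
    if np.any(theta0 < bounds[:, 0] - 1e-12) or np.any(theta0 > bounds[:, 1] + 1e-12):
        raise ValueError("theta0 must lie within bounds")

    def res_log(x):
        r = np.asarray(residuals(10.0**x), float)
        if not np.all(np.isfinite(r)):
            raise EstimationError("non-finite residuals during descent")
        return r

    x0 = np.log10(np.clip(theta0, bounds[:, 0], bounds[:, 1]))
    sol = least_squares(
        res_log, x0,
        bounds=(np.log10(bounds[:, 0]), np.log10(bounds[:, 1])),
        method="trf", x_scale="jac", xtol=xtol, ftol=ftol, gtol=1e-12,
        max_nfev=max_nfev,
    )
    theta = 10.0**sol.x
    cost = float(2.0 * sol.cost)  # scipy's cost is 0.5 * sum r^2

    # Sensitivities wrt ln(theta) are scale-free, so the covariance of
    # ln(theta-hat) is well conditioned even when parameters span many
    # orders of magnitude; its diagonal is directly the squared CV.
    J_rel = sol.jac / np.log(10.0)  # dr/dln(theta)
    n, p = J_rel.shape
    dof = max(n - p, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    try:
        cov_ln = _scaled_inverse(J_rel.T @ J_rel) * s2
        cv = 100.0 * np.sqrt(np.clip(np.diag(cov_ln), 0.0, np.inf))
        cov = cov_ln * np.outer(theta, theta)
        singular = False
    except SingularityError:
        cv = np.full(p, np.inf)
        cov = np.full((p, p), np.nan)
        singular = True
    return FitResult(
        theta=theta,
        cost=cost,
        cv_percent=cv,
        covariance=cov,
        n_iter=int(sol.nfev),
        converged=bool(sol.status > 0),
        cv_ok=bool(np.all(cv < CV_QUALITY_BAR)) and not singular,
        param_names=tuple(param_names),
        message=sol.message,
    )


def _scaled_inverse(JtJ: np.ndarray) -> np.ndarray:
    """Inverse of J'J via SVD with a relative rank check."""
    u, s, vt = np.linalg.svd(JtJ)
    if s.size == 0 or s[0] == 0 or s[-1] <= s[0] * 1e-12:
        weakest = int(np.argmax(np.abs(vt[-1]))) if s.size else 0
        raise SingularityError(
            f"sensitivity matrix rank deficient; weakest direction loads on "
            f"parameter index {weakest}"
        )
    return vt.T @ np.diag(1.0 / s) @ u.T


def linearized_cv(theta, jacobian, residual_variance):
    """Standard errors by the linearisation method, as CV%.

    The covariance of the estimate is approximated by
    ``residual_variance * inv(J'J)`` where ``J`` is the weighted residual
    sensitivity (Jacobian) at the optimum on the natural parameter scale;
    CV% = 100 * SE / |theta|.

    Raises
    ------
    SingularityError
        If ``J`` is rank deficient; the message names the weakest direction.
    """
    theta = np.asarray(theta, float)
    J = np.asarray(jacobian, float)
    cov = residual_variance * _scaled_inverse(J.T @ J)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * se / np.abs(theta)
    return cv, cov
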