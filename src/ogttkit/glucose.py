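"""Oral glucose minimal model.

The model describes post-load glucose dynamics with two states, plasma
glucose G (mmol/L) and a remote insulin-action variable Z (min^-1):

    dG/dt = -(SG + Z) * G + SG * Gb + Ra(t) / VG
    dZ/dt = -p * Z + p * SI * (I(t) - Ib)

where SG (min^-1) is glucose effectiveness, SI (min^-1 pM^-1) insulin
sensitivity, p (min^-1) the rate constant of insulin action, VG (dL/kg)
the glucose distribution volume, and Gb, Ib the basal glucose and insulin.
Insulin I(t) and the tracer-derived oral glucose rate of appearance Ra(t)
(umol/kg/min) are measured forcing functions, interpolated piecewise
linearly.  Ra/VG is bridged into mmol/L/min (1 umol/dL = 0.01 mmol/L).

At basal forcing (I = Ib, Ra = 0) the basal state (G = Gb, Z = 0) is an
exact fixed point.  SI is stored in min^-1 pM^-1 and conventionally
reported as SI x 10^4.

Estimation follows the shared engine: normalised WLS cost, fast-greedy
initialisation on a log lattice, bound-constrained LM-type descent in log
space, linearisation CV%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import BasalState, OgttTimeSeries, basal_means
from .estimation import (
    FitResult,
    WeightSpec,
    constrained_lm_fit,
    greedy_candidates,
    wls_cost,
)
from .exceptions import EstimationError

__all__ = [
    "GlucoseModelParams",
    "simulate_glucose",
    "GlucoseMinimalModel",
    "GlucoseModelResults",
    "DEFAULT_GLUCOSE_BOUNDS",
]

#: mmol/L per umol/dL (unit bridge for the Ra/VG input term).
_MMOLL_PER_UMOLDL = 0.01

#: Generous physiological box bounds for the constrained fit (natural scale).
DEFAULT_GLUCOSE_BOUNDS = {
    "SG": (1e-4, 0.2),
    "SI": (1e-7, 1e-2),
    "p": (1e-3, 1.0),
    "VG": (0.5, 5.0),
}


@dataclass(frozen=True)
class GlucoseModelParams:
    """Oral-minimal-model parameter vector (natural units)."""

    SG: float  # min^-1
    SI: float  # min^-1 pM^-1
    p: float  # min^-1
    VG: float  # dL/kg
    Gb: float  # mmol/L
    Ib: float  # pM

    def __post_init__(self) -> None:
        for name in ("SG", "SI", "p", "VG", "Gb", "Ib"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v!r}")

    @property
    def si_e4(self) -> float:
        """SI on the conventional x10^4 reporting scale."""
        return self.SI * 1e4

    @property
    def sg_e2(self) -> float:
        """SG on the conventional x10^2 reporting scale."""
        return self.SG * 1e2


def _refine_grid(times: np.ndarray, dt: float) -> np.ndarray:
    t0, t1 = float(times[0]), float(times[-1])
    fine = np.union1d(times, t0 + dt * np.arange(int(np.ceil((t1 - t0) / dt)) + 1))
    return fine[(fine >= t0) & (fine <= t1 + 1e-12)]


def simulate_glucose(params: GlucoseModelParams, insulin: np.ndarray,
                     ra: np.ndarray, times: np.ndarray,
                     dt: float = 0.5) -> np.ndarray:
    """Simulate plasma glucose at ``times`` (classic RK4, step <= dt).

    ``insulin`` (pM) and ``ra`` (umol/kg/min) are sampled on ``times`` and
    interpolated piecewise linearly between samples.  Initial condition:
    G = Gb, Z = 0 at ``times[0]``.
    """
    times = np.asarray(times, float)
    insulin = np.asarray(insulin, float)
    ra = np.asarray(ra, float)
    if times.ndim != 1 or times.size < 2 or not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing with >= 2 points")
    if insulin.shape != times.shape or ra.shape != times.shape:
        raise ValueError("insulin and ra must be sampled on `times`")
    if dt <= 0:
        raise ValueError("dt must be positive")

    fine = _refine_grid(times, dt)
    mids = 0.5 * (fine[:-1] + fine[1:])
    I_f = np.interp(fine, times, insulin)
    I_m = np.interp(mids, times, insulin)
    ra_f = np.interp(fine, times, ra) * _MMOLL_PER_UMOLDL / params.VG
    ra_m = np.interp(mids, times, ra) * _MMOLL_PER_UMOLDL / params.VG

    SG, SI, p, Gb, Ib = params.SG, params.SI, params.p, params.Gb, params.Ib

    def rhs(G, Z, I_t, q_t):
        return (-(SG + Z) * G + SG * Gb + q_t, -p * Z + p * SI * (I_t - Ib))

    G = np.empty(fine.size)
    G[0] = Gb
    g, z = Gb, 0.0
    for k in range(fine.size - 1):
        h = fine[k + 1] - fine[k]
        k1g, k1z = rhs(g, z, I_f[k], ra_f[k])
        k2g, k2z = rhs(g + 0.5 * h * k1g, z + 0.5 * h * k1z, I_m[k], ra_m[k])
        k3g, k3z = rhs(g + 0.5 * h * k2g, z + 0.5 * h * k2z, I_m[k], ra_m[k])
        k4g, k4z = rhs(g + h * k3g, z + h * k3z, I_f[k + 1], ra_f[k + 1])
        g += h / 6.0 * (k1g + 2 * k2g + 2 * k3g + k4g)
        z += h / 6.0 * (k1z + 2 * k2z + 2 * k3z + k4z)
        G[k + 1] = g
    return np.interp(times, fine, G)


class GlucoseMinimalModel:
    """Oral glucose minimal model bound to one subject's data.

    Parameters
    ----------
    series : OgttTimeSeries
        Subject data; the post-load samples (t >= 0) are fitted and basal
        means supply Gb and Ib.
    ra_oral : ndarray
        Oral glucose rate of appearance (umol/kg/min) on the post-load
        sample grid, typically from :func:`ogttkit.fluxes.compute_fluxes`.
    weights : WeightSpec, optional
        Observation weights; default constant 2% CV on glucose.
    dt : float
        Integrator step bound (min) used during fitting.
    """

    param_names = ("SG", "SI", "p", "VG")

    def __init__(self, series: OgttTimeSeries, ra_oral: np.ndarray,
                 weights: WeightSpec | None = None,
                 basal: BasalState | None = None, dt: float = 1.0):
        self.series = series
        self.basal = basal if basal is not None else basal_means(series)
        post = series.time >= 0.0
        self.times = series.time[post]
        if self.times.size < len(self.param_names) + 1:
            raise EstimationError("too few post-load samples to fit 4 parameters")
        self.glucose_obs = series.glucose[post]
        self.insulin = series.insulin[post]
        ra_oral = np.asarray(ra_oral, float)
        if ra_oral.shape == series.time.shape:
            ra_oral = ra_oral[post]
        if ra_oral.shape != self.times.shape:
            raise ValueError("ra_oral must be sampled on the (post-load) grid")
        self.ra_oral = ra_oral
        self.weights = weights if weights is not None else WeightSpec(cv=0.02)
        self.dt = dt
        # Degenerate data: a flat glucose trace under a nonzero oral input
        # carries no information on the disposal parameters.
        self.ill_conditioned = bool(np.ptp(self.glucose_obs) == 0.0
                                    and np.any(self.ra_oral > 0))
        if self.ill_conditioned:
            warnings.warn("flat glucose trace with nonzero Ra: fit is "
                          "ill-conditioned", stacklevel=2)

    def _params(self, theta: np.ndarray) -> GlucoseModelParams:
        return GlucoseModelParams(SG=theta[0], SI=theta[1], p=theta[2],
                                  VG=theta[3], Gb=self.basal.Gb, Ib=self.basal.Ib)

    def predict(self, theta) -> np.ndarray:
        """Model glucose at the fitted sample times for a parameter vector
        (SG, SI, p, VG) or a :class:`GlucoseModelParams`."""
        if isinstance(theta, GlucoseModelParams):
            params = theta
        else:
            params = self._params(np.asarray(theta, float))
        return simulate_glucose(params, self.insulin, self.ra_oral,
                                self.times, dt=self.dt)

    def cost(self, theta) -> float:
        return wls_cost(theta, self.glucose_obs, self.predict, self.weights)

    def fit(self, bounds: dict | None = None, grid_points: int = 5,
            n_starts: int = 8, max_nfev: int = 500) -> "GlucoseModelResults":
        """Fit SG, SI, p, VG.

        The descent is restarted from the ``n_starts`` best greedy
        candidates and the lowest-cost solution kept; the SG/p/SI exchange
        makes the surface multi-basined for weakly excited subjects.
        """
        b = dict(DEFAULT_GLUCOSE_BOUNDS)
        if bounds:
            b.update(bounds)
        barr = np.array([b[n] for n in self.param_names], float)

        z = self.glucose_obs
        w = self.weights.diagonal(z)
        norm = np.sqrt(z @ z)
        sw = np.sqrt(w) / norm

        def residuals(theta):
            return sw * (z - self.predict(theta))

        best = None
        for theta0 in greedy_candidates(self.cost, barr,
                                        grid_points=grid_points,
                                        n_candidates=n_starts):
            fitres = constrained_lm_fit(residuals, theta0, barr,
                                        max_nfev=max_nfev,
                                        param_names=self.param_names)
            if best is None or fitres.cost < best.cost:
                best = fitres
        return GlucoseModelResults(self, best)


class GlucoseModelResults:
    """Results of a fitted oral glucose minimal model."""

    def __init__(self, model: GlucoseMinimalModel, fitres: FitResult):
        self.model = model
        self.fitres = fitres
        self.params = model._params(fitres.theta)
        self.cv_percent = dict(zip(model.param_names, fitres.cv_percent))
        self.cost = fitres.cost
        self.converged = fitres.converged and fitres.cv_ok
        self.cv_ok = fitres.cv_ok
        self.ill_conditioned = model.ill_conditioned
        self.fitted_values = model.predict(fitres.theta)
        self.resid = model.glucose_obs - self.fitted_values

    @property
    def si(self) -> float:
        """Insulin sensitivity, min^-1 pM^-1 (natural scale)."""
        return self.params.SI

    def summary(self) -> str:
        lines = [
            "Oral glucose minimal model fit",
            "=" * 46,
            f"{'n obs':<22}{len(self.model.times):>10d}",
            f"{'cost (normalised WLS)':<22}{self.cost:>10.3e}",
            f"{'converged':<22}{str(self.converged):>10}",
            f"{'all CV% < 20':<22}{str(self.cv_ok):>10}",
            "-" * 46,
            f"{'param':<8}{'estimate':>14}{'CV%':>10}",
        ]
        display = {"SG": ("SG x10^2 (1/min)", self.params.sg_e2),
                   "SI": ("SI x10^4 (1/min/pM)", self.params.si_e4),
                   "p": ("p (1/min)", self.params.p),
                   "VG": ("VG (dL/kg)", self.params.VG)}
        for name in self.model.param_names:
            label, value = display[name]
            lines.append(f"{label:<22}{value:>10.4g}{self.cv_percent[name]:>10.1f}")
        lines.append("-" * 46)
        lines.append(f"Gb = {self.params.Gb:.3g} mmol/L, Ib = {self.params.Ib:.4g} pM")
        if self.ill_conditioned:
            lines.append("WARNING: ill-conditioned (flat glucose, nonzero Ra)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "SG": self.params.SG, "SI": self.params.SI,
            "p": self.params.p, "VG": self.params.VG,
            "Gb": self.params.Gb, "Ib": self.params.Ib,
            "SI_x1e4": self.params.si_e4,
            "cv_percent": {k: float(v) for k, v in self.cv_percent.items()},
            "cost": self.cost, "converged": bool(self.converged),
            "cv_ok": bool(self.cv_ok),
        }

    def plot_fit(self, ax=None):
        """Observed vs fitted glucose (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.times, self.model.glucose_obs, "o", label="observed")
        ax.plot(self.model.times, self.fitted_values, "-", label="fitted")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("glucose (mmol/L)")
        ax.legend()
        return ax
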