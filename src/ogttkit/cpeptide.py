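"""C-peptide secretion minimal model and beta-cell sensitivity indices.

C-peptide is secreted equimolarly with insulin but is not extracted by the
liver, so its plasma concentration can be deconvolved into the insulin
secretion rate (ISR) through linear two-compartment kinetics:

    dCP1/dt = -(k01 + k21) CP1 + k12 CP2 + SR(t)
    dCP2/dt = k21 CP1 - k12 CP2

with CP1 the measured (central) concentration in pM and SR the secretion
rate per unit central volume (pM/min).  Secretion above basal has a static
and a dynamic pathway:

    static:  dY/dt = -(Y - phi_s * (G - h)+) / tau        (delayed)
    dynamic: SRd(t) = phi_d * max(dG/dt, 0)               (rate-of-rise)

with glucose expressed in pM for the secretion arithmetic (1 mmol/L =
1e9 pM), which puts the sensitivity indices on the conventional 1e-9
scale: phi_s and phi_1 in min^-1 (reported x1e9), phi_d dimensionless
(reported x1e9).  ``h`` is the glucose threshold of the static pathway
(default: basal glucose) and tau the static-secretion delay.

Basal secretion SRb = k01 * CPb closes the steady state, so with G = h the
model stays flat at basal.  ISR in pmol/kg/min is SR * Vc.

Derived indices:

* phi (total): secretion-amount-weighted combination,
  phi = phi_s + phi_d * dGmax+ / integral((G - h)+ dt); reduces to phi_s
  when phi_d = 0.
* phi_1 (first phase): dynamic secretion released over the first 10 min
  normalised by the early above-basal glucose exposure.
* Disposition index DI = phi x SI on the reporting scales.
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
    "CpKinetics",
    "CpModelParams",
    "IsrProfile",
    "DEFAULT_CP_KINETICS",
    "DEFAULT_CP_BOUNDS",
    "simulate_cpeptide",
    "isr_auc",
    "disposition_index",
    "CPeptideMinimalModel",
    "CPeptideModelResults",
]

#: pM of glucose per mmol/L (secretion arithmetic scale).
PM_PER_MMOLL = 1e9

#: Early-phase window for the phi_1 index, min.
PHI1_WINDOW = 10.0


@dataclass(frozen=True)
class CpKinetics:
    """Two-compartment C-peptide kinetic constants.

    The defaults are a documented generic parameter set; population or
    individually estimated kinetics should be supplied when available, and
    all recovery tests in this package pass generator kinetics explicitly.
    """

    k01: float = 0.06  # min^-1, irreversible loss from the central pool
    k12: float = 0.05  # min^-1, peripheral -> central
    k21: float = 0.02  # min^-1, central -> peripheral
    Vc: float = 0.06  # L/kg, central distribution volume

    def __post_init__(self) -> None:
        for name in ("k01", "k12", "k21", "Vc"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v!r}")


DEFAULT_CP_KINETICS = CpKinetics()

#: Box bounds for the constrained fit (natural scale).
DEFAULT_CP_BOUNDS = {
    "phi_s": (1e-11, 1e-6),
    "phi_d": (1e-10, 1e-5),
    "tau": (1.0, 120.0),
}


@dataclass(frozen=True)
class CpModelParams:
    """Secretion-model parameters and derived sensitivity indices
    (natural scale; x1e9 reporting properties attached)."""

    phi_s: float  # min^-1
    phi_d: float  # dimensionless
    tau: float  # min
    h: float  # mmol/L
    phi_total: float | None = None  # min^-1
    phi_1: float | None = None  # min^-1

    def __post_init__(self) -> None:
        if self.phi_s < 0 or self.phi_d < 0:
            raise ValueError("phi_s and phi_d must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def phi_s_e9(self) -> float:
        return self.phi_s * 1e9

    @property
    def phi_d_e9(self) -> float:
        return self.phi_d * 1e9

    @property
    def phi_total_e9(self) -> float | None:
        return None if self.phi_total is None else self.phi_total * 1e9

    @property
    def phi_1_e9(self) -> float | None:
        return None if self.phi_1 is None else self.phi_1 * 1e9


@dataclass(frozen=True)
class IsrProfile:
    """Reconstructed insulin secretion rate.

    ``isr`` is pmol/kg/min when ``per_kg`` (the default), else pmol/min.
    """

    time: np.ndarray
    isr: np.ndarray
    per_kg: bool = True
    body_weight: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, float))
        object.__setattr__(self, "isr", np.asarray(self.isr, float))
        if self.isr.shape != self.time.shape:
            raise ValueError("isr and time must match")


def isr_auc(profile: IsrProfile) -> float:
    """Trapezoidal AUC of the ISR over its window, in nmol.

    Per-kg profiles require ``body_weight`` to resolve to whole-body nmol.
    """
    pmol = float(np.trapezoid(profile.isr, profile.time))
    if profile.per_kg:
        if profile.body_weight is None:
            raise ValueError("per-kg ISR needs body_weight for a whole-body AUC")
        pmol *= profile.body_weight
    return pmol / 1000.0


def disposition_index(phi_total: float, si: float) -> float:
    """Disposition index DI = phi x SI (product on the reporting scales:
    phi on x1e9, SI on x1e4; DI then lands on the conventional
    pM^-1 min^-2 reporting scale)."""
    if phi_total < 0 or si < 0:
        raise ValueError("phi and SI must be non-negative")
    return phi_total * si


def _segment_slopes(times: np.ndarray, glucose: np.ndarray) -> np.ndarray:
    return np.diff(glucose) / np.diff(times)


def simulate_cpeptide(kin: CpKinetics, phi_s: float, phi_d: float, tau: float,
                      h: float, glucose: np.ndarray, times: np.ndarray,
                      cp_basal: float, dt: float = 0.5,
                      include_basal_secretion: bool = True) -> np.ndarray:
    """Simulate plasma C-peptide (pM) at ``times``.

    Glucose (mmol/L) is interpolated piecewise linearly, so its rate of
    change driving the dynamic pathway is piecewise constant.  The initial
    condition is the two-compartment basal steady state consistent with
    ``cp_basal``; with ``include_basal_secretion`` off, only the
    above-basal pathways secrete and the initial basal concentration washes
    out along the kinetic impulse response.
    """
    times = np.asarray(times, float)
    glucose = np.asarray(glucose, float)
    if glucose.shape != times.shape:
        raise ValueError("glucose must be sampled on `times`")
    if not np.isfinite(cp_basal) or cp_basal <= 0:
        raise ValueError("cp_basal must be positive (basal steady state "
                         "requires a basal C-peptide value)")
    if dt <= 0:
        raise ValueError("dt must be positive")

    t0, t1 = float(times[0]), float(times[-1])
    fine = np.union1d(times, t0 + dt * np.arange(int(np.ceil((t1 - t0) / dt)) + 1))
    fine = fine[(fine >= t0) & (fine <= t1 + 1e-12)]
    mids = 0.5 * (fine[:-1] + fine[1:])
    G_f = np.interp(fine, times, glucose)
    G_m = np.interp(mids, times, glucose)
    seg = np.searchsorted(times, mids, side="right") - 1
    slopes = _segment_slopes(times, glucose)
    dGdt_step = slopes[np.clip(seg, 0, slopes.size - 1)]  # per fine step

    srb = kin.k01 * cp_basal if include_basal_secretion else 0.0
    cp1 = cp_basal
    cp2 = cp_basal * kin.k21 / kin.k12  # basal steady state of the remote pool
    # static pathway at basal: steady at its own forcing
    y = phi_s * max(G_f[0] - h, 0.0) * PM_PER_MMOLL

    out = np.empty(fine.size)
    out[0] = cp1

    def rhs(c1, c2, yy, G_t, sd):
        sr = srb + yy + sd
        dc1 = -(kin.k01 + kin.k21) * c1 + kin.k12 * c2 + sr
        dc2 = kin.k21 * c1 - kin.k12 * c2
        dy = -(yy - phi_s * max(G_t - h, 0.0) * PM_PER_MMOLL) / tau
        return dc1, dc2, dy

    for k in range(fine.size - 1):
        hstep = fine[k + 1] - fine[k]
        sd = phi_d * max(dGdt_step[k], 0.0) * PM_PER_MMOLL
        k1 = rhs(cp1, cp2, y, G_f[k], sd)
        k2 = rhs(cp1 + 0.5 * hstep * k1[0], cp2 + 0.5 * hstep * k1[1],
                 y + 0.5 * hstep * k1[2], G_m[k], sd)
        k3 = rhs(cp1 + 0.5 * hstep * k2[0], cp2 + 0.5 * hstep * k2[1],
                 y + 0.5 * hstep * k2[2], G_m[k], sd)
        k4 = rhs(cp1 + hstep * k3[0], cp2 + hstep * k3[1],
                 y + hstep * k3[2], G_f[k + 1], sd)
        cp1 += hstep / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        cp2 += hstep / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        y += hstep / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        out[k + 1] = cp1
    return np.interp(times, fine, out)


def _reconstruct_isr(kin: CpKinetics, phi_s: float, phi_d: float, tau: float,
                     h: float, glucose: np.ndarray, times: np.ndarray,
                     cp_basal: float, body_weight: float | None) -> IsrProfile:
    """Forward-model the secretion rate at the sample times (pmol/kg/min)."""
    # static pathway response by exact exponential stepping over segments
    y = np.empty(times.size)
    y[0] = phi_s * max(glucose[0] - h, 0.0) * PM_PER_MMOLL
    target = phi_s * np.clip(glucose - h, 0.0, None) * PM_PER_MMOLL
    for k in range(times.size - 1):
        dt = times[k + 1] - times[k]
        # linear target across the segment; trapezoidal update of the ODE
        a = np.exp(-dt / tau)
        y[k + 1] = a * y[k] + (1 - a) * 0.5 * (target[k] + target[k + 1])
    slopes = _segment_slopes(times, glucose)
    dgdt = np.gradient(glucose, times)
    srd = phi_d * np.clip(dgdt, 0.0, None) * PM_PER_MMOLL
    sr = kin.k01 * cp_basal + y + srd
    return IsrProfile(time=times, isr=sr * kin.Vc, per_kg=True,
                      body_weight=body_weight)


class CPeptideMinimalModel:
    """C-peptide secretion model bound to one subject's data.

    Fits (phi_s, phi_d, tau) to the post-load C-peptide trace given the
    observed glucose forcing and fixed kinetics; the threshold ``h`` is
    fixed at basal glucose.
    """

    param_names = ("phi_s", "phi_d", "tau")

    def __init__(self, series: OgttTimeSeries,
                 kinetics: CpKinetics = DEFAULT_CP_KINETICS,
                 weights: WeightSpec | None = None,
                 basal: BasalState | None = None,
                 body_weight: float | None = None, dt: float = 1.0):
        self.series = series
        self.kinetics = kinetics
        self.basal = basal if basal is not None else basal_means(series)
        post = series.time >= 0.0
        self.times = series.time[post]
        if self.times.size < len(self.param_names) + 1:
            raise EstimationError("too few post-load samples to fit 3 parameters")
        self.glucose = series.glucose[post]
        self.cp_obs = series.cpeptide[post]
        self.h = self.basal.Gb
        self.body_weight = body_weight
        self.weights = weights if weights is not None else WeightSpec(cv=0.04)
        self.dt = dt
        rise = np.max(np.clip(_segment_slopes(self.times, self.glucose), 0, None),
                      initial=0.0)
        # With no rising glucose the dynamic pathway never fires.
        self.phi_d_identifiable = bool(rise > 0)
        if not self.phi_d_identifiable:
            warnings.warn("glucose never rises: phi_d is unidentifiable",
                          stacklevel=2)

    def predict(self, theta) -> np.ndarray:
        phi_s, phi_d, tau = np.asarray(theta, float)
        return simulate_cpeptide(self.kinetics, phi_s, phi_d, tau, self.h,
                                 self.glucose, self.times, self.basal.CPb,
                                 dt=self.dt)

    def cost(self, theta) -> float:
        return wls_cost(theta, self.cp_obs, self.predict, self.weights)

    def fit(self, bounds: dict | None = None, grid_points: int = 5,
            n_starts: int = 2, max_nfev: int = 400) -> "CPeptideModelResults":
        b = dict(DEFAULT_CP_BOUNDS)
        if bounds:
            b.update(bounds)
        barr = np.array([b[n] for n in self.param_names], float)

        z = self.cp_obs
        w = self.weights.diagonal(z)
        sw = np.sqrt(w) / np.sqrt(z @ z)

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
        return CPeptideModelResults(self, best)


class CPeptideModelResults:
    """Results of a fitted C-peptide secretion model: sensitivity indices,
    reconstructed ISR and its AUC."""

    def __init__(self, model: CPeptideMinimalModel, fitres: FitResult):
        self.model = model
        self.fitres = fitres
        phi_s, phi_d, tau = fitres.theta
        t, G = model.times, model.glucose
        Gpm = G * PM_PER_MMOLL
        hpm = model.h * PM_PER_MMOLL
        above = np.clip(Gpm - hpm, 0.0, None)
        stim = float(np.trapezoid(above, t))  # pM min
        dg_plus = max(float(Gpm.max() - Gpm[0]), 0.0)  # pM
        phi_total = phi_s + (phi_d * dg_plus / stim if stim > 0 else 0.0)
        # first-phase: dynamic release over the first 10 min / early exposure
        m = t <= t[0] + PHI1_WINDOW
        if m.sum() >= 2:
            g10 = np.interp(t[0] + PHI1_WINDOW, t, Gpm)
            released = phi_d * max(g10 - Gpm[0], 0.0)  # pM released dynamically
            exposure = float(np.trapezoid(
                np.clip(Gpm[m] - Gpm[0], 0.0, None), t[m]))  # pM min
            phi_1 = released / exposure if exposure > 0 else 0.0
        else:
            phi_1 = 0.0
        self.params = CpModelParams(phi_s=phi_s, phi_d=phi_d, tau=tau,
                                    h=model.h, phi_total=phi_total,
                                    phi_1=phi_1)
        self.cv_percent = dict(zip(model.param_names, fitres.cv_percent))
        self.cost = fitres.cost
        self.converged = fitres.converged and fitres.cv_ok
        self.cv_ok = fitres.cv_ok
        self.phi_d_identifiable = model.phi_d_identifiable
        self.fitted_values = model.predict(fitres.theta)
        self.resid = model.cp_obs - self.fitted_values
        self.isr_profile = _reconstruct_isr(
            model.kinetics, phi_s, phi_d, tau, model.h, G, t,
            model.basal.CPb, model.body_weight)

    @property
    def auc_isr(self) -> float:
        """AUC of the reconstructed ISR over the test, nmol (needs body
        weight on the model)."""
        return isr_auc(self.isr_profile)

    def summary(self) -> str:
        p = self.params
        lines = [
            "C-peptide secretion minimal model fit",
            "=" * 50,
            f"{'n obs':<26}{len(self.model.times):>10d}",
            f"{'cost (normalised WLS)':<26}{self.cost:>10.3e}",
            f"{'converged':<26}{str(self.converged):>10}",
            f"{'all CV% < 20':<26}{str(self.cv_ok):>10}",
            "-" * 50,
            f"{'param':<8}{'estimate':>16}{'CV%':>10}",
            f"{'phi_s x1e9 (1/min)':<26}{p.phi_s_e9:>10.4g}{self.cv_percent['phi_s']:>10.1f}",
            f"{'phi_d x1e9':<26}{p.phi_d_e9:>10.4g}{self.cv_percent['phi_d']:>10.1f}",
            f"{'tau (min)':<26}{p.tau:>10.4g}{self.cv_percent['tau']:>10.1f}",
            "-" * 50,
            f"phi (total) x1e9 = {p.phi_total_e9:.4g} 1/min",
            f"phi_1 x1e9       = {p.phi_1_e9:.4g} 1/min",
        ]
        if self.model.body_weight is not None:
            lines.append(f"AUC_ISR          = {self.auc_isr:.4g} nmol")
        if not self.phi_d_identifiable:
            lines.append("WARNING: phi_d unidentifiable (glucose never rises)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        p = self.params
        d = {
            "phi_s": p.phi_s, "phi_d": p.phi_d, "tau": p.tau, "h": p.h,
            "phi_total": p.phi_total, "phi_1": p.phi_1,
            "phi_s_x1e9": p.phi_s_e9, "phi_d_x1e9": p.phi_d_e9,
            "phi_total_x1e9": p.phi_total_e9, "phi_1_x1e9": p.phi_1_e9,
            "cv_percent": {k: float(v) for k, v in self.cv_percent.items()},
            "cost": self.cost, "converged": bool(self.converged),
            "cv_ok": bool(self.cv_ok),
        }
        if self.model.body_weight is not None:
            d["auc_isr_nmol"] = self.auc_isr
        return d
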