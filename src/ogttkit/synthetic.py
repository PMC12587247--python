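"""Synthetic dual-tracer OGTT datasets with known ground truth.

The generator emulates the porcine study design this package analyses:
three treatment arms (sham endoscopy, endoscopic bypass device, GLP-1
receptor-agonist drug), the standard sampling grid (basal samples, then 0,
5, 10, 15, 20, 25 and every 10 min to 180), a primed-constant [6,6-2H2]
glucose infusion (prime 32 umol/kg, 0.32 umol/kg/min) and a 75 g oral load
enriched with 0.9 g of [U-13C] glucose (load TTR 0.012).

Construction is strictly forward:

1. insulin is a parametric gamma-shaped excursion over basal (the minimal
   models treat insulin as a measured input, so no insulin-kinetics model
   is simulated);
2. glucose follows the oral glucose minimal model under the truth
   parameters and truth oral Ra;
3. C-peptide follows the secretion model under the truth indices;
4. the infused-tracer TTR integrates the single-pool tracer balance under
   the truth total Ra (so the non-steady-state Steele estimator applied at
   zero noise recovers the truth fluxes up to discretisation);
5. the oral-tracer TTR partitions plasma glucose according to the truth
   oral fraction;
6. channels are sampled on the protocol grid and multiplicative log-normal
   noise is applied per channel.

The basal period is generated at steady state (constant channels, infused
TTR at its infusion/turnover equilibrium F / EGP_b).  Truth EGP follows
EGP(t) = EGP_b * (f + (1 - f) exp(-t / tau_e)), which spans sham-like mild
suppression through device-like deep suppression.

Default noise CVs mirror the assay precisions of the emulated protocol:
glucose 2%, insulin 3.5%, C-peptide 3.6%, TTR 2%.  What the generator does
NOT emulate: assay drift, non-multiplicative error, within-subject
correlation of errors across channels, gastric-emptying physiology behind
the oral Ra shape (it is an imposed piecewise-linear profile).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cpeptide import CpKinetics, DEFAULT_CP_BOUNDS, simulate_cpeptide
from .data import (
    DEFAULT_BASAL_GRID,
    DEFAULT_SAMPLING_GRID,
    OgttTimeSeries,
    SubjectProtocol,
    write_ogtt_csv,
)
from .exceptions import ScenarioError
from .fluxes import SteeleConfig
from .glucose import DEFAULT_GLUCOSE_BOUNDS, GlucoseModelParams, simulate_glucose

__all__ = [
    "InsulinExcursion",
    "EgpTruth",
    "OralRaTruth",
    "CpTruth",
    "NoiseSpec",
    "ScenarioSpec",
    "SubjectTruth",
    "arm_scenario",
    "generate_subject",
    "generate_cohort",
    "ARM_PRESETS",
]

_FINE_DT = 0.5


@dataclass(frozen=True)
class InsulinExcursion:
    """Parametric insulin forcing: Ib + amplitude * ((t/tp) e^(1-t/tp))^k
    for t > 0 (gamma-like rise and decay)."""

    amplitude: float  # pM above basal at the peak
    t_peak: float = 45.0  # min
    shape: float = 2.0

    def curve(self, t: np.ndarray, Ib: float) -> np.ndarray:
        t = np.asarray(t, float)
        x = np.clip(t, 0.0, None) / self.t_peak
        with np.errstate(over="ignore"):
            bump = np.where(t > 0, (x * np.exp(1.0 - x)) ** self.shape, 0.0)
        return Ib + self.amplitude * bump


@dataclass(frozen=True)
class EgpTruth:
    """EGP(t) = basal * (floor_frac + (1 - floor_frac) exp(-t/tau)) for
    t > 0; constant at ``basal`` during the basal period."""

    basal: float  # umol/kg/min
    floor_frac: float  # in [0, 1]
    tau: float = 40.0  # min

    def curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        supp = self.floor_frac + (1 - self.floor_frac) * np.exp(
            -np.clip(t, 0.0, None) / self.tau)
        return np.where(t > 0, self.basal * supp, self.basal)

    def window_mean(self, t0: float = 0.0, t1: float = 180.0) -> float:
        tt = np.linspace(t0, t1, 721)
        return float(np.trapezoid(self.curve(tt), tt) / (t1 - t0))

    @classmethod
    def from_window_mean(cls, basal: float, target_mean: float,
                         tau: float = 40.0, t1: float = 180.0) -> "EgpTruth":
        """Choose floor_frac so the [0, t1] time-average equals the target."""
        c = (tau / t1) * (1.0 - np.exp(-t1 / tau))
        f = (target_mean / basal - c) / (1.0 - c)
        if not 0.0 <= f <= 1.0:
            raise ScenarioError(
                f"target EGP mean {target_mean} unreachable from basal {basal}")
        return cls(basal=basal, floor_frac=float(f), tau=tau)


#: Relative oral-Ra shape (breakpoint times min, relative heights).  The
#: breakpoints sit on the sampling grid so the sampled profile determines
#: the truth curve exactly.
_ORAL_SHAPE_T = (0.0, 20.0, 55.0, 115.0, 180.0)
_ORAL_SHAPE_V = (0.0, 1.0, 0.55, 0.28, 0.05)


@dataclass(frozen=True)
class OralRaTruth:
    """Piecewise-linear truth profile of oral glucose appearance."""

    times: tuple = _ORAL_SHAPE_T
    values: tuple = _ORAL_SHAPE_V

    def curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return np.where(t > 0, np.interp(t, self.times, self.values), 0.0)

    def window_mean(self, t0: float = 0.0, t1: float = 180.0) -> float:
        tt = np.union1d(np.asarray(self.times), np.linspace(t0, t1, 361))
        tt = tt[(tt >= t0) & (tt <= t1)]
        return float(np.trapezoid(self.curve(tt), tt) / (t1 - t0))

    @classmethod
    def with_window_mean(cls, target_mean: float, t1: float = 180.0) -> "OralRaTruth":
        base = cls()
        scale = target_mean / base.window_mean(0.0, t1)
        return cls(times=base.times,
                   values=tuple(scale * v for v in base.values))


@dataclass(frozen=True)
class CpTruth:
    """Truth values for the secretion model."""

    phi_s: float
    phi_d: float
    tau: float = 12.0
    CPb: float = 250.0  # pM
    kinetics: CpKinetics = field(default_factory=CpKinetics)


@dataclass(frozen=True)
class NoiseSpec:
    """Per-channel multiplicative noise CVs (fractions)."""

    glucose: float = 0.02
    insulin: float = 0.035
    cpeptide: float = 0.036
    ttr: float = 0.02

    def __post_init__(self) -> None:
        for name in ("glucose", "insulin", "cpeptide", "ttr"):
            if getattr(self, name) < 0:
                raise ScenarioError(f"noise CV {name} must be >= 0")

    def scaled(self, factor: float) -> "NoiseSpec":
        return NoiseSpec(*(factor * getattr(self, n)
                           for n in ("glucose", "insulin", "cpeptide", "ttr")))


ZERO_NOISE = NoiseSpec(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete specification of one synthetic subject."""

    arm: str
    glucose_params: GlucoseModelParams
    cp_truth: CpTruth
    egp_truth: EgpTruth
    oral_ra_truth: OralRaTruth
    insulin_excursion: InsulinExcursion
    protocol: SubjectProtocol
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    steele: SteeleConfig = field(default_factory=SteeleConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        gp = self.glucose_params
        for name in ("SG", "SI", "p", "VG"):
            lo, hi = DEFAULT_GLUCOSE_BOUNDS[name]
            v = getattr(gp, name)
            if not lo <= v <= hi:
                raise ScenarioError(
                    f"truth {name}={v} outside fitting bounds [{lo}, {hi}]")
        for name in ("phi_s", "phi_d", "tau"):
            lo, hi = DEFAULT_CP_BOUNDS[name]
            v = getattr(self.cp_truth, name)
            if not lo <= v <= hi:
                raise ScenarioError(
                    f"truth {name}={v} outside fitting bounds [{lo}, {hi}]")
        if self.egp_truth.basal <= 0:
            raise ScenarioError("basal EGP must be positive")


@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth attached to a generated subject (noise-free, on the
    sample grid)."""

    glucose_params: GlucoseModelParams
    cp_truth: CpTruth
    time: np.ndarray
    ra_oral: np.ndarray
    ra_total: np.ndarray
    egp: np.ndarray
    mean_ra_oral: float
    mean_egp: float
    clean: OgttTimeSeries


#: Arm-level presets mirroring the study contrasts: minimal-model and
#: secretion indices at the reported group means (natural units), oral
#: absorption means 3.11 / 2.09 / 3.50 umol/kg/min and mean EGP
#: 9.38 / 4.60 / 8.55 umol/kg/min, with sham-like large insulin excursions
#: and a flatter device response.
ARM_PRESETS = {
    "sham": dict(SG=1.49e-2, SI=0.78e-4, p=0.025, VG=1.6, Gb=5.0, Ib=60.0,
                 phi_s=59.42e-9, phi_d=965.88e-9, CPb=280.0,
                 oral_mean=3.11, egp_basal=10.5, egp_mean=9.38,
                 insulin_amp=360.0),
    "device": dict(SG=2.05e-2, SI=2.75e-4, p=0.025, VG=1.6, Gb=4.6, Ib=45.0,
                   phi_s=40.95e-9, phi_d=624.0e-9, CPb=220.0,
                   oral_mean=2.09, egp_basal=9.0, egp_mean=4.60,
                   insulin_amp=110.0),
    "drug": dict(SG=1.42e-2, SI=1.34e-4, p=0.025, VG=1.6, Gb=4.8, Ib=55.0,
                 phi_s=32.39e-9, phi_d=746.53e-9, CPb=260.0,
                 oral_mean=3.50, egp_basal=10.0, egp_mean=8.55,
                 insulin_amp=260.0),
}


def arm_scenario(arm: str, body_weight: float = 55.0, seed: int = 0,
                 noise: NoiseSpec | None = None) -> ScenarioSpec:
    """Build the preset scenario for one treatment arm."""
    if arm not in ARM_PRESETS:
        raise ScenarioError(f"unknown arm {arm!r}; one of {sorted(ARM_PRESETS)}")
    p = ARM_PRESETS[arm]
    protocol = SubjectProtocol(body_weight=body_weight)
    return ScenarioSpec(
        arm=arm,
        glucose_params=GlucoseModelParams(SG=p["SG"], SI=p["SI"], p=p["p"],
                                          VG=p["VG"], Gb=p["Gb"], Ib=p["Ib"]),
        cp_truth=CpTruth(phi_s=p["phi_s"], phi_d=p["phi_d"], CPb=p["CPb"]),
        egp_truth=EgpTruth.from_window_mean(p["egp_basal"], p["egp_mean"]),
        oral_ra_truth=OralRaTruth.with_window_mean(p["oral_mean"]),
        insulin_excursion=InsulinExcursion(amplitude=p["insulin_amp"]),
        protocol=protocol,
        noise=noise if noise is not None else NoiseSpec(),
        seed=seed,
    )


def _integrate_infused_ttr(t_fine: np.ndarray, ra_total: np.ndarray,
                           e_oral: np.ndarray, glucose: np.ndarray,
                           F: float, steele: SteeleConfig,
                           e_basal: float) -> np.ndarray:
    """Integrate the single-pool tracer balance
    dE/dt = (F - Ra_total E) / (p V_D Cbar) with the same tracee
    correction convention the Steele estimator applies."""
    pv = steele.pool_fraction * steele.distribution_volume * 100.0  # umol/kg per mmol/L

    def pool(G, e_inf, e_or):
        tot = e_inf + e_or
        c = G / (1.0 + tot) if tot > 0.01 else G
        return pv * c

    E = np.empty(t_fine.size)
    E[0] = e_basal
    for k in range(t_fine.size - 1):
        h = t_fine[k + 1] - t_fine[k]
        if t_fine[k + 1] <= 0:  # basal steady state
            E[k + 1] = e_basal
            continue
        Gm = 0.5 * (glucose[k] + glucose[k + 1])
        Em_oral = 0.5 * (e_oral[k] + e_oral[k + 1])
        Rm = 0.5 * (ra_total[k] + ra_total[k + 1])

        def f(e, G, eo, R):
            return (F - R * e) / pool(G, e, eo)

        e = E[k]
        k1 = f(e, glucose[k], e_oral[k], ra_total[k])
        k2 = f(e + 0.5 * h * k1, Gm, Em_oral, Rm)
        k3 = f(e + 0.5 * h * k2, Gm, Em_oral, Rm)
        k4 = f(e + h * k3, glucose[k + 1], e_oral[k + 1], ra_total[k + 1])
        E[k + 1] = e + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return E


def generate_subject(spec: ScenarioSpec) -> tuple[OgttTimeSeries, SubjectTruth]:
    """Generate one subject: noisy sampled series plus its ground truth.

    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    proto = spec.protocol
    grid = np.concatenate([
        np.asarray(DEFAULT_BASAL_GRID[:-1], float),
        np.asarray(DEFAULT_SAMPLING_GRID, float),
    ])
    t0, t1 = grid[0], grid[-1]
    fine = np.union1d(grid, t0 + _FINE_DT * np.arange(
        int(round((t1 - t0) / _FINE_DT)) + 1))
    fine = np.union1d(fine, np.asarray(spec.oral_ra_truth.times))
    fine = fine[(fine >= t0) & (fine <= t1 + 1e-12)]

    # Forcing curves.  The truth insulin excursion is evaluated at the
    # sampling grid and interpolated piecewise linearly from there, so the
    # measured insulin samples carry the full forcing information (the
    # minimal model treats insulin as a measured input).
    insulin_grid = spec.insulin_excursion.curve(grid, spec.glucose_params.Ib)
    insulin_f = np.interp(fine, grid, insulin_grid)
    ra_oral_f = spec.oral_ra_truth.curve(fine)
    egp_f = spec.egp_truth.curve(fine)
    ra_total_f = egp_f + ra_oral_f

    post = fine >= 0.0
    glucose_f = np.full(fine.size, spec.glucose_params.Gb)
    glucose_f[post] = simulate_glucose(spec.glucose_params, insulin_f[post],
                                       ra_oral_f[post], fine[post],
                                       dt=_FINE_DT)
    # The secretion model and the tracer pool term see the measured glucose
    # trajectory, i.e. the piecewise-linear interpolant through the samples.
    glucose_pl_f = np.interp(fine, grid, np.interp(grid, fine, glucose_f))
    ct = spec.cp_truth
    cp_f = np.full(fine.size, ct.CPb)
    cp_f[post] = simulate_cpeptide(ct.kinetics, ct.phi_s, ct.phi_d, ct.tau,
                                   spec.glucose_params.Gb, glucose_pl_f[post],
                                   fine[post], ct.CPb, dt=_FINE_DT)

    # tracer bookkeeping
    e_oral_f = np.where(ra_total_f > 0,
                        proto.load_ttr * ra_oral_f / ra_total_f, 0.0)
    e_basal = proto.infusion_rate / spec.egp_truth.basal
    e_inf_f = _integrate_infused_ttr(fine, ra_total_f, e_oral_f, glucose_pl_f,
                                     proto.infusion_rate, spec.steele, e_basal)

    def on_grid(values):
        return np.interp(grid, fine, values)

    clean = OgttTimeSeries(
        time=grid.copy(),
        glucose=on_grid(glucose_f),
        insulin=on_grid(insulin_f),
        cpeptide=on_grid(cp_f),
        ttr_infused=on_grid(e_inf_f),
        ttr_oral=on_grid(e_oral_f),
    )

    def noisy(values, cv):
        if cv <= 0:
            return values.copy()
        sigma = np.sqrt(np.log(1.0 + cv**2))
        return values * np.exp(sigma * rng.standard_normal(values.size))

    noisy_series = OgttTimeSeries(
        time=grid.copy(),
        glucose=noisy(clean.glucose, spec.noise.glucose),
        insulin=noisy(clean.insulin, spec.noise.insulin),
        cpeptide=noisy(clean.cpeptide, spec.noise.cpeptide),
        ttr_infused=noisy(clean.ttr_infused, spec.noise.ttr),
        ttr_oral=noisy(clean.ttr_oral, spec.noise.ttr),
    )

    truth = SubjectTruth(
        glucose_params=spec.glucose_params,
        cp_truth=ct,
        time=grid.copy(),
        ra_oral=on_grid(ra_oral_f),
        ra_total=on_grid(ra_total_f),
        egp=on_grid(egp_f),
        mean_ra_oral=spec.oral_ra_truth.window_mean(0.0, proto.test_duration),
        mean_egp=spec.egp_truth.window_mean(0.0, proto.test_duration),
        clean=clean,
    )
    return noisy_series, truth


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic, collision-resistant child seeds (< 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def generate_cohort(out_dir, n_per_arm: int = 4, master_seed: int = 0,
                    arms: tuple = ("sham", "device", "drug"),
                    body_weight: float = 55.0,
                    noise: NoiseSpec | None = None) -> dict:
    """Write a cohort of per-subject CSVs plus a JSON manifest.

    The manifest records, for every subject, its arm, seed, file name and
    truth parameters, so the dataset round-trips through the readers.
    Returns the manifest as a dict.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(master_seed, n_per_arm * len(arms))
    manifest = {"master_seed": int(master_seed), "n_per_arm": n_per_arm,
                "subjects": []}
    i = 0
    for arm in arms:
        for j in range(n_per_arm):
            seed = seeds[i]
            i += 1
            spec = arm_scenario(arm, body_weight=body_weight, seed=seed,
                                noise=noise)
            series, truth = generate_subject(spec)
            fname = f"{arm}_{j + 1:02d}.csv"
            path = out / fname
            if path.exists():
                raise FileExistsError(f"refusing to overwrite {path}")
            write_ogtt_csv(series, path)
            gp = truth.glucose_params
            manifest["subjects"].append({
                "file": fname, "arm": arm, "seed": seed,
                "body_weight": body_weight,
                "truth": {
                    "SG": gp.SG, "SI": gp.SI, "p": gp.p, "VG": gp.VG,
                    "Gb": gp.Gb, "Ib": gp.Ib,
                    "phi_s": truth.cp_truth.phi_s,
                    "phi_d": truth.cp_truth.phi_d,
                    "tau": truth.cp_truth.tau,
                    "CPb": truth.cp_truth.CPb,
                    "mean_ra_oral": truth.mean_ra_oral,
                    "mean_egp": truth.mean_egp,
                },
            })
    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
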