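"""Domain types and I/O for dual-tracer OGTT time series.

A subject's test is a set of timed samples of plasma glucose, insulin,
C-peptide, and the tracer-to-tracee ratios (TTR) of two glucose tracers:
one infused intravenously at a constant rate ([6,6-2H2]-glucose, to trace
total glucose turnover) and one mixed into the oral load ([U-13C]-glucose,
to trace appearance of the ingested glucose).

Canonical internal units: minutes, mmol/L (glucose), pM (insulin and
C-peptide), dimensionless TTR, and umol/kg/min for fluxes.  Time t=0 is
administration of the oral load; samples with t <= 0 belong to the basal
isotope-equilibration period.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    InsufficientBasalError,
    ProtocolError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "ArmLabel",
    "OgttTimeSeries",
    "SubjectProtocol",
    "BasalState",
    "DEFAULT_SAMPLING_GRID",
    "MGDL_PER_MMOLL",
    "PM_PER_MUL",
    "basal_means",
    "resample_linear",
    "read_ogtt_csv",
    "write_ogtt_csv",
    "convert_units",
]

#: mg/dL per mmol/L of glucose (molar mass 180.16 g/mol -> 18.016 mg per mmol).
MGDL_PER_MMOLL = 18.016

#: pM of insulin per mU/L (1 mU/L = 6.00 pM, the conventional ELISA bridge).
PM_PER_MUL = 6.0

#: Post-load sampling grid (min): 0, 5, 10, 15, 20, 25, then every 10 min
#: to 175, plus 180.
DEFAULT_SAMPLING_GRID = tuple([0, 5, 10, 15, 20, 25] + list(range(35, 176, 10)) + [180])

#: Basal-period sample times used by the synthetic generator (min).
DEFAULT_BASAL_GRID = (-30.0, -15.0, 0.0)

_CHANNELS = ("glucose", "insulin", "cpeptide", "ttr_infused", "ttr_oral")
_REQUIRED_COLUMNS = ("time_min",) + _CHANNELS


class ArmLabel(str, enum.Enum):
    """Treatment arm of the study design: sham endoscopy (control),
    endoscopic bypass device, or GLP-1 receptor-agonist drug."""

    SHAM = "sham"
    DEVICE = "device"
    DRUG = "drug"


@dataclass(frozen=True)
class SubjectProtocol:
    """Tracer/OGTT protocol constants for one subject.

    Parameters
    ----------
    body_weight : float
        Subject body weight, kg.
    prime : float
        Priming dose of the infused tracer, umol/kg.
    infusion_rate : float
        Constant infusion rate of the infused tracer, umol/kg/min.
    oral_glucose_dose : float
        Oral glucose load, g.
    oral_tracer_dose : float
        Oral tracer mixed into the load, g.
    basal_duration : float
        Length of the basal isotope-equilibration period, min.
    test_duration : float
        Length of the post-load sampling window, min.
    """

    body_weight: float
    prime: float = 32.0
    infusion_rate: float = 0.32
    oral_glucose_dose: float = 75.0
    oral_tracer_dose: float = 0.9
    basal_duration: float = 120.0
    test_duration: float = 180.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ProtocolError(f"protocol field {f.name!r} must be positive, got {v!r}")

    @property
    def load_ttr(self) -> float:
        """Tracer-to-tracee ratio of the ingested load (oral tracer mass /
        oral glucose mass)."""
        return self.oral_tracer_dose / self.oral_glucose_dose

    @classmethod
    def from_yaml(cls, path) -> "SubjectProtocol":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ProtocolError(f"protocol file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ProtocolError(f"unknown protocol keys: {sorted(unknown)}")
        if "body_weight" not in raw:
            raise ProtocolError("protocol file must set body_weight")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass(frozen=True)
class OgttTimeSeries:
    """One subject's sampled OGTT/tracer curves.

    All arrays share the sample grid ``time`` (min, strictly increasing,
    need not be uniform).  Samples with ``time <= 0`` are basal.
    """

    time: np.ndarray
    glucose: np.ndarray  # mmol/L
    insulin: np.ndarray  # pM
    cpeptide: np.ndarray  # pM
    ttr_infused: np.ndarray  # dimensionless
    ttr_oral: np.ndarray  # dimensionless

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("time",) + _CHANNELS:
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim != 1:
                raise ValidationError(f"{name} must be 1-D")
            arrays[name] = a
            object.__setattr__(self, name, a)
        n = arrays["time"].size
        for name, a in arrays.items():
            if a.size != n:
                raise ValidationError(
                    f"channel {name!r} has length {a.size}, expected {n}"
                )
        if n < 2:
            raise ValidationError("need at least 2 samples")
        if not np.all(np.diff(arrays["time"]) > 0):
            raise ValidationError("time must be strictly increasing")
        for name in ("glucose", "insulin", "cpeptide"):
            if np.any(arrays[name] < 0):
                raise ValidationError(f"negative concentration in channel {name!r}")
        for name in ("ttr_infused", "ttr_oral"):
            a = arrays[name]
            if np.any((a < 0) | (a >= 1)):
                raise ValidationError(f"TTR channel {name!r} must lie in [0, 1)")

    def __len__(self) -> int:
        return self.time.size

    @property
    def basal_mask(self) -> np.ndarray:
        """Boolean mask of basal samples (t <= 0)."""
        return self.time <= 0.0

    @property
    def n_basal(self) -> int:
        return int(self.basal_mask.sum())

    def channel(self, name: str) -> np.ndarray:
        if name not in _CHANNELS:
            raise ValueError(f"unknown channel {name!r}; one of {_CHANNELS}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.time, **{c: getattr(self, c) for c in _CHANNELS}}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OgttTimeSeries":
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        return cls(
            time=frame["time_min"].to_numpy(float),
            **{c: frame[c].to_numpy(float) for c in _CHANNELS},
        )


@dataclass(frozen=True)
class BasalState:
    """Basal (pre-load) averages used as model baselines."""

    Gb: float  # mmol/L
    Ib: float  # pM
    CPb: float  # pM
    Eb_infused: float  # dimensionless
    Eb_oral: float  # dimensionless


def basal_means(series: OgttTimeSeries, min_samples: int = 3) -> BasalState:
    """Arithmetic means of every channel over the basal (t <= 0) samples.

    Raises
    ------
    InsufficientBasalError
        If fewer than ``min_samples`` basal samples are present.
    ValidationError
        If the basal glucose or insulin mean is not positive.
    """
    m = series.basal_mask
    if int(m.sum()) < min_samples:
        raise InsufficientBasalError(
            f"need >= {min_samples} basal samples (t <= 0), found {int(m.sum())}"
        )
    state = BasalState(
        Gb=float(series.glucose[m].mean()),
        Ib=float(series.insulin[m].mean()),
        CPb=float(series.cpeptide[m].mean()),
        Eb_infused=float(series.ttr_infused[m].mean()),
        Eb_oral=float(series.ttr_oral[m].mean()),
    )
    if state.Gb <= 0 or state.Ib <= 0:
        raise ValidationError("basal glucose and insulin means must be positive")
    return state


def resample_linear(series: OgttTimeSeries, dt: float) -> OgttTimeSeries:
    """Resample every channel onto a uniform grid by linear interpolation.

    The grid starts at the first sample time and steps by ``dt``; the final
    observed time is always included so the endpoints are preserved exactly.
    """
    if not np.isfinite(dt) or dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    t0, t1 = float(series.time[0]), float(series.time[-1])
    grid = t0 + dt * np.arange(int(np.floor((t1 - t0) / dt + 1e-9)) + 1)
    if grid[-1] < t1 - 1e-9:
        grid = np.append(grid, t1)
    else:
        grid[-1] = t1
    return OgttTimeSeries(
        time=grid,
        **{c: np.interp(grid, series.time, getattr(series, c)) for c in _CHANNELS},
    )


def convert_units(values, quantity: str, unit: str) -> np.ndarray:
    """Convert raw values of ``quantity`` expressed in ``unit`` to canonical
    internal units.

    Supported: glucose in {"mmol/L", "mg/dL"}; insulin/cpeptide in
    {"pM", "pmol/L", "mU/L"} (mU/L applies the 6.0 pM per mU/L bridge,
    conventionally used for insulin immunoassays).  TTRs are dimensionless.
    """
    v = np.asarray(values, dtype=float)
    u = unit.strip()
    if quantity == "glucose":
        if u in ("mmol/L", "mmol/l"):
            return v
        if u.lower() == "mg/dl":
            return v / MGDL_PER_MMOLL
    elif quantity in ("insulin", "cpeptide"):
        if u in ("pM", "pmol/L", "pmol/l"):
            return v
        if u.lower() == "mu/l":
            return v * PM_PER_MUL
    elif quantity in ("ttr_infused", "ttr_oral"):
        if u in ("", "1", "ratio", "dimensionless"):
            return v
    raise ValueError(f"unsupported unit {unit!r} for {quantity!r}")


def read_ogtt_csv(path, protocol: SubjectProtocol | None = None,
                  units: dict[str, str] | None = None) -> OgttTimeSeries:
    """Read a per-subject OGTT CSV into an :class:`OgttTimeSeries`.

    The file must have a header row with columns ``time_min, glucose,
    insulin, cpeptide, ttr_infused, ttr_oral`` (comma-separated, decimal
    point, UTF-8).  ``units`` optionally maps a channel name to the unit its
    column is expressed in (e.g. ``{"glucose": "mg/dL"}``); conversion to
    canonical units is applied on read.

    The ``protocol``, when given, is used to sanity-check that no sample
    falls beyond the protocol's test duration.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    if frame[list(_REQUIRED_COLUMNS)].isna().any().any():
        raise ValidationError(f"{path}: NaN values in required columns")
    data = {"time": frame["time_min"].to_numpy(float)}
    for c in _CHANNELS:
        raw = frame[c].to_numpy(float)
        if units and c in units:
            raw = convert_units(raw, c, units[c])
        data[c] = raw
    series = OgttTimeSeries(**data)
    if protocol is not None and series.time[-1] > protocol.test_duration + 1e-9:
        raise ProtocolError(
            f"last sample at t={series.time[-1]:g} min exceeds protocol "
            f"test_duration={protocol.test_duration:g} min"
        )
    return series


def write_ogtt_csv(series: OgttTimeSeries, path, float_format: str = "%.10g") -> None:
    """Write a series to CSV in canonical units (round-trips with
    :func:`read_ogtt_csv` at the declared precision)."""
    series.to_frame().to_csv(path, index=False, float_format=float_format)
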