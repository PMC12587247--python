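"""Data types, CSV round trips, unit conversion, basal means, resampling."""

import numpy as np
import pytest

from ogttkit.data import (
    MGDL_PER_MMOLL,
    PM_PER_MUL,
    OgttTimeSeries,
    SubjectProtocol,
    basal_means,
    convert_units,
    read_ogtt_csv,
    resample_linear,
    write_ogtt_csv,
)
from ogttkit.exceptions import (
    InsufficientBasalError,
    ProtocolError,
    SchemaError,
    ValidationError,
)


def make_series(n=8, t0=-20.0):
    t = np.linspace(t0, 180.0, n)
    return OgttTimeSeries(
        time=t,
        glucose=5.0 + 0.01 * np.clip(t, 0, None),
        insulin=60.0 + np.clip(t, 0, None),
        cpeptide=250.0 + np.clip(t, 0, None),
        ttr_infused=np.full(n, 0.03),
        ttr_oral=np.full(n, 0.004),
    )


class TestValidation:
    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValidationError, match="strictly increasing"):
            OgttTimeSeries(time=[0, 10, 5], glucose=[5, 5, 5],
                           insulin=[60, 60, 60], cpeptide=[250, 250, 250],
                           ttr_infused=[0.03] * 3, ttr_oral=[0.0] * 3)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError, match="glucose"):
            OgttTimeSeries(time=[0, 10], glucose=[5, -1],
                           insulin=[60, 60], cpeptide=[250, 250],
                           ttr_infused=[0.03] * 2, ttr_oral=[0.0] * 2)

    @pytest.mark.parametrize("bad", [-0.01, 1.0, 1.5])
    def test_ttr_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValidationError, match="TTR"):
            OgttTimeSeries(time=[0, 10], glucose=[5, 5], insulin=[60, 60],
                           cpeptide=[250, 250], ttr_infused=[0.03, bad],
                           ttr_oral=[0.0, 0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            OgttTimeSeries(time=[0, 10], glucose=[5, 5, 5], insulin=[60, 60],
                           cpeptide=[250, 250], ttr_infused=[0.03] * 2,
                           ttr_oral=[0.0] * 2)


class TestCsvIo:
    def test_round_trip_bit_exact(self, tmp_path):
        series = make_series()
        path = tmp_path / "subj.csv"
        write_ogtt_csv(series, path, float_format="%.17g")
        back = read_ogtt_csv(path)
        for ch in ("time", "glucose", "insulin", "cpeptide",
                   "ttr_infused", "ttr_oral"):
            np.testing.assert_array_equal(getattr(back, ch),
                                          getattr(series, ch))

    def test_missing_column_names_the_column(self, tmp_path):
        frame = make_series().to_frame().drop(columns=["cpeptide"])
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="cpeptide"):
            read_ogtt_csv(path)

    def test_shuffled_time_rejected(self, tmp_path):
        frame = make_series().to_frame().sample(frac=1.0, random_state=0)
        path = tmp_path / "shuffled.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(ValidationError):
            read_ogtt_csv(path)

    def test_mgdl_header_units_divide_by_18(self, tmp_path):
        # three hand-converted rows: 90, 126, 180 mg/dL
        frame = make_series(n=3, t0=-20).to_frame()
        frame["glucose"] = [90.0, 126.0, 180.0]
        path = tmp_path / "mgdl.csv"
        frame.to_csv(path, index=False)
        back = read_ogtt_csv(path, units={"glucose": "mg/dL"})
        np.testing.assert_allclose(
            back.glucose,
            [90.0 / 18.016, 126.0 / 18.016, 180.0 / 18.016], rtol=1e-12)

    def test_sample_beyond_protocol_duration_rejected(self, tmp_path):
        series = make_series()
        path = tmp_path / "long.csv"
        write_ogtt_csv(series, path)
        proto = SubjectProtocol(body_weight=55.0, test_duration=120.0)
        with pytest.raises(ProtocolError, match="test_duration"):
            read_ogtt_csv(path, protocol=proto)


class TestUnits:
    @pytest.mark.parametrize("quantity,unit,factor", [
        ("glucose", "mg/dL", 1.0 / MGDL_PER_MMOLL),
        ("insulin", "mU/L", PM_PER_MUL),
        ("cpeptide", "mU/L", PM_PER_MUL),
    ])
    def test_conversion_involutive(self, quantity, unit, factor):
        raw = np.array([1.0, 17.3, 250.0])
        converted = convert_units(raw, quantity, unit)
        np.testing.assert_allclose(converted / factor, raw, rtol=1e-12)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unsupported unit"):
            convert_units([1.0], "glucose", "furlongs")


class TestBasalMeans:
    def _series_with_basal(self, glucose, insulin=60.0, ttr=0.02):
        n = len(glucose) + 2
        t = np.concatenate([np.linspace(-30, 0, len(glucose)), [10, 20]])
        g = np.concatenate([glucose, [6.0, 6.5]])
        return OgttTimeSeries(
            time=t, glucose=g, insulin=np.full(n, insulin),
            cpeptide=np.full(n, 250.0), ttr_infused=np.full(n, ttr),
            ttr_oral=np.zeros(n))

    def test_symmetric_basal_glucose(self):
        state = basal_means(self._series_with_basal([5.0, 5.2, 4.8]))
        assert state.Gb == pytest.approx(5.0, abs=1e-12)

    def test_constant_basal_insulin(self):
        state = basal_means(self._series_with_basal([5.0, 5.0, 5.0],
                                                    insulin=60.0))
        assert state.Ib == pytest.approx(60.0, abs=1e-12)

    def test_ttr_arithmetic_mean(self):
        t = np.array([-20.0, -10.0, 0.0, 10.0])
        series = OgttTimeSeries(
            time=t, glucose=np.full(4, 5.0), insulin=np.full(4, 60.0),
            cpeptide=np.full(4, 250.0),
            ttr_infused=np.array([0.019, 0.020, 0.021, 0.02]),
            ttr_oral=np.zeros(4))
        assert basal_means(series).Eb_infused == pytest.approx(0.020, abs=1e-15)

    def test_too_few_basal_samples(self):
        series = make_series(t0=-5.0)  # only one t <= 0
        with pytest.raises(InsufficientBasalError):
            basal_means(series)


class TestResample:
    def test_linear_ramp_exact_at_midpoints(self):
        t = np.array([-10.0, 0.0, 10.0, 20.0])
        series = OgttTimeSeries(
            time=t, glucose=5.0 + 0.1 * (t + 10), insulin=np.full(4, 60.0),
            cpeptide=np.full(4, 250.0), ttr_infused=np.full(4, 0.03),
            ttr_oral=np.zeros(4))
        out = resample_linear(series, dt=5.0)
        np.testing.assert_allclose(out.glucose, 5.0 + 0.1 * (out.time + 10),
                                   rtol=1e-14)
        assert out.time[0] == t[0] and out.time[-1] == t[-1]

    def test_native_spacing_is_identity(self):
        series = make_series(n=5, t0=0.0)
        dt = float(series.time[1] - series.time[0])
        out = resample_linear(series, dt)
        np.testing.assert_allclose(out.glucose, series.glucose, rtol=1e-12)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            resample_linear(make_series(), 0.0)

    def test_smooth_curve_deviation_bounded_by_curvature(self):
        # piecewise-linear interpolation error <= max|f''| h^2 / 8
        t = np.arange(0.0, 181.0, 10.0)
        f = lambda x: 5.0 + np.sin(x / 30.0)
        series = OgttTimeSeries(
            time=t, glucose=f(t), insulin=np.full(t.size, 60.0),
            cpeptide=np.full(t.size, 250.0), ttr_infused=np.full(t.size, 0.03),
            ttr_oral=np.zeros(t.size))
        dense = resample_linear(series, dt=1.0)
        bound = (1.0 / 30.0**2) * 10.0**2 / 8.0
        assert np.max(np.abs(dense.glucose - f(dense.time))) <= bound + 1e-12


class TestProtocol:
    def test_defaults_match_design(self):
        proto = SubjectProtocol(body_weight=55.0)
        assert proto.prime == 32.0
        assert proto.infusion_rate == 0.32
        assert proto.load_ttr == pytest.approx(0.9 / 75.0)

    def test_yaml_round_trip(self, tmp_path):
        proto = SubjectProtocol(body_weight=48.5, prime=30.0)
        path = tmp_path / "proto.yaml"
        proto.to_yaml(path)
        assert SubjectProtocol.from_yaml(path) == proto

    @pytest.mark.parametrize("kwargs", [
        {"body_weight": -1.0},
        {"body_weight": 55.0, "infusion_rate": 0.0},
    ])
    def test_nonpositive_fields_rejected(self, kwargs):
        with pytest.raises(ProtocolError):
            SubjectProtocol(**kwargs)
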