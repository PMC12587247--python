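"""Steele non-steady-state fluxes: derivatives, Ra partitioning, EGP,
absorption percentages, window means."""

import numpy as np
import pytest

from ogttkit.data import OgttTimeSeries, SubjectProtocol
from ogttkit.exceptions import DivisionGuardError, GridMismatchError
from ogttkit.fluxes import (
    FluxProfile,
    GLUCOSE_MOLAR_MASS,
    Smoother,
    SteeleConfig,
    compute_fluxes,
    egp_profile,
    mean_flux,
    percent_ingested_appearing,
    steele_ra_oral,
    steele_ra_total,
    ttr_derivative,
)
from ogttkit.synthetic import ZERO_NOISE
import ogttkit as ok

PROTO = SubjectProtocol(body_weight=55.0)


def flat_series(n=10, e_inf=0.02, e_oral=0.0, glucose=5.0):
    t = np.linspace(-20.0, 160.0, n)
    return OgttTimeSeries(
        time=t, glucose=np.full(n, glucose), insulin=np.full(n, 60.0),
        cpeptide=np.full(n, 250.0), ttr_infused=np.full(n, e_inf),
        ttr_oral=np.full(n, e_oral))


class TestTtrDerivative:
    def test_constant_channel_zero_everywhere(self):
        series = flat_series()
        for sm in (Smoother.LINEAR_SLOPE, Smoother.SPLINE_CONTRACT):
            d = ttr_derivative(series, "ttr_infused", SteeleConfig(smoother=sm))
            np.testing.assert_array_equal(d, np.zeros(len(series)))

    def test_linear_channel_recovers_slope(self):
        t = np.linspace(0.0, 100.0, 11)
        series = OgttTimeSeries(
            time=t, glucose=np.full(11, 5.0), insulin=np.full(11, 60.0),
            cpeptide=np.full(11, 250.0), ttr_infused=0.02 - 1e-4 * t,
            ttr_oral=np.zeros(11))
        d = ttr_derivative(series, "ttr_infused")
        np.testing.assert_allclose(d, np.full(11, -1e-4), rtol=1e-10)

    def test_spline_tracks_analytic_slope_of_noisy_curve(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 181.0, 5.0)
        truth = 0.025 + 0.005 * np.sin(t / 40.0)
        dtruth = (0.005 / 40.0) * np.cos(t / 40.0)
        noisy = truth * (1.0 + 0.005 * rng.standard_normal(t.size))
        series = OgttTimeSeries(
            time=t, glucose=np.full(t.size, 5.0),
            insulin=np.full(t.size, 60.0), cpeptide=np.full(t.size, 250.0),
            ttr_infused=noisy, ttr_oral=np.zeros(t.size))
        d = ttr_derivative(series, "ttr_infused",
                           SteeleConfig(smoother=Smoother.SPLINE_CONTRACT))
        rms = np.sqrt(np.mean((d - dtruth) ** 2))
        assert rms < 0.5 * np.max(np.abs(dtruth))

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            ttr_derivative(flat_series(), "glucose")


class TestSteeleRaTotal:
    def test_steady_state_equals_infusion_over_enrichment(self):
        series = flat_series(e_inf=0.02)
        ra = steele_ra_total(series, PROTO)
        np.testing.assert_allclose(ra, 0.32 / 0.02, rtol=1e-12)

    def test_doubling_enrichment_halves_ra(self):
        ra1 = steele_ra_total(flat_series(e_inf=0.02), PROTO)
        ra2 = steele_ra_total(flat_series(e_inf=0.04), PROTO)
        np.testing.assert_allclose(ra1, 2.0 * ra2, rtol=1e-12)

    def test_zero_enrichment_names_sample_time(self):
        series = flat_series(e_inf=0.02)
        bad = OgttTimeSeries(
            time=series.time, glucose=series.glucose, insulin=series.insulin,
            cpeptide=series.cpeptide,
            ttr_infused=np.where(series.time == series.time[3], 0.0, 0.02),
            ttr_oral=series.ttr_oral)
        with pytest.raises(DivisionGuardError, match=f"{series.time[3]:g}"):
            steele_ra_total(bad, PROTO)


class TestOralPartition:
    def test_zero_oral_enrichment_gives_zero_oral_ra(self):
        series = flat_series(e_oral=0.0)
        np.testing.assert_array_equal(steele_ra_oral(series, PROTO),
                                      np.zeros(len(series)))

    def test_load_enrichment_limit_recovers_total(self):
        # all plasma glucose oral-derived: E_oral == load TTR -> oral == total
        series = flat_series(e_oral=PROTO.load_ttr)
        total = steele_ra_total(series, PROTO)
        oral = steele_ra_oral(series, PROTO)
        np.testing.assert_allclose(oral, total, rtol=1e-12)


class TestEgp:
    def test_pointwise_difference(self):
        np.testing.assert_array_equal(
            egp_profile(np.array([10.0, 10.0]), np.array([4.0, 4.0])),
            np.array([6.0, 6.0]))

    def test_total_equals_oral_gives_zero(self):
        x = np.array([3.0, 7.0, 5.0])
        np.testing.assert_array_equal(egp_profile(x, x), np.zeros(3))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            egp_profile(np.ones(4), np.ones(3))

    def test_conservation_identity_on_profile(self, sham_fluxes):
        np.testing.assert_allclose(
            sham_fluxes.egp + sham_fluxes.ra_oral, sham_fluxes.ra_total,
            rtol=1e-12, atol=1e-12)

    def test_negative_values_flagged_and_optionally_clipped(self):
        t = np.linspace(-20, 60, 6)
        # falling infused TTR fast enough to push the estimator negative
        series = OgttTimeSeries(
            time=t, glucose=np.full(6, 5.0), insulin=np.full(6, 60.0),
            cpeptide=np.full(6, 250.0),
            ttr_infused=np.clip(0.02 + 2e-3 * np.clip(t, 0, None), 1e-4, 0.9),
            ttr_oral=np.full(6, 0.011))
        raw = compute_fluxes(series, PROTO, SteeleConfig(clip_negative=False))
        assert raw.negative_flag.any()
        assert (raw.egp < 0).any()
        clipped = compute_fluxes(series, PROTO, SteeleConfig(clip_negative=True))
        assert (clipped.egp >= 0).all()
        assert clipped.negative_flag.any()  # flags survive clipping


class TestPercentIngested:
    def test_zero_oral_ra_is_zero_percent(self):
        t = np.linspace(0, 180, 19)
        assert percent_ingested_appearing(t, np.zeros(19), PROTO) == 0.0

    def test_constructed_full_dose_is_100_percent(self):
        # constant oral Ra sized so the 180-min integral equals the dose
        t = np.linspace(0.0, 180.0, 181)
        ra = PROTO.oral_glucose_dose * 1e6 / (
            GLUCOSE_MOLAR_MASS * PROTO.body_weight * 180.0)
        pct = percent_ingested_appearing(t, np.full(t.size, ra), PROTO)
        assert pct == pytest.approx(100.0, rel=1e-9)

    def test_halving_body_weight_halves_percent(self):
        t = np.linspace(0.0, 180.0, 19)
        ra = np.full(19, 2.0)
        light = SubjectProtocol(body_weight=PROTO.body_weight / 2)
        assert percent_ingested_appearing(t, ra, light) == pytest.approx(
            percent_ingested_appearing(t, ra, PROTO) / 2, rel=1e-12)


class TestMeanFlux:
    def _profile(self, t, v):
        return FluxProfile(time=t, ra_total=v, ra_oral=np.zeros_like(v),
                           egp=v, negative_flag=np.zeros(t.size, bool))

    def test_constant_profile(self):
        t = np.linspace(0, 180, 10)
        prof = self._profile(t, np.full(10, 3.3))
        assert mean_flux(prof, "ra_total", (0, 180)) == pytest.approx(3.3)

    def test_linear_ramp_gives_midpoint(self):
        t = np.linspace(0, 180, 10)
        prof = self._profile(t, 10.0 * t / 180.0)
        assert mean_flux(prof, "ra_total", (0, 180)) == pytest.approx(5.0)

    def test_matches_fine_riemann_oracle(self):
        rng = np.random.default_rng(11)
        t = np.sort(rng.uniform(0, 180, 15))
        t[0], t[-1] = 0.0, 180.0
        v = rng.uniform(0, 10, 15)
        prof = self._profile(t, v)
        got = mean_flux(prof, "ra_total", (20.0, 160.0))
        tt = np.linspace(20.0, 160.0, 200001)
        oracle = np.mean(np.interp(tt, t, v))
        assert got == pytest.approx(oracle, rel=1e-5)

    def test_empty_or_outside_window_rejected(self):
        prof = self._profile(np.linspace(0, 180, 10), np.ones(10))
        with pytest.raises(ValueError):
            mean_flux(prof, "ra_total", (50, 50))
        with pytest.raises(ValueError):
            mean_flux(prof, "ra_total", (-10, 50))


class TestRoundTripRecovery:
    """Zero-noise simulator output must give back the truth fluxes."""

    @pytest.mark.parametrize("arm", ["sham", "device", "drug"])
    def test_mean_fluxes_within_5_percent(self, arm):
        spec = ok.arm_scenario(arm, seed=3, noise=ZERO_NOISE)
        series, truth = ok.generate_subject(spec)
        prof = compute_fluxes(series, spec.protocol)
        for ch, target in (("ra_oral", truth.mean_ra_oral),
                           ("egp", truth.mean_egp)):
            est = mean_flux(prof, ch, (0.0, 180.0))
            assert est == pytest.approx(target, rel=0.05)

    def test_ra_total_profile_rms_within_5_percent(self, sham_noiseless,
                                                   sham_fluxes):
        _, _, truth = sham_noiseless
        post = sham_fluxes.time >= 0
        err = sham_fluxes.ra_total[post] - truth.ra_total[post]
        rms = np.sqrt(np.mean(err**2))
        scale = np.sqrt(np.mean(truth.ra_total[post] ** 2))
        assert rms / scale < 0.05
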