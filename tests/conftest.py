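"""Shared fixtures: synthetic subjects and (expensive) fitted models are
generated once per session and reused across test modules."""

import pytest

import ogttkit as ok
from ogttkit.synthetic import ZERO_NOISE


@pytest.fixture(scope="session")
def sham_noiseless():
    """Noiseless sham-arm subject with its ground truth."""
    spec = ok.arm_scenario("sham", seed=1, noise=ZERO_NOISE)
    series, truth = ok.generate_subject(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def device_noiseless():
    spec = ok.arm_scenario("device", seed=2, noise=ZERO_NOISE)
    series, truth = ok.generate_subject(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def sham_fluxes(sham_noiseless):
    spec, series, _ = sham_noiseless
    return ok.compute_fluxes(series, spec.protocol)


@pytest.fixture(scope="session")
def glucose_fit_sham(sham_noiseless):
    """Oral-minimal-model fit of the noiseless sham subject, driven by the
    truth oral Ra forcing."""
    _, series, truth = sham_noiseless
    return ok.GlucoseMinimalModel(series, truth.ra_oral).fit()


@pytest.fixture(scope="session")
def cpeptide_fit_sham(sham_noiseless):
    spec, series, _ = sham_noiseless
    model = ok.CPeptideMinimalModel(series, spec.cp_truth.kinetics,
                                    body_weight=spec.protocol.body_weight)
    return model.fit()


@pytest.fixture(scope="session")
def ni_replicated():
    """1000-replicate non-inferiority study at the group means of the
    emulated design (comparator 3.11, device 2.09, drug 3.50; CV 30%,
    12 subjects per group, margin 0.80)."""
    return ok.replicate_noninferiority(
        {"sham": 3.11, "device": 2.09, "drug": 3.50},
        cv=0.30, n_per_group=12, margin=0.80, n_reps=1000, seed=20260925)
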