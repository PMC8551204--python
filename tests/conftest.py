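"""Shared fixtures: small synthetic protocols, noise-free truths and trials."""

from dataclasses import replace

import pytest

import splitgait as sg
from splitgait import synthetic_data as sd


def strip_noise(laws):
    """Zero out the step-to-step noise of every adaptation law."""
    return {p: {f: replace(law, noise_sd=0.0) for f, law in d.items()}
            for p, d in laws.items()}


@pytest.fixture(scope="session")
def short_protocol():
    return sg.default_protocol(baseline_s=40.0, split_s=60.0, after_s=30.0)


@pytest.fixture(scope="session")
def outcome_protocol():
    """Long enough split for the last-50 + 9-step plateau rule per stride."""
    return sg.default_protocol(baseline_s=40.0, split_s=100.0, after_s=30.0)


@pytest.fixture(scope="session")
def clean_truth(short_protocol):
    """Noise-free step truth with a young-style CoM asymmetry."""
    laws = strip_noise(sd.default_laws(com_asym=0.02, cop_disp_asym=0.008))
    return sg.generate_step_truth(short_protocol, laws, seed=11)


@pytest.fixture(scope="session")
def clean_signal_params():
    return sg.SignalParams(marker_noise_sd=0.0, cop_noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_split_trial(clean_truth, clean_signal_params):
    return sg.synthesize_trial(clean_truth, "split", clean_signal_params, seed=12)


@pytest.fixture(scope="session")
def noisy_split_trial(short_protocol):
    """Split trial with 2 mm marker noise on top of noisy step truth."""
    truth = sg.generate_step_truth(
        short_protocol, sd.default_laws(com_asym=0.02, cop_disp_asym=0.008), seed=21)
    params = sg.SignalParams(marker_noise_sd=0.002, cop_noise_sd=0.002)
    return truth, sg.synthesize_trial(truth, "split", params, seed=22)
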