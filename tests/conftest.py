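import numpy as np
import pytest

from spinefate import RunConfig, StimulusProtocol, epscat, synthetic


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig(seed=0)


@pytest.fixture(scope="session")
def single_pulse() -> StimulusProtocol:
    """One light pulse — isolates per-pulse statistics from paired-pulse summation."""
    return StimulusProtocol("single", n_pulses=1, pulse_rate_hz=1.0)


@pytest.fixture(scope="session")
def clean_template(cfg, single_pulse):
    """Template fitted to a noiseless deterministic single-pulse trial."""
    model = cfg.synapse_model(p_release=1.0, amplitude_cv=0.0, noise_sd=1e-12)
    traces, _ = synthetic.generate_trial_set(model, single_pulse, n_trials=1,
                                             seed=0)
    tpl = epscat.fit_template(epscat.mean_trace(traces))
    assert tpl is not None
    return tpl


@pytest.fixture(scope="session")
def paired_template(cfg):
    model = cfg.synapse_model(p_release=1.0, amplitude_cv=0.0, noise_sd=1e-12)
    traces, _ = synthetic.generate_trial_set(model, cfg.protocol("test"),
                                             n_trials=1, seed=0)
    tpl = epscat.fit_template(epscat.mean_trace(traces))
    assert tpl is not None
    return tpl
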