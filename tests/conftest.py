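import numpy as np
import pytest

from optopulse import stimuli, synth


@pytest.fixture(scope="session")
def default_protocol():
    """One realized default semi-stochastic protocol (20 iterations)."""
    return stimuli.make_semistochastic(seed=12345)


@pytest.fixture(scope="session")
def small_protocol():
    """Reduced schedule (6 iterations) for faster unit tests."""
    return stimuli.make_semistochastic(seed=54321, n_iterations=6)


@pytest.fixture(scope="session")
def train_100pps():
    return stimuli.make_pulse_train(rate=100.0, duration=1.6, train_len=400.0,
                                    dark_len=100.0, intensity=35.0)


@pytest.fixture()
def deterministic_params():
    """Unit that fires on every pulse at a fixed latency, nothing else."""
    return synth.NeuronParams(
        q50=-100.0, slope=1.0, adapt_depletion=0.0, block_rate=1e9,
        spont_rate=0.0, latency_sd=0.0, latency_drive_mu=0.0,
        latency_drive_sd=0.0,
    )


def constant_p_params(p, duration, intensity, **kw):
    """NeuronParams whose per-pulse probability equals p for the given pulse."""
    slope = kw.pop("slope", 5.0)
    tau_int = kw.pop("tau_int", 1.8)
    charge = intensity * min(duration, tau_int)
    q50 = charge - slope * np.log(p / (1.0 - p))
    defaults = dict(adapt_depletion=0.0, block_rate=1e9, spont_rate=0.0)
    defaults.update(kw)
    return synth.NeuronParams(q50=q50, slope=slope, tau_int=tau_int, **defaults)
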