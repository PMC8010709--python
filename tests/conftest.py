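import numpy as np
import pytest

from bindkit import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def true_steps_of(config: syn.TraceGenConfig):
    """Ground-truth step indices and sizes for a trace config: regenerate
    the noiseless counterpart and read the staircase jumps."""
    noiseless = syn.TraceGenConfig(
        dwell_mean=config.dwell_mean,
        step_sizes=config.step_sizes,
        back_step_prob=config.back_step_prob,
        noise_sd=0.0,
        sample_rate=config.sample_rate,
        duration=config.duration,
        detach_rate=config.detach_rate,
        n_spikes=config.n_spikes,
        seed=config.seed,
    )
    tr = syn.gen_motility_trace(noiseless)
    d = np.diff(tr.position)
    idx = np.nonzero(d)[0]
    return idx, d[idx]
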