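import numpy as np
import pytest

from ecgrpm.synth import SynthSpec, synth_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_record():
    """Noiseless synthetic record: 4 beats of each class, seed fixed."""
    spec = SynthSpec(n_beats={c: 4 for c in "NLRAV"}, noise_snr_db=None,
                     baseline_wander_mv=0.0, amp_jitter=0.0, seed=11)
    return synth_record(spec)


@pytest.fixture
def noisy_record():
    spec = SynthSpec(n_beats={c: 4 for c in "NLRAV"}, noise_snr_db=15.0,
                     seed=11)
    return synth_record(spec)
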