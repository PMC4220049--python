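import numpy as np
import pytest

from cirsseq.reactivity import compute_profile
from cirsseq.simulate import SimParams, simulate_dataset


def profiles_for(transcripts, counts, **kwargs):
    return [
        compute_profile(t, counts[(t.id, "DMS")], counts[(t.id, "CMCT")], counts[(t.id, "NT")], **kwargs)
        for t in transcripts
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """30 structured transcripts at default signal parameters, with profiles."""
    params = SimParams(n_transcripts=30, seed=11)
    transcripts, structures, counts = simulate_dataset(params)
    return transcripts, structures, counts, profiles_for(transcripts, counts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
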