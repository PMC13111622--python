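import numpy as np
import pytest

from voicelearn import SpeakerFeatures


@pytest.fixture
def tiny_speakers():
    """Four male + four female speakers with hand-set embeddings and F0."""
    rng = np.random.default_rng(42)

    def spk(sid, gender, f0, n_rec=2, dim=4):
        recs = {}
        for r in range(n_rec):
            v = rng.standard_normal(dim)
            recs[f"r{r}"] = v / np.linalg.norm(v)
        return SpeakerFeatures(sid, gender, f0, recs)

    return [
        spk("m0", "male", 100.0),
        spk("m1", "male", 110.0),
        spk("m2", "male", 125.0),
        spk("m3", "male", 140.0),
        spk("f0", "female", 200.0),
        spk("f1", "female", 215.0),
        spk("f2", "female", 230.0),
        spk("f3", "female", 250.0),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
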