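import numpy as np
import pytest

from hypnostates.montage import make_montage
from hypnostates.synthetic import CohortSpec


@pytest.fixture(scope="session")
def montage():
    return make_montage(63)


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec(seed=123)


@pytest.fixture(scope="session")
def subject(montage, default_spec):
    """One preprocessed default synthetic subject with masks and truth."""
    from hypnostates.pipeline import preprocess_recording, subject_state_masks
    from hypnostates.synthetic import simulate_subject

    rec, events, truth = simulate_subject(default_spec, seed=2024,
                                          montage=montage)
    rec = preprocess_recording(rec)
    masks = subject_state_masks(rec, events)
    return {"rec": rec, "events": events, "truth": truth, "masks": masks}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
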