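import numpy as np
import pytest
from hypothesis import settings

from zoochimera.modality_store import ModalityDataset, SampleRecord

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_dataset(data, modality_id="m1", session_order=None):
    """Build a ModalityDataset from {individual: {session: [vectors]}}."""
    records = []
    sessions = []
    for ind, per_sess in data.items():
        for sess, vectors in per_sess.items():
            if sess not in sessions:
                sessions.append(sess)
            for k, vec in enumerate(vectors):
                records.append(SampleRecord(ind, sess, k, np.asarray(vec, float)))
    dim = records[0].features.shape[0]
    return ModalityDataset(
        modality_id=modality_id,
        dimension=dim,
        records=records,
        session_order=session_order or sessions,
    )


def random_dataset(rng, n_individuals, dim=4, sessions=("s1", "s2"), samples=3):
    """Random multi-session dataset with `samples` samples per cell."""
    data = {}
    for j in range(n_individuals):
        center = rng.normal(0, 1, dim)
        data[f"i{j:02d}"] = {
            sess: [center + rng.normal(0, 0.5, dim) for _ in range(samples)]
            for sess in sessions
        }
    return make_dataset(data, session_order=list(sessions))


@pytest.fixture
def two_by_two():
    """2 individuals x 2 sessions x 2 samples, d=3."""
    return make_dataset(
        {
            "a": {"s1": [[0, 0, 0], [1, 0, 0]], "s2": [[0, 1, 0], [1, 1, 0]]},
            "b": {"s1": [[5, 5, 5], [6, 5, 5]], "s2": [[5, 6, 5], [6, 6, 5]]},
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
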