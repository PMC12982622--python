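import numpy as np
import pandas as pd
import pytest

from flashlmm.sstats import compute_sstats


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_instance(
    rng,
    n=80,
    p=3,
    n_subjects=6,
    m=4,
    sigma_subject2=0.5,
    sigma2=1.0,
    beta=None,
):
    """Random LMM instance with a single subject random intercept.

    Returns (X, Z, Y, partition, ss).
    """
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    subj = rng.integers(n_subjects, size=n)
    Z = np.eye(n_subjects)[subj]
    if beta is None:
        beta = rng.normal(size=p)
    U = rng.normal(0.0, np.sqrt(sigma_subject2), size=(m, n_subjects))
    Y = X @ beta + U[:, subj] + rng.normal(0.0, np.sqrt(sigma2), size=(m, n))
    ss = compute_sstats(X, Z, Y, partition=(n_subjects,))
    return X, Z, Y, (n_subjects,), ss


@pytest.fixture
def small_instance(rng):
    return make_instance(rng)


@pytest.fixture
def toy_meta():
    return pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3", "c4"],
            "subject": ["a", "a", "b", "b"],
            "cell_type": ["T", "B", "T", "B"],
            "condition": ["ctl", "ctl", "stim", "stim"],
            "sex": ["F", "M", "F", "M"],
            "library_size": [100, 200, 150, 250],
        }
    )
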