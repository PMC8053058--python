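import numpy as np
import pytest

from geetgdr import LongitudinalDataset, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_dataset():
    """3 subjects, 2 features, 2 time points with hand-pickable numbers."""
    X = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 7.0]])
    Y = np.array([[10.0, 1.0], [20.0, 2.0], [30.0, 3.0]])
    return LongitudinalDataset(
        X=X,
        Y=Y,
        subject_ids=["a", "b", "c"],
        feature_names=["f1", "f2"],
        time_labels=["t0", "t1"],
    )


@pytest.fixture
def small_panel():
    """A modest signal-bearing synthetic panel used across fitter tests."""
    data, truth = generate(
        n=60, t=3, P=25, support=4, effect_size=1.0,
        kind="exchangeable", alpha_true=0.4, seed=11,
    )
    return data, truth
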