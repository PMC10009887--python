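import numpy as np
import pandas as pd
import pytest

from fecgsqa import FEATURE_NAMES, LabelledFeatureTable


def make_table(X: np.ndarray, y: np.ndarray) -> LabelledFeatureTable:
    """Wrap a plain (n, 16) matrix + labels into a labelled feature table."""
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df["label"] = np.asarray(y, dtype=bool)
    df["recording"] = "r0"
    df["channel"] = 0
    df["start"] = np.arange(len(df))
    return LabelledFeatureTable(df)


def separable_table(n: int = 400, seed: int = 0, shift: float = 8.0) -> LabelledFeatureTable:
    """Balanced two-class table where three features separate the classes."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2 == 0
    X = rng.standard_normal((n, 16))
    for col in (0, 1, 2):
        X[y, col] += shift
    return make_table(X, y)


@pytest.fixture(scope="session")
def small_recording():
    """One 4+3-channel 20-s synthetic recording with graded fetal content."""
    from fecgsqa import SynthConfig, generate_recording

    cfg = SynthConfig(
        n_abdominal_channels=4,
        duration=20.0,
        fetal_amp_per_channel=[60.0, 40.0, 2.0, 0.0],
        maternal_gain_per_channel=[0.05, 0.05, 0.8, 0.8],
        seed=42,
    )
    return generate_recording(cfg)
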