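import numpy as np
import pandas as pd
import pytest

from clickcyto import SceneConfig, generate_intensity_table


@pytest.fixture
def bimodal_table() -> pd.DataFrame:
    """Perfectly separated two-population table: 5000 at 10, 5000 at 1000."""
    n = 10_000
    signal = np.concatenate([np.full(n // 2, 10.0), np.full(n // 2, 1000.0)])
    return pd.DataFrame(
        {
            "sample_id": "fixture",
            "condition": "treated",
            "replicate": 1,
            "nucleus_id": np.arange(1, n + 1),
            "x": 0.0,
            "y": 0.0,
            "area_px": 300,
            "dapi_mean": 8000.0,
            "signal_mean": signal,
        }
    )


def make_table(signals, ids=None) -> pd.DataFrame:
    """Minimal intensity table around an explicit signal vector."""
    signals = np.asarray(signals, dtype=float)
    n = len(signals)
    return pd.DataFrame(
        {
            "sample_id": "t",
            "condition": "c",
            "replicate": 1,
            "nucleus_id": ids if ids is not None else np.arange(1, n + 1),
            "x": 0.0,
            "y": 0.0,
            "area_px": 300,
            "dapi_mean": 8000.0,
            "signal_mean": signals,
        }
    )


@pytest.fixture
def synthetic_table() -> pd.DataFrame:
    return generate_intensity_table(
        SceneConfig(n_nuclei=10_000, labelled_fraction=0.45, seed=11)
    )
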