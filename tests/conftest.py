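import warnings

import numpy as np
import pandas as pd
import pytest

import chillclass as cc
from chillclass.chlf import records_to_frame


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default-condition synthetic study: 4 temperatures × 6 days × 8 plants."""
    records, labels = cc.generate_chlf_dataset(cc.SyntheticConfig(seed=1))
    return records, labels


@pytest.fixture(scope="session")
def normalized_matrix(synthetic_dataset):
    """Filtered + normalized feature matrix with aligned planted labels."""
    records, labels = synthetic_dataset
    M = cc.FeatureMatrix.from_frame(records_to_frame(records))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        M, _ = cc.filter_outliers_3sigma(M)
    keep = set(M.sample_meta["plant_id"])
    planted = labels[labels["plant_id"].isin(keep)]["planted_class"].to_numpy()
    return cc.minmax_normalize(M), planted


def make_matrix(values: dict, temps=None, days=None) -> cc.FeatureMatrix:
    """Small FeatureMatrix helper for unit tests."""
    frame = pd.DataFrame(values)
    n = len(frame)
    meta = pd.DataFrame(
        {
            "plant_id": [f"p{i}" for i in range(n)],
            "temperature_C": temps if temps is not None else [8.0] * n,
            "day": days if days is not None else [1] * n,
        }
    )
    return cc.FeatureMatrix(values=frame.astype(float), sample_meta=meta)


@pytest.fixture
def four_blobs():
    """Four well-separated Gaussian blobs in 2-D (σ=0.5, centers 10 apart)."""
    rng = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
    X = np.vstack([c + rng.normal(0, 0.5, size=(25, 2)) for c in centers])
    y = np.repeat(np.arange(4), 25)
    return X, y, centers, 0.5
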