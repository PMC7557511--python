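"""Shared fixtures: one default synthetic dataset and its derived tables.

Session-scoped so the full 240-trial offline protocol is synthesized and
cross-validated once and reused by all tests that need it.
"""

import numpy as np
import pytest

import facemyo as fm
from facemyo.features import FeatureScaler
from facemyo.lmbp import LabelCodec, init_network, train_lmbp
from facemyo.online_control import TrainedDecoder


@pytest.fixture(scope="session")
def default_dataset():
    """Full offline protocol: 10 sessions x 6 trials/action x 4 actions."""
    return fm.synthesize_dataset(seed=1)


@pytest.fixture(scope="session")
def default_epochs(default_dataset):
    recs, _ = default_dataset
    return fm.epochs_from_dataset(recs)


@pytest.fixture(scope="session")
def fft_table(default_epochs):
    return fm.build_feature_table(default_epochs, method="fft")


@pytest.fixture(scope="session")
def wt_table(default_epochs):
    return fm.build_feature_table(default_epochs, method="wt")


@pytest.fixture(scope="session")
def cv_fft_lmbp(fft_table):
    table, y = fft_table
    return fm.repeated_kfold(table, y, k=10, repeats=4, trainer="lmbp", seed=1)


@pytest.fixture(scope="session")
def cv_wt_lmbp(wt_table):
    table, y = wt_table
    return fm.repeated_kfold(table, y, k=10, repeats=4, trainer="lmbp", seed=1)


@pytest.fixture(scope="session")
def cv_fft_adam(fft_table):
    table, y = fft_table
    return fm.repeated_kfold(table, y, k=10, repeats=4, trainer="adam", seed=1)


@pytest.fixture(scope="session")
def trained_decoder(fft_table):
    """Decoder fit on the full default feature table (online-experiment style)."""
    table, y = fft_table
    X = table.to_numpy()
    scaler = FeatureScaler().fit(X)
    net, _ = train_lmbp(
        init_network(seed=0), scaler.transform(X), LabelCodec.encode(y)
    )
    return TrainedDecoder(net, scaler)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
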