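import numpy as np
import pytest

from ecgwaves import NoiseSpec, generate_dataset
from ecgwaves.delineator import ConvBiLSTMDelineator

#: scaled-down study conditions reused across the suite
N_TRAIN = 200
N_HELD = 50
DELIN_EPOCHS = 30
DELIN_LR = 1e-3


@pytest.fixture(scope="session")
def dataset_35db():
    """250 paired clean/noisy beats at 35 dB white-noise injection."""
    return generate_dataset(N_TRAIN + N_HELD, noise=NoiseSpec(35.0), seed=7)


@pytest.fixture(scope="session")
def trained_delineator():
    """Delineator fit on 200 clean synthetic beats (30 epochs, lr 1e-3).

    Returns (estimator, held-out clean frames, held-out X, held-out y).
    """
    pairs = generate_dataset(N_TRAIN + N_HELD, noise=NoiseSpec(35.0), seed=3)
    clean = [c for c, _ in pairs]
    X = np.stack([f.samples for f in clean])
    y = np.stack([f.labels for f in clean])
    est = ConvBiLSTMDelineator(epochs=DELIN_EPOCHS, batch_size=8,
                               learning_rate=DELIN_LR, seed=3)
    est.fit(X[:N_TRAIN], y[:N_TRAIN])
    return est, clean[N_TRAIN:], X[N_TRAIN:], y[N_TRAIN:]
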