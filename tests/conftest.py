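"""Shared fixtures: a small synthetic corpus, a trained codec and a
trained network, all session-scoped because training is the expensive
part of the suite."""

import numpy as np
import pytest

from pvrnn_agency.network import NetworkConfig, PVRNN
from pvrnn_agency.synthetic_data import build_dataset
from pvrnn_agency.training import TrainConfig, train
from pvrnn_agency.vision_codec import CodecConfig, encode_corpus, train_codec

IMAGE_SIZE = 16
LATENT_DIM = 8


@pytest.fixture(scope="session")
def toy_corpus():
    """6 sequences (4 train + 2 held out), 4 segments x 25 steps = T=100."""
    return build_dataset(n_sequences=6, n_segments=4, segment_len=25,
                         seed=3, image_size=IMAGE_SIZE)


@pytest.fixture(scope="session")
def toy_codec(toy_corpus):
    frames = np.concatenate([s.frames for s in toy_corpus[:4]])
    codec, history = train_codec(
        frames, CodecConfig(image_size=IMAGE_SIZE, latent_dim=LATENT_DIM),
        epochs=40, seed=0, alpha=0.008)
    return codec, history


@pytest.fixture(scope="session")
def encoded_corpus(toy_corpus, toy_codec):
    codec, _ = toy_codec
    encode_corpus(codec, toy_corpus)
    return toy_corpus


@pytest.fixture(scope="session")
def trained_model(encoded_corpus):
    """Half-width model trained 500 epochs on 4 sequences x 100 steps
    (the scaled convergence protocol); returns (model, history)."""
    model = PVRNN(NetworkConfig.small(l_dim=LATENT_DIM), seed=0)
    model, history, _ = train(model, encoded_corpus[:4],
                              TrainConfig(epochs=500, seed=0, log_every=25))
    return model, history


@pytest.fixture()
def tiny_model():
    """Miniature network for fast unit tests."""
    from pvrnn_agency.pvrnn_core import LayerConfig
    cfg = NetworkConfig(layers={
        "assoc": LayerConfig(3, 1, 4.0),
        "prop_slow": LayerConfig(4, 1, 3.0),
        "prop_fast": LayerConfig(5, 2, 2.0),
        "vis_slow": LayerConfig(4, 1, 3.0),
        "vis_fast": LayerConfig(5, 2, 2.0),
    }, p_dim=4, l_dim=3)
    return PVRNN(cfg, seed=42)
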