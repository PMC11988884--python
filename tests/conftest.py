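import numpy as np
import pytest

from flatfoot import backbone as bb
from flatfoot import elm, synthetic
from flatfoot.samples import one_hot


@pytest.fixture(scope="session")
def toy_config():
    """Desk-scale backbone: 32px image, 16px patches -> 5 tokens."""
    return bb.BackboneConfig(image_size=32, patch_size=16, embed_dim=8,
                             n_heads=2, depth=2, feature_dim=10, seed=0)


@pytest.fixture(scope="session")
def toy_weights(toy_config):
    return bb.init_backbone(toy_config, seed=0)


@pytest.fixture(scope="session")
def separable_clusters():
    """Two well-separated Gaussian feature clusters (n=200, d=20)."""
    X, y, pids = synthetic.gen_feature_clusters(200, 20, separation=8.0, seed=1)
    return X, y, pids, one_hot(y)


@pytest.fixture(scope="session")
def trained_separable(separable_clusters):
    """OELM trained with Adam on the separable fixture (150/50 split)."""
    X, y, _, T = separable_clusters
    layer = elm.init_hidden(20, 50, "sigmoid", seed=0)
    cfg = elm.OELMConfig(L=50, solver="adam", lr=0.01, seed=0)
    beta, log = elm.solve_adam(X[:150], T[:150], X[150:], T[150:], layer, cfg)
    return X, y, layer, beta, log


@pytest.fixture(scope="session")
def tiny_image_dataset(tmp_path_factory):
    """Small synthetic radiograph dataset written to disk once."""
    from flatfoot import io
    cfg = synthetic.SyntheticConfig(n_patients=12, image_size=32, seed=5)
    samples = synthetic.gen_dataset(cfg)
    root = tmp_path_factory.mktemp("ds")
    io.write_image_dataset(samples, root)
    return root, samples
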