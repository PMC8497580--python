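import numpy as np
import pytest
from hypothesis import settings

import cellannotator as ca

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def corpus():
    spec = ca.scenegen.separable_scene_spec(seed=101)
    return ca.scenegen.generate_pretraining_corpus(spec, 300)


@pytest.fixture(scope="session")
def backbone(corpus):
    patches, _ = corpus
    return ca.backbone.pretrain_backbone(patches)


@pytest.fixture(scope="session")
def small_scene():
    """Patch-scale separable scene used by most session-level tests."""
    spec = ca.scenegen.separable_scene_spec(
        seed=3, width=640, height=640, n_cells=160
    )
    return ca.scenegen.generate_scene(spec)


@pytest.fixture(scope="session")
def small_setup(small_scene, backbone):
    """Scene + ground-truth detections + per-cell backbone features."""
    det = ca.scenegen.ground_truth_detections(small_scene)
    patches = ca.patchio.extract_patches(small_scene.image, det)
    ids = sorted(patches)
    feats = backbone.transform(np.stack([patches[i] for i in ids]))
    features_by_id = {cid: feats[k] for k, cid in enumerate(ids)}
    return {
        "scene": small_scene,
        "detections": det,
        "patches": patches,
        "features_by_id": features_by_id,
        "backbone": backbone,
    }


@pytest.fixture
def stub_backbone():
    """Identity backbone over precomputed feature rows (patches ARE features)."""

    def make(dim=32):
        return ca.backbone.StubBackbone(lambda p: p.reshape(len(p), -1)[:, :dim], dim)

    return make


def separable_embeddings(n_per_class, dim=32, separation=3.0, seed=0):
    """Two well-separated Gaussian classes; the stub-backbone training oracle."""
    rng = np.random.default_rng(seed)
    mu = rng.normal(0, 1, dim)
    mu = mu / np.linalg.norm(mu) * separation
    X = np.vstack(
        [
            rng.normal(0, 1, (n_per_class, dim)) + mu,
            rng.normal(0, 1, (n_per_class, dim)) - mu,
        ]
    )
    y = np.concatenate([np.ones(n_per_class, int), np.zeros(n_per_class, int)])
    return X, y
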