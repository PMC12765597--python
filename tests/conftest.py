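import numpy as np
import pytest

import batdialect as bd


@pytest.fixture(scope="session")
def nt_sites():
    return bd.make_sites("paper_nt")


@pytest.fixture(scope="session")
def nt_geo(nt_sites):
    return bd.geographic_distance_matrix(nt_sites)


@pytest.fixture(scope="session")
def planted(
):
    """Standard planted-call fixture: 10 calls at 20 dB SNR, plus its
    spectrogram, noise profile and detections (computed once)."""
    scene = bd.planted_scene(seed=3)
    spec = bd.compute_spectrogram(scene.audio)
    noise = bd.estimate_noise_profile(spec)
    dets = bd.detect_calls(spec, noise)
    return scene, spec, noise, dets


def random_distance_matrix(n, rng, labels=None):
    """Distances between random planar points (valid metric, no ties)."""
    pts = rng.random((n, 2))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    labels = labels or [f"s{i}" for i in range(n)]
    return bd.DistanceMatrix(labels, d, "random_euclidean")
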