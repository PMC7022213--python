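import numpy as np
import pytest
from hypothesis import settings

from vascuscope import SceneConfig, generate_scene, quantize_u16

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


NOISELESS = dict(noise_sd=0.0, background_gradient_amplitude=0.0)


@pytest.fixture(scope="session")
def tiny_scene():
    """A small deterministic scene with ground truth (64x64, 4 nuclei)."""
    cfg = SceneConfig(image_height=64, image_width=64, n_nuclei=4,
                      nucleus_axis_range=(5.0, 7.0),
                      puncta_mean_per_cell={"CD31": 2.0, "TARGET1": 2.0},
                      punctum_min_separation=6.0, seed=42)
    truth, images, mask = generate_scene(cfg)
    return cfg, truth, images, mask


@pytest.fixture(scope="session")
def default_scene():
    """One full-size scene under the default study conditions."""
    cfg = SceneConfig(seed=7)
    truth, images, mask = generate_scene(cfg)
    qimages = {ch: quantize_u16(im) for ch, im in images.items()}
    return cfg, truth, qimages, mask


def greedy_match(detected_pts, truth_pts, rmax):
    """1-1 greedy nearest-neighbour matching within rmax pixels."""
    pairs = []
    for i, d in enumerate(detected_pts):
        for j, t in enumerate(truth_pts):
            dist = np.hypot(d[0] - t[0], d[1] - t[1])
            if dist <= rmax:
                pairs.append((dist, i, j))
    pairs.sort()
    used_i, used_j = set(), set()
    matches = []
    for _, i, j in pairs:
        if i not in used_i and j not in used_j:
            used_i.add(i)
            used_j.add(j)
            matches.append((i, j))
    return matches
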