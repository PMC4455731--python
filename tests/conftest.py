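import numpy as np
import pytest

from morphorate.morphometrics import LandmarkSet, SliderSpec
from morphorate.trees import PhyloTree


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def three_taxon_tree():
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree_4():
    return PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")


def random_similarity(rng):
    """Random det=+1 similarity transform (R, scale, translation)."""
    th = rng.uniform(-np.pi, np.pi)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return R, float(np.exp(rng.normal(0, 0.5))), rng.uniform(-5, 5, 2)


def apply_similarity(coords, R, s, t):
    return coords @ R.T * s + t


@pytest.fixture
def noisy_specimens(rng):
    """12 specimens around one 6-point template, arbitrary frames."""
    template = np.array([[0.0, 0.0], [1.0, 0.1], [2.0, 0.0],
                         [1.8, 1.0], [1.0, 1.4], [0.2, 1.0]])
    out = []
    for i in range(12):
        cfg = template + rng.normal(0, 0.02, template.shape)
        R, s, t = random_similarity(rng)
        out.append(LandmarkSet(f"s{i}", apply_similarity(cfg, R, s, t)))
    return out, template
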