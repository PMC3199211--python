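import numpy as np
import pytest

from dermcrf import (
    CrfFeatures,
    DatasetRanges,
    LabelField,
    PipelineConfig,
    WeightVector,
    build_grid,
    generate_dataset,
)
from dermcrf.training import CrfInstance


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, height, width, *, node_scale=1.0, edge_scale=1.0):
    """Random binary CRF instance: uniform node costs and edge costs."""
    g = build_grid(height, width)
    nf = node_scale * rng.random((g.n_nodes, 2))
    ef = edge_scale * rng.random(g.n_edges)
    feats = CrfFeatures((nf,), (ef,))
    truth = LabelField(rng.integers(0, 2, g.n_nodes), height, width)
    return CrfInstance(feats, truth, g)


@pytest.fixture
def tiny_instances(rng):
    """A handful of random instances small enough for enumeration."""
    shapes = [(1, 1), (1, 3), (2, 2), (2, 3), (3, 3), (2, 4)]
    return [random_instance(rng, h, w) for h, w in shapes]


@pytest.fixture(scope="session")
def easy_dataset():
    """Well-separated colors, mild noise: the separable sanity regime."""
    ranges = DatasetRanges(
        height=32,
        width=32,
        noise_sd=(0.005, 0.02),
        lstar_offset=(-10.0, 10.0),
        n_hairs=(0, 0),
    )
    data = generate_dataset(16, ranges, seed=11)
    return [d[0] for d in data], [d[1] for d in data]


@pytest.fixture(scope="session")
def fitted_pp(easy_dataset):
    """PP model fitted on the easy dataset (training = evaluation set)."""
    import warnings

    from dermcrf import LabelSet, fit_pp_model
    from dermcrf.evaluation import compute_stack

    images, truths = easy_dataset
    cfg = PipelineConfig()
    pairs = [compute_stack(img, cfg) for img in images]
    stacks = [p[0] for p in pairs]
    labs = [p[1] for p in pairs]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = fit_pp_model(stacks, truths, LabelSet((0, 1)))
    return model, stacks, labs, truths


@pytest.fixture
def w_standard():
    return WeightVector(np.array([1.0, 0.5]), (1,))
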