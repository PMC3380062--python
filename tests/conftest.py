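import numpy as np
import pytest

from lexalign.core import Dataset, Feature, ResolutionSet


@pytest.fixture
def res():
    """Default tolerances: 0.3 min RT, 10 ppm mass."""
    return ResolutionSet()


@pytest.fixture
def fixed_res():
    """Constant 0.001 Da mass tolerance (worked-example mode)."""
    return ResolutionSet(delta_r=0.3, mode="fixed_da", delta_m_fixed=0.001)


def make_features(rows):
    """rows: iterable of (rt, mz, map_index, intensity)."""
    return [
        Feature(uid=i, rt=rt, mz=mz, map_index=m, intensity=z)
        for i, (rt, mz, m, z) in enumerate(rows)
    ]


def make_dataset(rows, n_maps=None):
    feats = make_features(rows)
    if n_maps is None:
        n_maps = max((f.map_index for f in feats), default=0)
    return Dataset(features=feats, n_maps=n_maps)


@pytest.fixture
def tiny_dataset():
    return make_dataset(
        [
            (1.5, 130.034, 1, 100.0),
            (1.52, 130.0341, 2, 250.0),
            (12.0, 250.5, 1, 50.0),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
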