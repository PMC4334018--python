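import numpy as np
import pytest
from hypothesis import settings

from metacad.segment import LabeledRegion, RegionSet

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_region(coords, mean_intensity=100.0, label_id=1) -> LabeledRegion:
    """Build a LabeledRegion directly from pixel coordinates."""
    coords = np.asarray(coords, int)
    return LabeledRegion(
        label_id=label_id,
        coords=coords,
        area=len(coords),
        centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
        mean_intensity=float(mean_intensity),
    )


def random_regionset(rng: np.random.Generator, max_regions: int = 8) -> RegionSet:
    """A RegionSet of random non-overlapping rectangular blobs."""
    n = int(rng.integers(1, max_regions + 1))
    regions = []
    for i in range(n):
        h, w = rng.integers(1, 6, 2)
        r0 = int(rng.integers(0, 40)) + 50 * i  # stripes guarantee disjointness
        c0 = int(rng.integers(0, 40))
        rr, cc = np.mgrid[r0 : r0 + h, c0 : c0 + w]
        coords = np.column_stack([rr.ravel(), cc.ravel()])
        regions.append(make_region(coords, mean_intensity=float(rng.uniform(10, 250)), label_id=i + 1))
    return RegionSet(regions=regions, source_shape=(50 * n, 64))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: SceneSpec overrides that shrink every object so whole datasets render fast.
TINY_SCENE = dict(
    image_shape=(218, 128),
    n_chromosomes_per_cluster=8,
    cluster_spread=30.0,
    chromosome_length_range=(6.0, 12.0),
    chromosome_width_range=(2.0, 4.0),
    interphase_radius_range=(4.0, 10.0),
    n_interphase=2,
    n_debris=3,
)


@pytest.fixture
def tiny_scene_overrides():
    return dict(TINY_SCENE)
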