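"""The nine morphology features of one labeled ROI.

Per image: the number of labeled regions; mean and standard deviation of the
per-region mean intensity; mean and STD of region area; mean and STD of
region circularity (overlap fraction with the equal-area circle centered at
the region's gravity center); mean and STD of the radial distance from each
region's gravity center to the global gravity center of all regions.

Standard deviations are population (divide-by-N) values, so a single-region
image has zero STD rather than a missing value. An image with no surviving
regions yields ``n_regions = 0`` and NaN for the other eight features.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .segment import LabeledRegion, RegionSet, binarize, label_regions

__all__ = [
    "FEATURE_NAMES",
    "ANN_FEATURES",
    "FeatureConfig",
    "FeatureVector",
    "count_regions",
    "intensity_stats",
    "area_stats",
    "region_circularity",
    "circularity_stats",
    "global_gravity_center",
    "distance_stats",
    "extract_feature_vector",
    "extract_feature_table",
]

FEATURE_NAMES = (
    "n_regions",
    "mean_intensity",
    "std_intensity",
    "mean_area",
    "std_area",
    "mean_circ",
    "std_circ",
    "mean_dist",
    "std_dist",
)

#: The three inputs of the first-level neural-network classifier.
ANN_FEATURES = ("mean_area", "mean_intensity", "std_dist")


class UndefinedFeatureError(ValueError):
    """A feature was requested for an empty RegionSet."""


@dataclasses.dataclass(frozen=True)
class FeatureConfig:
    """Segmentation and aggregation choices behind feature extraction."""

    method: str = "otsu"
    fixed_threshold: float | None = None
    connectivity: int = 8
    min_area: int = 20
    #: "area_weighted" global gravity center equals the centroid of the union
    #: of all labeled pixels; "unweighted" averages region centroids directly.
    center_mode: str = "area_weighted"


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    n_regions: int
    mean_intensity: float
    std_intensity: float
    mean_area: float
    std_area: float
    mean_circ: float
    std_circ: float
    mean_dist: float
    std_dist: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def count_regions(rs: RegionSet) -> int:
    return len(rs.regions)


def _require_regions(rs: RegionSet) -> None:
    if len(rs.regions) == 0:
        raise UndefinedFeatureError("feature undefined for an empty RegionSet")


def _mean_std(values: np.ndarray) -> tuple[float, float]:
    return float(np.mean(values)), float(np.std(values))


def intensity_stats(rs: RegionSet) -> tuple[float, float]:
    """Mean and population STD of the per-region mean intensities."""
    _require_regions(rs)
    return _mean_std(np.array([r.mean_intensity for r in rs.regions]))


def area_stats(rs: RegionSet) -> tuple[float, float]:
    """Mean and population STD of the region areas (pixel counts)."""
    _require_regions(rs)
    return _mean_std(np.array([r.area for r in rs.regions], float))


def region_circularity(region: LabeledRegion) -> float:
    """Overlap fraction between a region and its equal-area circle.

    The equivalent circle has radius ``sqrt(A/pi)`` and is centered at the
    region's gravity center; the overlap area is the count of region pixels
    whose centers lie within that radius, so a rasterized disk scores ~1 and
    elongated shapes score low.
    """
    coords = region.coords
    area = len(coords)
    r = math.sqrt(area / math.pi)
    d2 = ((coords - np.array(region.centroid)) ** 2).sum(axis=1)
    overlap = int(np.count_nonzero(d2 <= r * r))
    return overlap / area


def circularity_stats(rs: RegionSet) -> tuple[float, float]:
    _require_regions(rs)
    return _mean_std(np.array([region_circularity(r) for r in rs.regions]))


def global_gravity_center(
    rs: RegionSet, mode: str = "area_weighted"
) -> tuple[float, float]:
    """Gravity center of all labeled regions.

    Area-weighted mode returns the centroid of the union of all labeled
    pixels; unweighted mode averages the region centroids with equal weight.
    """
    _require_regions(rs)
    cents = np.array([r.centroid for r in rs.regions])
    if mode == "area_weighted":
        w = np.array([r.area for r in rs.regions], float)
        c = (cents * w[:, None]).sum(axis=0) / w.sum()
    elif mode == "unweighted":
        c = cents.mean(axis=0)
    else:
        raise ValueError(f"unknown center mode {mode!r}")
    return float(c[0]), float(c[1])


def distance_stats(
    rs: RegionSet, mode: str = "area_weighted"
) -> tuple[float, float]:
    """Mean and population STD of region-centroid distances to the global center."""
    _require_regions(rs)
    gc = np.array(global_gravity_center(rs, mode))
    cents = np.array([r.centroid for r in rs.regions])
    d = np.sqrt(((cents - gc) ** 2).sum(axis=1))
    return _mean_std(d)


def features_from_regions(
    rs: RegionSet, center_mode: str = "area_weighted"
) -> FeatureVector:
    """All nine features of an already-labeled RegionSet."""
    n = count_regions(rs)
    if n == 0:
        nan = float("nan")
        return FeatureVector(0, nan, nan, nan, nan, nan, nan, nan, nan)
    mi, si = intensity_stats(rs)
    ma, sa = area_stats(rs)
    mc, sc = circularity_stats(rs)
    md, sd = distance_stats(rs, center_mode)
    return FeatureVector(n, mi, si, ma, sa, mc, sc, md, sd)


def extract_feature_vector(
    image: np.ndarray, config: FeatureConfig | None = None
) -> FeatureVector:
    """Segment an image and compute its nine-feature vector."""
    config = config or FeatureConfig()
    mask = binarize(image, method=config.method, fixed_threshold=config.fixed_threshold)
    rs = label_regions(
        mask,
        connectivity=config.connectivity,
        min_area=config.min_area,
        image=np.asarray(image, float),
    )
    return features_from_regions(rs, config.center_mode)


def extract_feature_table(
    images,
    labels=None,
    scene_classes=None,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """One row of features per image; optional label/scene-class columns."""
    rows = []
    for i, image in enumerate(images):
        row: dict = {"image_id": i}
        if labels is not None:
            row["label"] = int(labels[i])
        if scene_classes is not None:
            row["scene_class"] = scene_classes[i]
        row.update(extract_feature_vector(image, config).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
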