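"""Binarization and connected-region labeling of microscope ROIs.

Chromosomes and nuclei are bright objects on a dark background, so the
foreground is the bright side of a global threshold (Otsu by default).
"Region growth and labeling" is realized as connected-component labeling
(8-connected by default) followed by a minimum-area filter that suppresses
noise speckle.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.measure import regionprops

__all__ = [
    "LabeledRegion",
    "RegionSet",
    "binarize",
    "label_regions",
    "region_properties",
]


@dataclasses.dataclass
class LabeledRegion:
    """One connected foreground region.

    ``centroid`` is the unweighted mean of pixel (row, col) coordinates —
    the region's gravity center. ``mean_intensity`` is NaN when the region
    was labeled from a mask without an intensity image.
    """

    label_id: int
    coords: np.ndarray  # (N, 2) int (row, col)
    area: int
    centroid: tuple[float, float]
    mean_intensity: float


@dataclasses.dataclass
class RegionSet:
    regions: list[LabeledRegion]
    source_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


def binarize(
    image: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    max_foreground: float | None = 0.25,
) -> np.ndarray:
    """Threshold an image; foreground = pixels strictly above the threshold.

    With ``method="otsu"`` the threshold maximizes between-class variance of
    the gray-level histogram. A constant image has no such split: an empty
    mask is returned with a warning.

    Otsu assumes a roughly bimodal histogram; when bright objects cover only
    a tiny fraction of the field the global split can land inside the
    background noise and label half the field as foreground. If the
    foreground fraction exceeds ``max_foreground``, the threshold is
    therefore re-estimated by applying Otsu to the pixels above the first
    split (two-stage Otsu). Pass ``max_foreground=None`` for the pure
    single-stage criterion.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image must be non-empty")
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold required for method='fixed'")
        thr = float(fixed_threshold)
    elif method == "otsu":
        if fixed_threshold is not None:
            raise ValueError("fixed_threshold only valid with method='fixed'")
        if np.ptp(image) == 0:
            warnings.warn(
                "constant image: Otsu threshold undefined, returning empty mask",
                stacklevel=2,
            )
            return np.zeros(image.shape, bool)
        thr = float(threshold_otsu(image))
        if max_foreground is not None and np.mean(image > thr) > max_foreground:
            upper = image[image > thr]
            if np.ptp(upper) > 0:
                thr = float(threshold_otsu(upper))
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return image > thr


def label_regions(
    mask: np.ndarray,
    connectivity: int = 8,
    min_area: int = 20,
    image: np.ndarray | None = None,
) -> RegionSet:
    """Label connected foreground components and keep those with area >= min_area.

    ``connectivity`` is the pixel neighborhood (4 = edges only, 8 = edges and
    corners). When ``image`` is given, per-region mean intensity is computed
    from it.
    """
    mask = np.asarray(mask, bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if image is not None and image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    lbl = _cc_label(mask, connectivity=1 if connectivity == 4 else 2)
    regions = []
    for rp in regionprops(lbl, intensity_image=image):
        if rp.area < min_area:
            continue
        regions.append(
            LabeledRegion(
                label_id=int(rp.label),
                coords=np.asarray(rp.coords),
                area=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                mean_intensity=(
                    float(rp.intensity_mean) if image is not None else float("nan")
                ),
            )
        )
    return RegionSet(regions=regions, source_shape=tuple(mask.shape))


def region_properties(image: np.ndarray, coords: np.ndarray, label_id: int = 0) -> LabeledRegion:
    """Compute area, gravity center and mean intensity for an explicit pixel set."""
    image = np.asarray(image)
    coords = np.asarray(coords)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) == 0:
        raise ValueError("coords must be a non-empty (N, 2) array")
    if (
        coords.min() < 0
        or coords[:, 0].max() >= image.shape[0]
        or coords[:, 1].max() >= image.shape[1]
    ):
        raise ValueError("region pixel outside image bounds")
    vals = image[coords[:, 0], coords[:, 1]]
    return LabeledRegion(
        label_id=label_id,
        coords=coords,
        area=int(len(coords)),
        centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
        mean_intensity=float(vals.mean()),
    )
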