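"""Synthetic scanning-microscopy scenes with per-object ground truth.

Emulates the three region-of-interest classes seen when scanning bone-marrow
slides for karyotyping:

* ``analyzable`` — a single metaphase spread: ~46 small, bright, elongated
  chromosomes clustered in one area of the field, possibly with a few
  interphase nuclei elsewhere.
* ``interphase_only`` — a field containing only large, round, dimmer
  interphase nuclei; unanalyzable.
* ``overlapped_metaphase`` — two or more metaphase spreads intermingled so
  that chromosomes touch and merge under connected-component labeling; also
  unanalyzable.

All three classes additionally carry a variable amount of brightly stained
debris (precipitate and chromatin fragments), which real slides always show:
it shifts region counts modestly on every field but strongly perturbs
mean-type features by adding many small regions.

Every scene is deterministic given its :class:`SceneSpec` (including the
seed), so downstream segmentation and feature code is testable without the
original microscope data.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SceneSpec",
    "SceneObject",
    "GroundTruth",
    "PlacementError",
    "render_chromosome",
    "render_interphase",
    "generate_scene",
    "iter_dataset",
    "generate_dataset",
    "write_dataset",
]

SCENE_CLASSES = ("analyzable", "interphase_only", "overlapped_metaphase")

#: Default field size: 1/4 linear scale of the 3488x2048 scanner ROI.
DEFAULT_SHAPE = (872, 512)


class PlacementError(RuntimeError):
    """Objects could not be placed inside the field within bounded retries."""


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    """Generative parameters of one synthetic ROI.

    Lengths are in pixels at the configured ``image_shape`` scale; intensity
    parameters are 8-bit gray levels. Chromosome intensities must lie
    strictly above the background: metaphase chromosomes are the brightest,
    smallest objects in the field.
    """

    scene_class: str
    image_shape: tuple[int, int] = DEFAULT_SHAPE
    n_chromosomes_per_cluster: int = 46
    n_clusters: int = 1
    n_interphase: int = 0
    cluster_center: tuple[float, float] | None = None
    cluster_spread: float = 100.0
    chromosome_length_range: tuple[float, float] = (10.0, 30.0)
    chromosome_width_range: tuple[float, float] = (3.0, 6.5)
    chromosome_bend_range: tuple[float, float] = (0.0, 1.0)
    interphase_radius_range: tuple[float, float] = (7.0, 40.0)
    n_debris: int = 0
    debris_length_range: tuple[float, float] = (5.0, 12.0)
    debris_width_range: tuple[float, float] = (2.0, 4.0)
    foreground_intensity_range: tuple[float, float] = (150.0, 230.0)
    interphase_intensity_range: tuple[float, float] = (80.0, 120.0)
    background_level: float = 20.0
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scene_class not in SCENE_CLASSES:
            raise ValueError(f"unknown scene_class {self.scene_class!r}")
        if min(self.image_shape) <= 0:
            raise ValueError("image_shape must be strictly positive")
        for name in (
            "chromosome_length_range",
            "chromosome_width_range",
            "chromosome_bend_range",
            "interphase_radius_range",
            "debris_length_range",
            "debris_width_range",
            "foreground_intensity_range",
            "interphase_intensity_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy low <= high")
        if self.scene_class == "analyzable" and self.n_clusters != 1:
            raise ValueError("analyzable scenes have exactly one cluster")
        if self.scene_class == "overlapped_metaphase" and self.n_clusters < 2:
            raise ValueError("overlapped_metaphase scenes need >= 2 clusters")
        if self.foreground_intensity_range[0] <= self.background_level:
            raise ValueError(
                "chromosome intensities must lie strictly above background"
            )

    @property
    def label(self) -> int:
        """1 for the clinically analyzable (positive) class, else 0."""
        return int(self.scene_class == "analyzable")


@dataclasses.dataclass
class SceneObject:
    """One rendered object: its kind, pixel coordinates and centroid."""

    kind: str  # "chromosome" | "interphase" | "debris"
    coords: np.ndarray  # (N, 2) int array of (row, col)
    centroid: tuple[float, float]


@dataclasses.dataclass
class GroundTruth:
    label: int
    scene_class: str
    objects: list[SceneObject]

    def count(self, kind: str) -> int:
        return sum(1 for o in self.objects if o.kind == kind)


# ---------------------------------------------------------------------------
# Object rendering


def render_chromosome(
    length: float, width: float, bend: float = 0.0, orientation: float = 0.0
) -> np.ndarray:
    """Rasterize a single chromosome as a bent rod with rounded caps.

    The shape is the set of pixels whose centers lie within ``width/2`` of a
    two-segment polyline (two arms joined at a vertex). ``bend`` is the
    deflection of the arms from a straight line in radians: 0 gives a
    straight rod; the overall extent along the main axis is ``length``.
    """
    if length < 1 or width < 1:
        raise ValueError("length and width must be >= 1 pixel")
    if width > length:
        raise ValueError("length must be >= width")
    radius = width / 2.0
    half = max(length - width, 0.0) / 2.0
    a1 = orientation + bend / 2.0
    a2 = orientation + math.pi - bend / 2.0
    p1 = np.array([half * math.sin(a1), half * math.cos(a1)])
    p2 = np.array([half * math.sin(a2), half * math.cos(a2)])
    ext = int(math.ceil(half + radius)) + 1
    rr, cc = np.mgrid[-ext : ext + 1, -ext : ext + 1]
    pts = np.stack([rr, cc], axis=-1).astype(float)
    d = np.minimum(_dist_to_segment(pts, p1), _dist_to_segment(pts, p2))
    mask = d <= radius
    return _crop(mask)


def _dist_to_segment(pts: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Distance from each point to the segment from the origin to ``end``."""
    L2 = float(end @ end)
    if L2 == 0.0:
        return np.sqrt((pts**2).sum(axis=-1))
    t = np.clip((pts @ end) / L2, 0.0, 1.0)
    proj = t[..., None] * end
    return np.sqrt(((pts - proj) ** 2).sum(axis=-1))


def render_interphase(radius: float) -> np.ndarray:
    """Rasterize an interphase nucleus as a disk of the given pixel radius."""
    if radius < 1:
        raise ValueError("radius must be >= 1 pixel")
    ext = int(math.ceil(radius))
    rr, cc = np.mgrid[-ext : ext + 1, -ext : ext + 1]
    return _crop(rr * rr + cc * cc <= radius * radius)


def _crop(mask: np.ndarray) -> np.ndarray:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


# ---------------------------------------------------------------------------
# Scene assembly


def _dilate(mask: np.ndarray) -> np.ndarray:
    """8-connected single-pixel dilation (keeps placed objects from touching)."""
    out = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), bool)
    for dr in (0, 1, 2):
        for dc in (0, 1, 2):
            out[dr : dr + mask.shape[0], dc : dc + mask.shape[1]] |= mask
    return out


def _try_place(
    rng: np.random.Generator,
    mask: np.ndarray,
    shape: tuple[int, int],
    occupied: np.ndarray | None,
    sampler,
    max_tries: int = 500,
) -> tuple[int, int]:
    """Find a top-left offset for ``mask`` via rejection sampling.

    ``sampler`` draws a candidate object center (row, col). Rejects
    candidates out of bounds or (when ``occupied`` is given) 8-touching an
    already placed object; the occupancy test uses a 1-px dilated footprint.
    """
    h, w = mask.shape
    footprint = _dilate(mask) if occupied is not None else None
    for _ in range(max_tries):
        cr, cc = sampler(rng)
        r0 = int(round(cr - h / 2.0))
        c0 = int(round(cc - w / 2.0))
        if r0 < 0 or c0 < 0 or r0 + h > shape[0] or c0 + w > shape[1]:
            continue
        if occupied is not None:
            win = occupied[max(r0 - 1, 0) : r0 + h + 1, max(c0 - 1, 0) : c0 + w + 1]
            fp = footprint[
                1 - min(r0, 1) : 1 + h + (1 if r0 + h < shape[0] else 0),
                1 - min(c0, 1) : 1 + w + (1 if c0 + w < shape[1] else 0),
            ]
            if (win & fp).any():
                continue
        return r0, c0
    raise PlacementError(
        f"could not place a {h}x{w} object after {max_tries} attempts"
    )


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one ROI and its ground truth, deterministically from the seed.

    Chromosomes in analyzable scenes never touch (so connected-component
    labeling recovers exactly the generated count); chromosomes in
    overlapped-metaphase scenes may touch and merge, mirroring why such
    images defeat region counting in practice. Interphase nuclei are placed
    anywhere in the field without touching other objects.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    img = np.full(shape, float(spec.background_level))
    occupied = np.zeros(shape, bool)
    objects: list[SceneObject] = []

    # Staining and illumination set a shared brightness level per scene;
    # individual objects vary only modestly around it.
    chrom_intensity = _intensity_sampler(rng, spec.foreground_intensity_range)
    nucleus_intensity = _intensity_sampler(rng, spec.interphase_intensity_range)

    centers = _cluster_centers(spec, rng)
    avoid_touching = spec.scene_class == "analyzable"
    for center in centers:
        sigma = spec.cluster_spread / 2.5
        for _ in range(spec.n_chromosomes_per_cluster):
            mask = render_chromosome(
                length=rng.uniform(*spec.chromosome_length_range),
                width=rng.uniform(*spec.chromosome_width_range),
                bend=rng.uniform(*spec.chromosome_bend_range),
                orientation=rng.uniform(0.0, math.pi),
            )

            def in_cluster(g, _c=center, _s=sigma):
                # Gaussian scatter around the cluster center, hard-capped at
                # the spread radius so every chromosome stays in the cluster.
                while True:
                    off = g.normal(0.0, _s, 2)
                    if np.hypot(*off) <= spec.cluster_spread:
                        return _c[0] + off[0], _c[1] + off[1]

            r0 = c0 = None
            for attempt in range(3):  # widen the scatter if packing is tight
                try:
                    r0, c0 = _try_place(
                        rng,
                        mask,
                        shape,
                        occupied if avoid_touching else None,
                        lambda g, _f=1.3**attempt: in_cluster(g, _s=sigma * _f),
                    )
                    break
                except PlacementError:
                    continue
            if r0 is None:
                raise PlacementError("chromosome placement failed")
            _stamp(img, occupied, objects, mask, r0, c0, "chromosome",
                   chrom_intensity(rng))

    for _ in range(spec.n_interphase):
        # Marrow fields are dominated by small cells; large nuclei are rare.
        lo_r, hi_r = spec.interphase_radius_range
        mask = render_interphase(lo_r + (hi_r - lo_r) * rng.beta(1.2, 3.5))

        def anywhere(g, _h=mask.shape[0], _w=mask.shape[1]):
            return (
                g.uniform(_h / 2.0, shape[0] - _h / 2.0),
                g.uniform(_w / 2.0, shape[1] - _w / 2.0),
            )

        r0, c0 = _try_place(rng, mask, shape, occupied, anywhere)
        _stamp(img, occupied, objects, mask, r0, c0, "interphase",
               nucleus_intensity(rng))

    for _ in range(spec.n_debris):
        dl = rng.uniform(*spec.debris_length_range)
        dw = min(rng.uniform(*spec.debris_width_range), dl)
        mask = render_chromosome(dl, dw, bend=rng.uniform(0.0, 1.2),
                                 orientation=rng.uniform(0.0, math.pi))

        def anywhere(g, _h=mask.shape[0], _w=mask.shape[1]):
            return (
                g.uniform(_h / 2.0, shape[0] - _h / 2.0),
                g.uniform(_w / 2.0, shape[1] - _w / 2.0),
            )

        r0, c0 = _try_place(rng, mask, shape, occupied, anywhere)
        _stamp(img, occupied, objects, mask, r0, c0, "debris",
               chrom_intensity(rng))

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    gt = GroundTruth(label=spec.label, scene_class=spec.scene_class, objects=objects)
    return img, gt


def _intensity_sampler(rng: np.random.Generator, bounds: tuple[float, float],
                       jitter: float = 12.0):
    """Per-scene base level plus small per-object jitter, clipped to bounds.

    Staining and illumination set one brightness level per scene; individual
    objects deviate from it by at most ``jitter`` gray levels.
    """
    lo, hi = bounds
    span = hi - lo
    base = rng.uniform(lo + 0.35 * span, hi - 0.35 * span)

    def draw(g: np.random.Generator) -> float:
        return float(np.clip(base + g.uniform(-jitter, jitter), lo, hi))

    return draw


def _cluster_centers(
    spec: SceneSpec, rng: np.random.Generator
) -> list[tuple[float, float]]:
    if spec.scene_class == "interphase_only":
        return []
    base = spec.cluster_center or (spec.image_shape[0] / 2.0, spec.image_shape[1] / 2.0)
    if spec.scene_class == "analyzable":
        return [base]
    # Overlapped spreads: cluster centers mutually closer than the spread so
    # the chromosome clouds intermingle.
    return [
        (
            base[0] + rng.uniform(-0.35, 0.35) * spec.cluster_spread,
            base[1] + rng.uniform(-0.35, 0.35) * spec.cluster_spread,
        )
        for _ in range(spec.n_clusters)
    ]


def _stamp(img, occupied, objects, mask, r0, c0, kind, intensity) -> None:
    h, w = mask.shape
    view = img[r0 : r0 + h, c0 : c0 + w]
    view[mask] = np.maximum(view[mask], intensity)
    occupied[r0 : r0 + h, c0 : c0 + w] |= mask
    rr, cc = np.nonzero(mask)
    coords = np.column_stack([rr + r0, cc + c0])
    centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
    objects.append(SceneObject(kind=kind, coords=coords, centroid=centroid))


# ---------------------------------------------------------------------------
# Dataset generation


def _child_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def iter_dataset(
    n_positive: int,
    n_negative: int,
    interphase_fraction: float = 0.8,
    seed: int = 0,
    **spec_overrides,
) -> Iterator[tuple[SceneSpec, np.ndarray, GroundTruth]]:
    """Yield ``(spec, image, ground_truth)`` for a full synthetic study.

    Negatives are split between interphase-only and overlapped-metaphase
    scenes according to ``interphase_fraction``. Per-scene seeds and the
    per-scene randomized structure (nucleus counts, cluster counts) are
    derived deterministically from the master seed.
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("counts must be >= 0")
    n_inter = int(round(interphase_fraction * n_negative))
    classes = (
        ["analyzable"] * n_positive
        + ["interphase_only"] * n_inter
        + ["overlapped_metaphase"] * (n_negative - n_inter)
    )
    rng = np.random.default_rng(_child_seed(seed, 0))
    rng.shuffle(classes)
    for i, scene_class in enumerate(classes):
        fields = dict(spec_overrides)
        fields["scene_class"] = scene_class
        fields["seed"] = _child_seed(seed, i + 1)
        # Field cellularity is independent of whether a spread is present:
        # interphase-only fields hold 1-10 nuclei, fields with spreads 0-8.
        if scene_class == "interphase_only":
            fields.setdefault("n_interphase", int(rng.integers(1, 11)))
        else:
            fields.setdefault("n_interphase", int(rng.integers(0, 9)))
            # Slide preparation breaks and clumps part of each spread: a
            # cell presents between ~30 and the full 46 countable objects.
            fields.setdefault(
                "n_chromosomes_per_cluster", int(rng.integers(30, 47))
            )
        # Stain precipitate / fragment load varies widely from field to field.
        fields.setdefault("n_debris", int(rng.integers(0, 36)))
        if scene_class == "overlapped_metaphase":
            fields.setdefault("n_clusters", int(rng.integers(2, 4)))
            # How much adjacent spreads intermingle varies continuously; a
            # wider spread means fewer touching chromosomes merge.
            fields.setdefault("cluster_spread", float(rng.uniform(80.0, 150.0)))
        spec = SceneSpec(**fields)
        img, gt = generate_scene(spec)
        yield spec, img, gt


def generate_dataset(
    n_positive: int,
    n_negative: int,
    interphase_fraction: float = 0.8,
    seed: int = 0,
    **spec_overrides,
) -> tuple[list[tuple[np.ndarray, GroundTruth]], pd.DataFrame]:
    """Materialize a dataset plus its manifest (image id, class, label)."""
    scenes = []
    rows = []
    for i, (spec, img, gt) in enumerate(
        iter_dataset(n_positive, n_negative, interphase_fraction, seed, **spec_overrides)
    ):
        scenes.append((img, gt))
        rows.append(
            {
                "image_path": f"scene_{i:04d}.tif",
                "scene_class": spec.scene_class,
                "label": gt.label,
                "seed": spec.seed,
            }
        )
    manifest = pd.DataFrame(rows, columns=["image_path", "scene_class", "label", "seed"])
    return scenes, manifest


def write_dataset(
    out_dir: str | Path,
    n_positive: int,
    n_negative: int,
    interphase_fraction: float = 0.8,
    seed: int = 0,
    **spec_overrides,
) -> pd.DataFrame:
    """Write 8-bit single-channel TIFFs plus ``manifest.csv``; return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (spec, img, gt) in enumerate(
        iter_dataset(n_positive, n_negative, interphase_fraction, seed, **spec_overrides)
    ):
        name = f"scene_{i:04d}.tif"
        tifffile.imwrite(out / name, img)
        rows.append(
            {
                "image_path": name,
                "scene_class": spec.scene_class,
                "label": gt.label,
                "seed": spec.seed,
            }
        )
    manifest = pd.DataFrame(rows, columns=["image_path", "scene_class", "label", "seed"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
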