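"""Synthetic microscopy-like scenes with ground-truth cell labels.

Every downstream stage (detection, patch extraction, classification, active
learning, simulated annotation sessions) is exercised on scenes produced here,
so the generator aims for the *statistical* structure those stages care about
rather than photorealism: two nucleus classes that differ in size, color and
texture; a stain-tinted noisy background; configurable class balance; and
spatial clustering of the positive class so that region-level active learning
has signal to exploit.

Coordinates are 0-based with ``x`` = column and ``y`` = row throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

NEGATIVE = 0
POSITIVE = 1

LABEL_NAMES = {NEGATIVE: "negative", POSITIVE: "positive"}

_SUBSTREAMS = ("placement", "appearance", "noise")


class SceneTooDenseError(RuntimeError):
    """Raised when cells cannot be placed at the requested min_separation."""


@dataclass(frozen=True)
class ClassAppearance:
    """Rendered look of one nucleus class.

    color_mean/color_std are 8-bit RGB intensities; texture_amplitude is the
    relative amplitude of the multiplicative intra-nucleus noise texture.
    """

    color_mean: tuple[float, float, float]
    color_std: tuple[float, float, float] = (8.0, 8.0, 8.0)
    texture_amplitude: float = 0.08


# Hematoxylin-like blue/purple nuclei vs weakly DAB-shifted positives: the
# class colors overlap enough that the classifier keeps learning over the
# whole 200-label budget instead of saturating on the first few examples.
DEFAULT_NEGATIVE_APPEARANCE = ClassAppearance(
    color_mean=(100.0, 85.0, 150.0), color_std=(15.0, 15.0, 15.0)
)
DEFAULT_POSITIVE_APPEARANCE = ClassAppearance(
    color_mean=(115.0, 85.0, 125.0), color_std=(15.0, 15.0, 15.0), texture_amplitude=0.16
)

# high-contrast variant: classes trivially separable, no regional structure;
# the cleanest condition for boundary contracts and detector checks
SEPARABLE_NEGATIVE_APPEARANCE = ClassAppearance(color_mean=(95.0, 80.0, 160.0))
SEPARABLE_POSITIVE_APPEARANCE = ClassAppearance(
    color_mean=(130.0, 75.0, 45.0), texture_amplitude=0.14
)
DEFAULT_BACKGROUND = (231.0, 213.0, 224.0)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Defaults describe the study condition used throughout the package: a
    region of roughly 800 cells at whole-patch scale (a 640 px viewport holds
    ~200 of them), a minority positive class (30%, as for lymphocyte- or
    proliferation-marker-type targets), and 90% of positives concentrated in
    three Gaussian clusters whose appearance differs slightly (regional
    staining heterogeneity).
    """

    width: int = 1280
    height: int = 1280
    n_cells: int = 800
    positive_fraction: float = 0.3
    radius_range_negative: tuple[float, float] = (5.0, 8.0)
    radius_range_positive: tuple[float, float] = (7.0, 11.0)
    appearance_negative: ClassAppearance = DEFAULT_NEGATIVE_APPEARANCE
    appearance_positive: ClassAppearance = DEFAULT_POSITIVE_APPEARANCE
    background_color: tuple[float, float, float] = DEFAULT_BACKGROUND
    background_noise_std: float = 4.0
    spatial_clustering: float = 0.9
    n_clusters: int = 3
    cluster_color_shift: float = 40.0
    n_compartments: int = 6
    regional_color_shift: float = 25.0
    min_separation: float = 24.0
    seed: int = 0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if not 0.0 <= self.spatial_clustering <= 1.0:
            raise ValueError("spatial_clustering must lie in [0, 1]")
        for lo, hi in (self.radius_range_negative, self.radius_range_positive):
            if lo <= 0 or hi < lo:
                raise ValueError("radius ranges must satisfy 0 < min <= max")


@dataclass(frozen=True)
class GroundTruthCell:
    cell_id: int
    centroid: tuple[float, float]  # (x, y)
    radius: float
    true_label: int  # POSITIVE or NEGATIVE


@dataclass
class SyntheticScene:
    image: np.ndarray  # uint8, (height, width, 3)
    cells: list[GroundTruthCell]
    spec: SceneSpec

    @property
    def truth(self) -> dict[int, int]:
        """cell_id -> true class label."""
        return {c.cell_id: c.true_label for c in self.cells}


def separable_scene_spec(seed: int = 0, **overrides) -> SceneSpec:
    """Patch-scale scene with trivially separable classes and no regional
    structure — the condition for boundary contracts (a perfect classifier
    should reach zero workload here)."""
    base = dict(
        appearance_negative=SEPARABLE_NEGATIVE_APPEARANCE,
        appearance_positive=SEPARABLE_POSITIVE_APPEARANCE,
        positive_fraction=0.5,
        cluster_color_shift=0.0,
        regional_color_shift=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SceneSpec(**base)


def slide_scale_spec(seed: int = 0, **overrides) -> SceneSpec:
    """Slide-like effectiveness condition: the 200-label budget covers only a
    few percent of the cells, positives are a clustered minority, and staining
    varies regionally — the regime in which annotators are guided around a
    slide."""
    base = dict(
        width=2560,
        height=2560,
        n_cells=3000,
        positive_fraction=0.15,
        spatial_clustering=0.95,
        seed=seed,
    )
    base.update(overrides)
    return SceneSpec(**base)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    streams = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_SUBSTREAMS, streams)}


def _place_cells(
    spec: SceneSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rejection-sample centroids respecting min_separation.

    Returns (positions (n,2) as x,y; labels (n,); cluster index per cell).
    Positives are placed first, drawn with probability ``spatial_clustering``
    from one of ``n_clusters`` Gaussian clusters, otherwise uniformly;
    negatives are uniform. Uniformly placed positives are still affiliated
    with a (random) cluster so their appearance matches one subpopulation;
    negatives carry cluster -1.
    """
    n_pos = int(round(spec.n_cells * spec.positive_fraction))
    n_neg = spec.n_cells - n_pos
    margin = max(spec.radius_range_negative[1], spec.radius_range_positive[1]) + 2.0
    if spec.width <= 2 * margin or spec.height <= 2 * margin:
        raise ValueError("scene too small for the configured cell radii")

    centers = np.column_stack(
        [
            rng.uniform(0.15 * spec.width, 0.85 * spec.width, spec.n_clusters),
            rng.uniform(0.15 * spec.height, 0.85 * spec.height, spec.n_clusters),
        ]
    )
    sigma = min(spec.width, spec.height) / 12.0

    accepted = np.empty((spec.n_cells, 2))
    labels = np.concatenate(
        [np.full(n_pos, POSITIVE, dtype=int), np.full(n_neg, NEGATIVE, dtype=int)]
    )
    clusters = np.full(spec.n_cells, -1, dtype=int)
    n_accepted = 0
    max_attempts = 200 * max(spec.n_cells, 1)
    attempts = 0
    sep2 = spec.min_separation**2
    while n_accepted < spec.n_cells:
        if attempts >= max_attempts:
            raise SceneTooDenseError(
                f"placed only {n_accepted}/{spec.n_cells} cells after "
                f"{max_attempts} attempts; scene too dense for "
                f"min_separation={spec.min_separation}"
            )
        attempts += 1
        is_positive = n_accepted < n_pos
        clustered = is_positive and rng.uniform() < spec.spatial_clustering
        cluster = int(rng.integers(spec.n_clusters)) if is_positive else -1
        if clustered:
            pos = centers[cluster] + rng.normal(0.0, sigma, 2)
        else:
            pos = np.array(
                [
                    rng.uniform(margin, spec.width - margin),
                    rng.uniform(margin, spec.height - margin),
                ]
            )
        if not (margin <= pos[0] <= spec.width - margin and margin <= pos[1] <= spec.height - margin):
            continue
        if n_accepted and (((accepted[:n_accepted] - pos) ** 2).sum(axis=1) < sep2).any():
            continue
        accepted[n_accepted] = pos
        clusters[n_accepted] = cluster
        n_accepted += 1
    return accepted, labels, clusters


def _render_nucleus(
    image: np.ndarray,
    center: tuple[float, float],
    radius: float,
    appearance: ClassAppearance,
    appearance_rng: np.random.Generator,
    noise_rng: np.random.Generator,
) -> None:
    """Draw one textured ellipse (eccentricity <= 0.5) in place."""
    cx, cy = center
    ecc = appearance_rng.uniform(0.0, 0.5)
    a = radius
    b = radius * np.sqrt(1.0 - ecc**2)
    theta = appearance_rng.uniform(0.0, np.pi)
    color = np.asarray(appearance.color_mean) + appearance_rng.normal(
        0.0, appearance.color_std, 3
    )

    half = int(np.ceil(a)) + 1
    x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
    y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, image.shape[1]), min(y1, image.shape[0])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not mask.any():
        return
    texture = 1.0 + appearance.texture_amplitude * noise_rng.standard_normal(
        mask.sum()
    )
    image[y0:y1, x0:x1][mask] = color[None, :] * texture[:, None]


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a scene; deterministic for a fixed spec (seed included).

    Raises SceneTooDenseError if placement fails, ValueError on an invalid
    spec.
    """
    spec.validate()
    rngs = _rngs(spec.seed)

    image = np.empty((spec.height, spec.width, 3), dtype=np.float64)
    image[:] = np.asarray(spec.background_color)
    image += rngs["noise"].normal(0.0, spec.background_noise_std, image.shape)

    positions, labels, clusters = _place_cells(spec, rngs["placement"])
    shifts = _cluster_shifts(spec, rngs["appearance"])
    compartments = _Compartments(spec, rngs["appearance"])
    cells: list[GroundTruthCell] = []
    radius_ranges = {
        NEGATIVE: spec.radius_range_negative,
        POSITIVE: spec.radius_range_positive,
    }
    appearances = {
        NEGATIVE: spec.appearance_negative,
        POSITIVE: spec.appearance_positive,
    }
    for cell_id in range(spec.n_cells):
        label = int(labels[cell_id])
        lo, hi = radius_ranges[label]
        radius = rngs["appearance"].uniform(lo, hi)
        center = (float(positions[cell_id, 0]), float(positions[cell_id, 1]))
        _render_nucleus(
            image,
            center,
            radius,
            _shifted(
                appearances[label],
                shifts,
                int(clusters[cell_id]),
                compartments.offset_at(*center),
            ),
            rngs["appearance"],
            rngs["noise"],
        )
        cells.append(
            GroundTruthCell(
                cell_id=cell_id, centroid=center, radius=radius, true_label=label
            )
        )

    # light blur softens aliasing at nucleus rims, as optics would
    for ch in range(3):
        image[..., ch] = ndi.gaussian_filter(image[..., ch], sigma=0.6)
    image = np.clip(image, 0.0, 255.0).astype(np.uint8)
    return SyntheticScene(image=image, cells=cells, spec=spec)


def _cluster_shifts(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-cluster color offsets for the positive class.

    Emulates regional staining heterogeneity: each positive subpopulation is
    shifted by a fixed RGB offset, so a classifier trained on one region does
    not automatically generalize to the others — the property that makes
    spatially diverse sampling worth anything.
    """
    return rng.normal(0.0, spec.cluster_color_shift, (spec.n_clusters, 3))


class _Compartments:
    """Voronoi tissue compartments with per-compartment stain offsets.

    Real slides show regional staining variation that moves the appearance of
    *every* cell in a region; an annotation model calibrated on one region is
    systematically off in unvisited ones. Offsets apply to both classes
    identically, so they never change a cell's true label.
    """

    def __init__(self, spec: SceneSpec, rng: np.random.Generator):
        self.centers = np.column_stack(
            [
                rng.uniform(0, spec.width, spec.n_compartments),
                rng.uniform(0, spec.height, spec.n_compartments),
            ]
        )
        self.offsets = rng.normal(
            0.0, spec.regional_color_shift, (spec.n_compartments, 3)
        )

    def offset_at(self, x: float, y: float) -> np.ndarray:
        d2 = ((self.centers - np.array([x, y])) ** 2).sum(axis=1)
        return self.offsets[int(np.argmin(d2))]


def _shifted(
    appearance: ClassAppearance,
    shifts: np.ndarray,
    cluster: int,
    regional: np.ndarray | None = None,
) -> ClassAppearance:
    mean = np.asarray(appearance.color_mean, dtype=float)
    if cluster >= 0:
        mean = mean + shifts[cluster]
    if regional is not None:
        mean = mean + regional
    return ClassAppearance(
        color_mean=tuple(mean),
        color_std=appearance.color_std,
        texture_amplitude=appearance.texture_amplitude,
    )


def generate_pretraining_corpus(
    spec: SceneSpec, n_patches: int, patch_size: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled 40x40 nucleus patches standing in for a public pretraining set.

    Each patch is a single nucleus, centered, rendered with the scene's
    appearance model over the scene background. Returns
    ``(patches uint8 (n, patch_size, patch_size, 3), labels (n,))`` with class
    balance matching ``spec.positive_fraction`` after deterministic rounding.
    """
    spec.validate()
    if n_patches < 0:
        raise ValueError("n_patches must be >= 0")
    rngs = _rngs(spec.seed)
    n_pos = int(round(n_patches * spec.positive_fraction))
    labels = np.concatenate(
        [
            np.full(n_pos, POSITIVE, dtype=int),
            np.full(n_patches - n_pos, NEGATIVE, dtype=int),
        ]
    )
    labels = labels[rngs["placement"].permutation(n_patches)] if n_patches else labels

    patches = np.empty((n_patches, patch_size, patch_size, 3), dtype=np.uint8)
    radius_ranges = {
        NEGATIVE: spec.radius_range_negative,
        POSITIVE: spec.radius_range_positive,
    }
    appearances = {
        NEGATIVE: spec.appearance_negative,
        POSITIVE: spec.appearance_positive,
    }
    shifts = _cluster_shifts(spec, rngs["appearance"])
    center = ((patch_size - 1) / 2.0, (patch_size - 1) / 2.0)
    for i in range(n_patches):
        label = int(labels[i])
        tile = np.empty((patch_size, patch_size, 3), dtype=np.float64)
        tile[:] = np.asarray(spec.background_color)
        tile += rngs["noise"].normal(0.0, spec.background_noise_std, tile.shape)
        lo, hi = radius_ranges[label]
        radius = rngs["appearance"].uniform(lo, hi)
        jitter = rngs["placement"].uniform(-2.0, 2.0, 2)
        cluster = (
            int(rngs["placement"].integers(spec.n_clusters)) if label == POSITIVE else -1
        )
        # corpus patches come from many tissues/regions: emulate the same
        # regional stain variation the scenes carry
        regional = rngs["appearance"].normal(0.0, spec.regional_color_shift, 3)
        _render_nucleus(
            tile,
            (center[0] + jitter[0], center[1] + jitter[1]),
            radius,
            _shifted(appearances[label], shifts, cluster, regional),
            rngs["appearance"],
            rngs["noise"],
        )
        patches[i] = np.clip(tile, 0.0, 255.0).astype(np.uint8)
    return patches, labels


def write_scene(scene: SyntheticScene, image_path, cells_path) -> None:
    """Write the raster (PNG/TIFF by suffix) and ground truth CSV.

    The CSV is the detect module's dialect plus a ``true_label`` column, so it
    can be read back as a DetectionSet.
    """
    from . import detect  # local import: avoid a cycle at module load

    save_image(scene.image, image_path)
    det = detect.DetectionSet(
        detections=[
            detect.CellDetection(
                cell_id=c.cell_id,
                centroid=c.centroid,
                bbox=_bbox_for(c, scene.spec),
            )
            for c in scene.cells
        ],
        image_ref=str(image_path),
    )
    detect.write_detections_csv(
        det, cells_path, extra_columns={"true_label": [c.true_label for c in scene.cells]}
    )


def _bbox_for(cell: GroundTruthCell, spec: SceneSpec) -> tuple[int, int, int, int]:
    x, y = cell.centroid
    r = cell.radius
    return (
        max(int(np.floor(x - r)), 0),
        max(int(np.floor(y - r)), 0),
        min(int(np.ceil(x + r)) + 1, spec.width),
        min(int(np.ceil(y + r)) + 1, spec.height),
    )


def save_image(image: np.ndarray, path) -> None:
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, image)
    else:
        from PIL import Image

        Image.fromarray(image).save(path)


def load_image(path) -> np.ndarray:
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        return np.asarray(tifffile.imread(path))
    from PIL import Image

    return np.asarray(Image.open(path).convert("RGB"))


def ground_truth_detections(scene: SyntheticScene):
    """DetectionSet built directly from ground truth (bypasses the detector)."""
    from . import detect

    return detect.DetectionSet(
        detections=[
            detect.CellDetection(
                cell_id=c.cell_id, centroid=c.centroid, bbox=_bbox_for(c, scene.spec)
            )
            for c in scene.cells
        ],
        image_ref="<ground truth>",
    )


def spec_to_dict(spec: SceneSpec) -> dict:
    d = dataclasses.asdict(spec)
    return d
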