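"""Cell detection (centroid + bounding box) and detection-file I/O.

This is an interface-compatible stand-in for the deep segmentation stage of a
full slide-annotation system: background estimation, color-distance
thresholding, connected components, and a distance-transform watershed to
split touching blobs. It emits the same contract a neural instance segmenter
would — a list of cells, each with a centroid and a tight bounding box — so
everything downstream is agnostic to the detector.

Conventions: 0-based pixel coordinates, x = column, y = row, boxes
``(x_min, y_min, x_max, y_max)`` half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

CSV_COLUMNS = ["cell_id", "x", "y", "x_min", "y_min", "x_max", "y_max"]


class DetectionParseError(ValueError):
    """A detection file contains a malformed or invariant-violating record."""


@dataclass(frozen=True)
class CellDetection:
    cell_id: int
    centroid: tuple[float, float]  # (x, y)
    bbox: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max), half-open

    def validate(self) -> None:
        x, y = self.centroid
        x_min, y_min, x_max, y_max = self.bbox
        if not (x_min <= x < x_max and y_min <= y < y_max):
            raise ValueError(
                f"cell {self.cell_id}: centroid ({x}, {y}) outside bbox {self.bbox}"
            )
        if x_max <= x_min or y_max <= y_min:
            raise ValueError(f"cell {self.cell_id}: bbox {self.bbox} has no area")


@dataclass
class DetectionSet:
    detections: list[CellDetection] = field(default_factory=list)
    image_ref: str = ""
    pixel_scale: float = 1.0  # relative physical-area-per-pixel factor

    def __post_init__(self) -> None:
        ids = [d.cell_id for d in self.detections]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate cell_ids in DetectionSet")

    def ids(self) -> list[int]:
        return [d.cell_id for d in self.detections]

    def by_id(self) -> dict[int, CellDetection]:
        return {d.cell_id: d for d in self.detections}


@dataclass(frozen=True)
class DetectionParams:
    """Knobs of the classical detection pipeline.

    min_area rejects noise specks; min_peak_distance is the expected minimum
    nucleus radius and controls watershed seeding; smoothing_sigma smooths the
    color-distance map before thresholding.
    """

    min_area: int = 25
    min_peak_distance: int = 5
    smoothing_sigma: float = 1.0
    min_foreground_distance: float = 12.0  # ignore near-background contrast


def detect_cells(image: np.ndarray, params: DetectionParams | None = None) -> DetectionSet:
    """Detect nucleus-like blobs. Deterministic; raises ValueError on empty input."""
    if image is None or image.size == 0:
        raise ValueError("empty image")
    params = params or DetectionParams()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[..., None].repeat(3, axis=2)

    background = np.median(img.reshape(-1, img.shape[2]), axis=0)
    dist = np.sqrt(((img - background) ** 2).sum(axis=2))
    dist = ndi.gaussian_filter(dist, params.smoothing_sigma)

    if dist.max() <= params.min_foreground_distance:
        return DetectionSet(detections=[])
    thresh = max(threshold_otsu(dist), params.min_foreground_distance)
    mask = dist > thresh
    mask = remove_small_objects(mask, max_size=params.min_area - 1)
    if not mask.any():
        return DetectionSet(detections=[])

    edt = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        edt, min_distance=params.min_peak_distance, labels=cc_label(mask)
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndi.label(markers > 0)
    segments = watershed(-edt, markers, mask=mask)

    detections: list[CellDetection] = []
    h, w = mask.shape
    next_id = 0
    for region in regionprops(segments):
        if region.area < params.min_area:
            continue
        ry, rx = region.centroid
        y_min, x_min, y_max, x_max = region.bbox
        det = CellDetection(
            cell_id=next_id,
            centroid=(float(rx), float(ry)),
            bbox=(
                int(np.clip(x_min, 0, w)),
                int(np.clip(y_min, 0, h)),
                int(np.clip(x_max, 0, w)),
                int(np.clip(y_max, 0, h)),
            ),
        )
        det.validate()
        detections.append(det)
        next_id += 1
    return DetectionSet(detections=detections)


# ---------------------------------------------------------------------------
# file dialects


def write_detections_csv(
    det: DetectionSet, path, extra_columns: dict[str, list] | None = None
) -> None:
    data = {
        "cell_id": [d.cell_id for d in det.detections],
        "x": [d.centroid[0] for d in det.detections],
        "y": [d.centroid[1] for d in det.detections],
        "x_min": [d.bbox[0] for d in det.detections],
        "y_min": [d.bbox[1] for d in det.detections],
        "x_max": [d.bbox[2] for d in det.detections],
        "y_max": [d.bbox[3] for d in det.detections],
    }
    for name, values in (extra_columns or {}).items():
        data[name] = values
    pd.DataFrame(data).to_csv(path, index=False)


def read_detections_csv(path) -> DetectionSet:
    """Read dialect (a). Raises DetectionParseError naming the offending row."""
    frame = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise DetectionParseError(f"missing columns: {missing}")
    detections = []
    for i, row in frame.iterrows():
        try:
            det = CellDetection(
                cell_id=int(row["cell_id"]),
                centroid=(float(row["x"]), float(row["y"])),
                bbox=(
                    int(row["x_min"]),
                    int(row["y_min"]),
                    int(row["x_max"]),
                    int(row["y_max"]),
                ),
            )
            det.validate()
        except (ValueError, TypeError) as exc:
            raise DetectionParseError(
                f"row {i} (cell_id={row.get('cell_id')}): {exc}"
            ) from exc
        detections.append(det)
    try:
        return DetectionSet(detections=detections, image_ref=str(path))
    except ValueError as exc:
        raise DetectionParseError(str(exc)) from exc


def read_truth_csv(path) -> tuple[DetectionSet, dict[int, int]]:
    """Read a CSV carrying a true_label column (scenegen output)."""
    frame = pd.read_csv(path)
    det = read_detections_csv(path)
    if "true_label" not in frame.columns:
        raise DetectionParseError("no true_label column")
    truth = {
        int(r["cell_id"]): int(r["true_label"]) for _, r in frame.iterrows()
    }
    return det, truth


def write_detections_geojson(det: DetectionSet, path) -> None:
    """Dialect (b): FeatureCollection of bbox polygons with centroid properties."""
    features = []
    for d in det.detections:
        x_min, y_min, x_max, y_max = d.bbox
        ring = [
            [x_min, y_min],
            [x_max, y_min],
            [x_max, y_max],
            [x_min, y_max],
            [x_min, y_min],
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "cell_id": d.cell_id,
                    "centroid_x": d.centroid[0],
                    "centroid_y": d.centroid[1],
                },
            }
        )
    payload = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"image_ref": det.image_ref, "pixel_scale": det.pixel_scale},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_detections_geojson(path) -> DetectionSet:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("type") != "FeatureCollection":
        raise DetectionParseError("not a FeatureCollection")
    detections = []
    for i, feature in enumerate(payload.get("features", [])):
        try:
            props = feature["properties"]
            ring = np.asarray(feature["geometry"]["coordinates"][0], dtype=float)
            det = CellDetection(
                cell_id=int(props["cell_id"]),
                centroid=(float(props["centroid_x"]), float(props["centroid_y"])),
                bbox=(
                    int(ring[:, 0].min()),
                    int(ring[:, 1].min()),
                    int(ring[:, 0].max()),
                    int(ring[:, 1].max()),
                ),
            )
            det.validate()
        except (KeyError, IndexError, ValueError, TypeError) as exc:
            raise DetectionParseError(f"feature {i}: {exc}") from exc
        detections.append(det)
    meta = payload.get("properties", {})
    try:
        return DetectionSet(
            detections=detections,
            image_ref=meta.get("image_ref", str(path)),
            pixel_scale=float(meta.get("pixel_scale", 1.0)),
        )
    except ValueError as exc:
        raise DetectionParseError(str(exc)) from exc


def write_detections(det: DetectionSet, path) -> None:
    if str(path).lower().endswith((".json", ".geojson")):
        write_detections_geojson(det, path)
    else:
        write_detections_csv(det, path)


def read_detections(path) -> DetectionSet:
    if str(path).lower().endswith((".json", ".geojson")):
        return read_detections_geojson(path)
    return read_detections_csv(path)


def match_to_ground_truth(
    det: DetectionSet, cells, max_distance_factor: float = 1.0
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections to ground-truth cells.

    A detection matches an unclaimed truth cell when the centroid distance is
    within ``max_distance_factor`` times that cell's radius. Returns
    (true_positives, false_positives, false_negatives).
    """
    truth_pos = np.array([c.centroid for c in cells], dtype=float)
    radii = np.array([c.radius for c in cells], dtype=float)
    claimed = np.zeros(len(cells), dtype=bool)
    tp = fp = 0
    for d in det.detections:
        if len(cells) == 0:
            fp += 1
            continue
        dist = np.sqrt(((truth_pos - np.asarray(d.centroid)) ** 2).sum(axis=1))
        dist[claimed] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= max_distance_factor * radii[j]:
            claimed[j] = True
            tp += 1
        else:
            fp += 1
    fn = int((~claimed).sum())
    return tp, fp, fn
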