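"""Fixed-size centroid patches and training-set normalization.

A classifier input is a 40x40 window centered on a detected cell's centroid.
When slides are scanned at different resolutions, a fixed pixel window would
cover different physical areas, so the source window side is scaled by
``sqrt(area_scale)`` and resampled back to ``out_size`` — the patch then
always covers the same physical area.

Normalization statistics are computed on training patches only and applied
everywhere; they must never be recomputed from validation or evaluation data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

#: returned by extract_patch for an edge cell under edge_policy="omit"
SKIPPED = None


@dataclass(frozen=True)
class PatchSpec:
    out_size: int = 40
    area_scale: float = 1.0
    edge_policy: str = "reflect_pad"  # or "omit"

    def validate(self) -> None:
        if self.out_size <= 0:
            raise ValueError("out_size must be > 0")
        if self.area_scale <= 0:
            raise ValueError("area_scale must be > 0")
        if self.edge_policy not in ("omit", "reflect_pad"):
            raise ValueError(f"unknown edge_policy {self.edge_policy!r}")


@dataclass(frozen=True)
class NormStats:
    mean: tuple[float, float, float]
    std: tuple[float, float, float]
    epsilon: float = 1e-7

    def validate(self) -> None:
        if any(s < 0 for s in self.std):
            raise ValueError("std must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def extract_patch(
    image: np.ndarray, centroid: tuple[float, float], spec: PatchSpec | None = None
) -> np.ndarray | None:
    """Extract the centroid patch; returns SKIPPED for edge cells under "omit".

    The source window side is ``round(out_size * sqrt(area_scale))``; when it
    equals out_size the window is copied without resampling, otherwise it is
    resampled bilinearly.
    """
    spec = spec or PatchSpec()
    spec.validate()
    h, w = image.shape[:2]
    cx, cy = centroid
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"centroid ({cx}, {cy}) outside image {w}x{h}")

    side = int(round(spec.out_size * np.sqrt(spec.area_scale)))
    x0 = int(round(cx)) - side // 2
    y0 = int(round(cy)) - side // 2
    x1, y1 = x0 + side, y0 + side

    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        if spec.edge_policy == "omit":
            return SKIPPED
        pad_x = (max(-x0, 0), max(x1 - w, 0))
        pad_y = (max(-y0, 0), max(y1 - h, 0))
        image = np.pad(image, (pad_y, pad_x, (0, 0)), mode="reflect")
        x0, x1 = x0 + pad_x[0], x1 + pad_x[0]
        y0, y1 = y0 + pad_y[0], y1 + pad_y[0]

    window = np.asarray(image[y0:y1, x0:x1], dtype=np.float64)
    if side == spec.out_size:
        return window.copy()
    return resize(
        window,
        (spec.out_size, spec.out_size),
        order=1,
        mode="edge",
        anti_aliasing=side > spec.out_size,
        preserve_range=True,
    )


def extract_patches(
    image: np.ndarray, detections, spec: PatchSpec | None = None
) -> dict[int, np.ndarray]:
    """Patches for every detection, keyed by cell_id (skipped cells absent)."""
    out: dict[int, np.ndarray] = {}
    for d in detections.detections:
        patch = extract_patch(image, d.centroid, spec)
        if patch is not SKIPPED:
            out[d.cell_id] = patch
    return out


def compute_norm_stats(patches: np.ndarray, epsilon: float = 1e-7) -> NormStats:
    """Per-channel mean/std pooled over all pixels of the training patches."""
    patches = np.asarray(patches, dtype=np.float64)
    if patches.size == 0:
        raise ValueError("cannot compute normalization statistics from no patches")
    flat = patches.reshape(-1, patches.shape[-1])
    return NormStats(
        mean=tuple(float(m) for m in flat.mean(axis=0)),
        std=tuple(float(s) for s in flat.std(axis=0)),
        epsilon=epsilon,
    )


def apply_norm(patches: np.ndarray, stats: NormStats) -> np.ndarray:
    """(pixel - mean) / max(std, epsilon), per channel. Not idempotent."""
    stats.validate()
    mean = np.asarray(stats.mean)
    std = np.maximum(np.asarray(stats.std), stats.epsilon)
    return (np.asarray(patches, dtype=np.float64) - mean) / std


def invert_norm(patches: np.ndarray, stats: NormStats) -> np.ndarray:
    stats.validate()
    mean = np.asarray(stats.mean)
    std = np.maximum(np.asarray(stats.std), stats.epsilon)
    return np.asarray(patches, dtype=np.float64) * std + mean
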