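"""Coreset-style active learning: k-center greedy selection and patch ranking.

The annotator is steered by (1) selecting from the unlabeled pool U a subset
S that is maximally diverse — each greedy step adds the point whose minimum
Euclidean distance to the labeled set plus the already-selected points is
largest (the classical greedy 2-approximation to the k-center objective) —
and (2) sending the annotator to the image patch that contains the most
points of S.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .classifier import FeatureMatrix


@dataclass
class CandidateSubset:
    selected_ids: list[int]
    selection_distances: list[float]  # max-min distance at each greedy step
    budget: int


@dataclass
class PatchRegion:
    patch_id: int
    bounds: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max), half-open
    member_cell_ids: list[int] = field(default_factory=list)


class NoPatchesRemainingError(RuntimeError):
    pass


def kcenter_greedy(
    features: FeatureMatrix,
    labeled_ids,
    budget: int,
    normalize: bool = False,
) -> CandidateSubset:
    """Greedy k-center selection from the unlabeled pool.

    Deterministic: ties are broken by the smallest cell id. If the labeled set
    is empty the first pick is the smallest unlabeled id (an arbitrary but
    fixed anchor). ``normalize`` optionally L2-normalizes rows first.
    """
    labeled_ids = set(labeled_ids)
    unlabeled = [cid for cid in features.ids if cid not in labeled_ids]
    if budget > len(unlabeled):
        raise ValueError(
            f"budget {budget} exceeds unlabeled pool size {len(unlabeled)}"
        )
    # sort by id so np.argmax's first-hit tie-break is smallest-id
    unlabeled = sorted(unlabeled)
    X = np.vstack([features.row_of(cid) for cid in unlabeled]) if unlabeled else np.empty((0, 1))
    if normalize and len(X):
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        X = X / np.where(norms > 0, norms, 1.0)

    selected: list[int] = []
    distances: list[float] = []
    if budget == 0:
        return CandidateSubset(selected_ids=[], selection_distances=[], budget=0)

    if labeled_ids:
        L = np.vstack([features.row_of(cid) for cid in sorted(labeled_ids)])
        if normalize:
            norms = np.linalg.norm(L, axis=1, keepdims=True)
            L = L / np.where(norms > 0, norms, 1.0)
        min_dist = cdist(X, L).min(axis=1)
    else:
        min_dist = np.full(len(unlabeled), np.inf)

    chosen_mask = np.zeros(len(unlabeled), dtype=bool)
    for _ in range(budget):
        masked = np.where(chosen_mask, -np.inf, min_dist)
        pick = int(np.argmax(masked))
        dist = float(min_dist[pick]) if np.isfinite(min_dist[pick]) else float("inf")
        selected.append(unlabeled[pick])
        distances.append(dist)
        chosen_mask[pick] = True
        new_d = np.sqrt(((X - X[pick]) ** 2).sum(axis=1))
        min_dist = np.minimum(min_dist, new_d)
    return CandidateSubset(selected_ids=selected, selection_distances=distances, budget=budget)


def build_patch_grid(
    width: int, height: int, patch_side: int, detections
) -> list[PatchRegion]:
    """Row-major non-overlapping grid covering the image; ragged last row/col.

    Each detection is assigned to exactly one patch by its centroid.
    """
    if patch_side <= 0:
        raise ValueError("patch_side must be > 0")
    n_cols = int(np.ceil(width / patch_side))
    n_rows = int(np.ceil(height / patch_side))
    patches = [
        PatchRegion(
            patch_id=r * n_cols + c,
            bounds=(
                c * patch_side,
                r * patch_side,
                min((c + 1) * patch_side, width),
                min((r + 1) * patch_side, height),
            ),
        )
        for r in range(n_rows)
        for c in range(n_cols)
    ]
    for d in detections.detections:
        x, y = d.centroid
        col = min(int(x // patch_side), n_cols - 1)
        row = min(int(y // patch_side), n_rows - 1)
        patches[row * n_cols + col].member_cell_ids.append(d.cell_id)
    return patches


def select_next_patch(
    subset: CandidateSubset, grid: list[PatchRegion], exclude=()
) -> int:
    """Patch (not excluded) holding the most subset points; ties -> lowest id."""
    if not grid:
        raise ValueError("empty patch grid")
    exclude = set(exclude)
    candidates = [p for p in grid if p.patch_id not in exclude]
    if not candidates:
        raise NoPatchesRemainingError("no patches remaining")
    in_subset = set(subset.selected_ids)
    best_patch = None
    best_count = -1
    for patch in candidates:  # grid is row-major ordered, so first win = lowest id
        count = sum(1 for cid in patch.member_cell_ids if cid in in_subset)
        if count > best_count:
            best_count = count
            best_patch = patch
    return best_patch.patch_id
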