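"""Human-in-the-loop annotation sessions with a simulated annotator.

Two experiment protocols are orchestrated here:

* **Workload**: the annotator initializes the classifier with 20 cells per
  class, then annotates one working patch of ~200 roughly class-balanced
  cells while the classifier suggests a label for every cell; the annotator
  accepts or corrects each suggestion, and the classifier refits after every
  five new labels. The fraction of suggestions corrected is the workload.

* **Effectiveness**: after the same initialization, the annotator is guided
  from patch to patch by the active learner until 200 cells are labeled; a
  control run repeats this with all models disabled, visiting patches in
  fixed row-major order. The labeling order is preserved in the log so
  learning curves can be computed on prefixes.

The human is replaced by an oracle that knows the ground truth but holds a
fixed, possibly wrong, *belief* about each cell: with probability
``error_rate`` its belief flips from the truth, sampled once per cell
(a person's opinion of a cell is stable within a session).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import active, classifier, patchio
from .classifier import ClassifierModel, TrainConfig

HUMAN_INITIAL = "human_initial"
SUGGESTION_ACCEPTED = "suggestion_accepted"
SUGGESTION_CORRECTED = "suggestion_corrected"


@dataclass(frozen=True)
class OracleSpec:
    """Simulated annotator: error_rate is the per-cell belief flip probability."""

    error_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")


@dataclass(frozen=True)
class SessionConfig:
    init_per_class: int = 20
    retrain_interval: int = 5
    suggestion_gate: int = 10  # min labels per class before suggestions appear
    workload_patch_target: int = 200
    effectiveness_total: int = 200
    workload_patch_side: int = 640
    effectiveness_patch_side: int = 320
    active_budget: int = 40
    embedding_layer: str = "head"  # or "backbone"
    augmented: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.suggestion_gate < 1:
            raise ValueError("suggestion_gate must be >= 1")
        if self.effectiveness_total < 2 * self.init_per_class:
            raise ValueError("effectiveness_total must cover initialization")


@dataclass(frozen=True)
class AnnotationEvent:
    order_index: int
    cell_id: int
    suggested_label: int | None  # None when no suggestion was shown
    final_label: int
    source: str

    def __post_init__(self) -> None:
        if (self.source == HUMAN_INITIAL) != (self.suggested_label is None):
            raise ValueError("human_initial events are exactly those without a suggestion")
        if self.source == SUGGESTION_CORRECTED and self.final_label == self.suggested_label:
            raise ValueError("a corrected suggestion must change the label")


@dataclass
class SessionLog:
    events: list[AnnotationEvent]
    config: dict
    retrain_indices: list[int]  # event counts at which a finetune ran
    mode: str
    scene_ref: str = ""

    def labels_in_order(self) -> list[tuple[int, int]]:
        return [(e.cell_id, e.final_label) for e in self.events]


def serialize_log(log: SessionLog) -> str:
    """JSON-lines: one header line then one line per event (stable bytes)."""
    header = {
        "mode": log.mode,
        "config": log.config,
        "retrain_indices": log.retrain_indices,
        "scene_ref": log.scene_ref,
    }
    lines = [json.dumps(header, sort_keys=True)]
    for e in log.events:
        lines.append(json.dumps(dataclasses.asdict(e), sort_keys=True))
    return "\n".join(lines) + "\n"


def write_log(log: SessionLog, path, config_snapshot: bool = True) -> None:
    """Write the JSON-lines log plus a YAML snapshot of the configuration."""
    path = str(path)
    with open(path, "w") as fh:
        fh.write(serialize_log(log))
    if config_snapshot:
        import yaml

        snapshot = path.rsplit(".", 1)[0] + ".config.yaml"
        with open(snapshot, "w") as fh:
            yaml.safe_dump({"mode": log.mode, "config": log.config}, fh)


def read_log(path) -> SessionLog:
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    header = json.loads(lines[0])
    events = [AnnotationEvent(**json.loads(ln)) for ln in lines[1:]]
    return SessionLog(
        events=events,
        config=header["config"],
        retrain_indices=header["retrain_indices"],
        mode=header["mode"],
        scene_ref=header.get("scene_ref", ""),
    )


# ---------------------------------------------------------------------------
# oracle


def sample_beliefs(
    truth: dict[int, int], oracle: OracleSpec
) -> dict[int, int]:
    """One fixed belief per cell, flipped from truth with prob error_rate."""
    oracle.validate()
    rng = np.random.default_rng(oracle.seed)
    beliefs = {}
    for cid in sorted(truth):
        flip = rng.uniform() < oracle.error_rate
        beliefs[cid] = 1 - truth[cid] if flip else truth[cid]
    return beliefs


def simulate_decision(
    oracle: OracleSpec, suggestion: int | None, true_label: int, rng: np.random.Generator
) -> tuple[int, str]:
    """One annotation decision: returns (final_label, source).

    The oracle's belief is the true label flipped with probability
    ``error_rate``. Without a suggestion the event is a plain human label;
    with one, it is accepted iff it matches the belief, else corrected.
    """
    oracle.validate()
    belief = true_label if rng.uniform() >= oracle.error_rate else 1 - true_label
    return _decide(belief, suggestion)


def _decide(belief: int, suggestion: int | None) -> tuple[int, str]:
    if suggestion is None:
        return belief, HUMAN_INITIAL
    if suggestion == belief:
        return belief, SUGGESTION_ACCEPTED
    return belief, SUGGESTION_CORRECTED


# ---------------------------------------------------------------------------
# assistants: the model stack behind suggestions and guidance


class Assistant:
    """Interface the session uses to talk to the model stack."""

    def fit(self, cell_ids: list[int], labels: list[int]) -> None:
        raise NotImplementedError

    def suggest(self, cell_ids: list[int]) -> list[int]:
        raise NotImplementedError

    def embeddings(self, cell_ids: list[int], layer: str = "head") -> classifier.FeatureMatrix:
        raise NotImplementedError


class ClassifierAssistant(Assistant):
    """The real stack: patch features cached once, head refit on demand."""

    def __init__(
        self,
        model: ClassifierModel,
        patches_by_id: dict[int, np.ndarray],
        train_cfg: TrainConfig,
    ):
        self.model = model
        self.train_cfg = train_cfg
        self.ids = sorted(patches_by_id)
        stack = np.stack([patches_by_id[cid] for cid in self.ids])
        self._features = model.features(stack)
        self._row = {cid: i for i, cid in enumerate(self.ids)}
        self.fit_count = 0

    def _rows(self, cell_ids) -> np.ndarray:
        return self._features[[self._row[cid] for cid in cell_ids]]

    def fit(self, cell_ids, labels) -> None:
        # a distinct seed per refit keeps split randomness fresh yet reproducible
        cfg = dataclasses.replace(
            self.train_cfg, seed=self.train_cfg.seed + self.fit_count
        )
        classifier.finetune(
            self.model,
            patches=None,
            labels=labels,
            cfg=cfg,
            features=self._rows(cell_ids),
        )
        self.fit_count += 1

    def suggest(self, cell_ids) -> list[int]:
        labels, _ = classifier.predict(
            self.model, patches=None, features=self._rows(cell_ids)
        )
        return [int(l) for l in labels]

    def embeddings(self, cell_ids, layer: str = "head") -> classifier.FeatureMatrix:
        return classifier.embed(
            self.model,
            patches=None,
            ids=cell_ids,
            features=self._rows(cell_ids),
            layer=layer,
        )


class StubAssistant(Assistant):
    """Suggests a fixed mapping of the ground truth; for boundary contracts."""

    def __init__(self, truth: dict[int, int], invert: bool = False, dim: int = 2):
        self.truth = truth
        self.invert = invert
        self.dim = dim

    def fit(self, cell_ids, labels) -> None:
        pass

    def suggest(self, cell_ids) -> list[int]:
        return [1 - self.truth[c] if self.invert else self.truth[c] for c in cell_ids]

    def embeddings(self, cell_ids, layer: str = "head") -> classifier.FeatureMatrix:
        rows = np.zeros((len(cell_ids), self.dim))
        rows[:, 0] = [self.truth[c] for c in cell_ids]
        return classifier.FeatureMatrix(rows=rows, ids=list(cell_ids))


# ---------------------------------------------------------------------------
# session protocols


class _Recorder:
    def __init__(self) -> None:
        self.events: list[AnnotationEvent] = []
        self.retrain_indices: list[int] = []

    def add(self, cell_id: int, suggestion: int | None, belief: int) -> AnnotationEvent:
        final, source = _decide(belief, suggestion)
        event = AnnotationEvent(
            order_index=len(self.events),
            cell_id=cell_id,
            suggested_label=suggestion,
            final_label=final,
            source=source,
        )
        self.events.append(event)
        return event


def _pick_init_cells(
    beliefs: dict[int, int],
    candidates: list[int],
    per_class: int,
    rng: np.random.Generator,
) -> list[int]:
    """init_per_class cells of each believed class, in a seeded random order."""
    chosen: list[int] = []
    for cls in (0, 1):
        of_class = sorted(c for c in candidates if beliefs[c] == cls)
        if len(of_class) < per_class:
            raise ValueError(
                f"insufficient cells of class {cls} for initialization: "
                f"{len(of_class)} < {per_class}"
            )
        chosen.extend(rng.choice(of_class, size=per_class, replace=False))
    order = rng.permutation(len(chosen))
    return [int(chosen[i]) for i in order]


def _init_region(
    grid: list[active.PatchRegion],
    beliefs: dict[int, int],
    candidates: set[int],
    per_class: int,
    rng: np.random.Generator,
) -> list[int]:
    """Candidate cells for initialization, restricted to a starting viewport.

    A human annotator finds their first examples of each class in one local
    field of view, not scattered over the whole slide. The starting viewport
    is a seeded-random patch holding at least ``per_class`` believed cells of
    each class; it is widened by neighbouring patches (in patch-id order)
    until both classes are covered, and falls back to the whole slide only if
    even that fails.
    """
    def counts(cells):
        pos = sum(beliefs[c] for c in cells)
        return min(pos, len(cells) - pos)

    usable = [
        p
        for p in grid
        if counts([c for c in p.member_cell_ids if c in candidates]) >= per_class
    ]
    if usable:
        start = usable[rng.integers(len(usable))]
        return [c for c in start.member_cell_ids if c in candidates]
    # widen: take patches in a seeded random order until both classes covered
    order = rng.permutation(len(grid))
    pool: list[int] = []
    for idx in order:
        pool.extend(c for c in grid[idx].member_cell_ids if c in candidates)
        if counts(pool) >= per_class:
            return pool
    return sorted(candidates)


def _gate_open(labels: list[int], gate: int) -> bool:
    return labels.count(0) >= gate and labels.count(1) >= gate


def _pick_working_patch(
    grid: list[active.PatchRegion],
    truth: dict[int, int],
    target: int,
) -> active.PatchRegion:
    """The annotator's ~target-cell, roughly class-balanced patch of choice."""
    best = None
    best_score = None
    for patch in grid:
        n = len(patch.member_cell_ids)
        n_pos = sum(truth[c] for c in patch.member_cell_ids)
        score = abs(n - target) + abs(2 * n_pos - n)
        if best_score is None or score < best_score:
            best_score = score
            best = patch
    return best


def run_workload_session(
    image_shape: tuple[int, int],
    detections,
    truth: dict[int, int],
    oracle: OracleSpec,
    cfg: SessionConfig,
    assistant: Assistant,
) -> SessionLog:
    """Workload protocol; ``image_shape`` is (height, width).

    The working patch is chosen first (closest to the target cell count and
    class balance), and initialization cells are drawn from outside it, so the
    event count is exactly ``2*init_per_class + patch cells``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    beliefs = sample_beliefs(truth, oracle)
    h, w = image_shape

    grid = active.build_patch_grid(w, h, cfg.workload_patch_side, detections)
    patch = _pick_working_patch(grid, truth, cfg.workload_patch_target)
    outside = [c for c in detections.ids() if c not in set(patch.member_cell_ids)]

    rec = _Recorder()
    init_pool = _init_region(grid, beliefs, set(outside), cfg.init_per_class, rng)
    init_ids = _pick_init_cells(beliefs, init_pool, cfg.init_per_class, rng)
    for cid in init_ids:
        rec.add(cid, None, beliefs[cid])
    labeled_ids = list(init_ids)
    labeled_labels = [beliefs[c] for c in init_ids]
    assistant.fit(labeled_ids, labeled_labels)
    rec.retrain_indices.append(len(rec.events))

    todo = sorted(patch.member_cell_ids)
    since_retrain = 0
    i = 0
    while i < len(todo):
        chunk = todo[i : i + (cfg.retrain_interval - since_retrain)]
        gate = _gate_open(labeled_labels, cfg.suggestion_gate)
        suggestions = assistant.suggest(chunk) if gate else [None] * len(chunk)
        for cid, sug in zip(chunk, suggestions):
            rec.add(cid, sug, beliefs[cid])
            labeled_ids.append(cid)
            labeled_labels.append(beliefs[cid])
            since_retrain += 1
        i += len(chunk)
        if since_retrain >= cfg.retrain_interval:
            assistant.fit(labeled_ids, labeled_labels)
            rec.retrain_indices.append(len(rec.events))
            since_retrain = 0

    return SessionLog(
        events=rec.events,
        config=dataclasses.asdict(cfg) | {"oracle": dataclasses.asdict(oracle)},
        retrain_indices=rec.retrain_indices,
        mode="workload",
    )


def run_effectiveness_session(
    image_shape: tuple[int, int],
    detections,
    truth: dict[int, int],
    oracle: OracleSpec,
    cfg: SessionConfig,
    assistant: Assistant | None = None,
) -> SessionLog:
    """Effectiveness protocol: guided (augmented) or row-major control run.

    Stops at exactly ``cfg.effectiveness_total`` events. In the control run
    (``cfg.augmented`` False) every event is a plain human label and no model
    is ever consulted.
    """
    cfg.validate()
    if len(truth) < cfg.effectiveness_total:
        raise ValueError("scene has fewer cells than effectiveness_total")
    if cfg.augmented and assistant is None:
        raise ValueError("augmented session needs an assistant")
    rng = np.random.default_rng(cfg.seed)
    beliefs = sample_beliefs(truth, oracle)
    h, w = image_shape
    grid = active.build_patch_grid(w, h, cfg.effectiveness_patch_side, detections)

    rec = _Recorder()
    all_ids = detections.ids()
    init_pool = _init_region(grid, beliefs, set(all_ids), cfg.init_per_class, rng)
    init_ids = _pick_init_cells(beliefs, init_pool, cfg.init_per_class, rng)
    for cid in init_ids:
        rec.add(cid, None, beliefs[cid])
    labeled_ids = list(init_ids)
    labeled_labels = [beliefs[c] for c in init_ids]

    if cfg.augmented:
        assistant.fit(labeled_ids, labeled_labels)
        rec.retrain_indices.append(len(rec.events))

    visited: set[int] = set()
    control_order: list[int] | None = None
    since_retrain = 0
    while len(rec.events) < cfg.effectiveness_total:
        labeled_set = set(labeled_ids)
        if cfg.augmented:
            feats = assistant.embeddings(all_ids, layer=cfg.embedding_layer)
            n_unlabeled = len(all_ids) - len(labeled_set)
            subset = active.kcenter_greedy(
                feats, labeled_set, min(cfg.active_budget, n_unlabeled)
            )
            candidates = [
                p
                for p in grid
                if p.patch_id not in visited
                and any(c not in labeled_set for c in p.member_cell_ids)
            ]
            if not candidates:
                raise RuntimeError("ran out of unlabeled patches before the target")
            patch_id = active.select_next_patch(
                subset, candidates, exclude=()
            )
        else:
            # the control annotator roams the slide on a path of their own:
            # a seeded random patch order, distinct per annotator seed
            if control_order is None:
                control_order = [grid[i].patch_id for i in rng.permutation(len(grid))]
            patch_id = next(
                (
                    pid
                    for pid in control_order
                    if pid not in visited
                    and any(
                        c not in labeled_set for c in grid[pid].member_cell_ids
                    )
                ),
                None,
            )
            if patch_id is None:
                raise RuntimeError("ran out of unlabeled patches before the target")
        visited.add(patch_id)
        patch = grid[patch_id]
        todo = sorted(c for c in patch.member_cell_ids if c not in labeled_set)

        i = 0
        while i < len(todo) and len(rec.events) < cfg.effectiveness_total:
            room = cfg.effectiveness_total - len(rec.events)
            step = (
                min(cfg.retrain_interval - since_retrain, room)
                if cfg.augmented
                else room
            )
            chunk = todo[i : i + step]
            if cfg.augmented and _gate_open(labeled_labels, cfg.suggestion_gate):
                suggestions = assistant.suggest(chunk)
            else:
                suggestions = [None] * len(chunk)
            for cid, sug in zip(chunk, suggestions):
                rec.add(cid, sug, beliefs[cid])
                labeled_ids.append(cid)
                labeled_labels.append(beliefs[cid])
                since_retrain += 1
            i += len(chunk)
            if cfg.augmented and since_retrain >= cfg.retrain_interval:
                assistant.fit(labeled_ids, labeled_labels)
                rec.retrain_indices.append(len(rec.events))
                since_retrain = 0

    return SessionLog(
        events=rec.events,
        config=dataclasses.asdict(cfg) | {"oracle": dataclasses.asdict(oracle)},
        retrain_indices=rec.retrain_indices,
        mode="effectiveness" if cfg.augmented else "effectiveness_control",
    )


# ---------------------------------------------------------------------------
# convenience wiring for synthetic scenes


def make_assistant(
    scene_image: np.ndarray,
    detections,
    backbone,
    train_cfg: TrainConfig | None = None,
    patch_spec: patchio.PatchSpec | None = None,
    model_seed: int = 0,
) -> ClassifierAssistant:
    """Wire patches + backbone + fresh classifier into a session assistant."""
    patches = patchio.extract_patches(scene_image, detections, patch_spec)
    model = classifier.build_classifier(backbone, seed=model_seed)
    return ClassifierAssistant(
        model, patches, train_cfg or TrainConfig(seed=model_seed)
    )
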