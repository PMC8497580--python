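"""Outcome measures: annotation workload and annotation effectiveness.

Workload is the fraction of model suggestions the annotator changed
(workload reduction = 1 − fraction). Effectiveness of an annotated data set
is the normalized area under the validation-accuracy-versus-N learning
curve, N ≤ 200, where the first N events of the session (labeling order
preserved) train a fresh classifier head and accuracy is measured on held-out
labels; two data sets are compared by their AUC ratio. Because real sessions
have no ground truth, evaluation labels come from *other* annotators'
control runs (the N−1 protocol): an annotator's augmented and control curves
share one evaluation set, making their AUC ratio a fair comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import classifier as clf
from .classifier import TrainConfig
from .session import SessionLog

DEFAULT_GRID = tuple(range(0, 201, 10))
CHANCE_ACCURACY = 0.5  # binary task; convention for untrainable prefixes


@dataclass
class WorkloadResult:
    suggestions_shown: int
    suggestions_corrected: int

    @property
    def workload_fraction(self) -> float:
        return self.suggestions_corrected / self.suggestions_shown

    @property
    def workload_reduction(self) -> float:
        return 1.0 - self.workload_fraction


@dataclass
class LearningCurve:
    n_values: np.ndarray
    accuracy: np.ndarray  # mean over repeats, per N
    sd: np.ndarray
    repeats: int

    @property
    def auc(self) -> float:
        return effectiveness_auc(self)


def workload_fraction(log: SessionLog) -> WorkloadResult:
    """Corrected / shown over suggestion events; errors if none were shown."""
    shown = sum(1 for e in log.events if e.suggested_label is not None)
    if shown == 0:
        raise ValueError("workload undefined: the log contains no suggestion events")
    corrected = sum(1 for e in log.events if e.source == "suggestion_corrected")
    return WorkloadResult(suggestions_shown=shown, suggestions_corrected=corrected)


def learning_curve(
    log: SessionLog,
    train_features_by_id: dict[int, np.ndarray],
    eval_features: np.ndarray,
    eval_labels: np.ndarray,
    backbone,
    grid=DEFAULT_GRID,
    repeats: int = 10,
    train_cfg: TrainConfig | None = None,
    base_seed: int = 0,
) -> LearningCurve:
    """Accuracy vs N on order-preserved prefixes of the session's labels.

    ``train_features_by_id`` holds precomputed backbone embeddings of the
    annotator's cells; ``eval_features``/``eval_labels`` define the held-out
    evaluation set (they never influence training). For each N the first N
    events train a fresh head, ``repeats`` times with different training
    seeds; prefixes with fewer than two labels in either class score chance
    accuracy by convention.
    """
    eval_labels = np.asarray(eval_labels, dtype=int)
    if len(eval_labels) == 0:
        raise ValueError("empty evaluation set")
    grid = np.asarray(sorted(grid), dtype=int)
    if (grid < 0).any():
        raise ValueError("grid values must be >= 0")
    pairs = log.labels_in_order()
    train_cfg = train_cfg or TrainConfig()

    means = np.empty(len(grid))
    sds = np.empty(len(grid))
    for gi, n in enumerate(grid):
        prefix = pairs[:n]
        labels = np.array([lab for _, lab in prefix], dtype=int)
        if len(prefix) == 0 or min(
            (labels == 0).sum(), (labels == 1).sum()
        ) < 2:
            means[gi] = CHANCE_ACCURACY
            sds[gi] = 0.0
            continue
        X = np.vstack([train_features_by_id[cid] for cid, _ in prefix])
        accs = np.empty(repeats)
        for r in range(repeats):
            seed = base_seed * 10_000 + r
            model = clf.build_classifier(backbone, seed=seed)
            cfg_r = TrainConfig(
                learning_rate=train_cfg.learning_rate,
                momentum=train_cfg.momentum,
                max_epochs=train_cfg.max_epochs,
                patience=train_cfg.patience,
                train_fraction=train_cfg.train_fraction,
                retrain_interval=train_cfg.retrain_interval,
                batch_size=train_cfg.batch_size,
                seed=seed,
            )
            clf.finetune(model, patches=None, labels=labels, cfg=cfg_r, features=X)
            pred, _ = clf.predict(model, patches=None, features=eval_features)
            accs[r] = float((pred == eval_labels).mean())
        means[gi] = accs.mean()
        sds[gi] = accs.std()
    return LearningCurve(n_values=grid, accuracy=means, sd=sds, repeats=repeats)


def effectiveness_auc(curve) -> float:
    """Normalized trapezoid AUC of accuracy vs N (dimensionless, in [0, 1])."""
    n = np.asarray(curve.n_values, dtype=float)
    acc = np.asarray(curve.accuracy, dtype=float)
    if len(n) < 2:
        raise ValueError("AUC needs at least two grid points")
    return float(np.trapezoid(acc, n) / (n[-1] - n[0]))


def auc_ratio(augmented, control) -> float:
    """Percent improvement: 100 * (AUC_aug / AUC_control − 1)."""
    a = effectiveness_auc(augmented)
    c = effectiveness_auc(control)
    if c == 0.0:
        raise ValueError("control AUC is zero; ratio undefined")
    return 100.0 * (a / c - 1.0)


@dataclass
class AnnotatorEvaluation:
    annotator: int
    curve_augmented: LearningCurve
    curve_control: LearningCurve
    auc_ratio_percent: float


def cross_annotator_effectiveness(
    runs: list[tuple[SessionLog, SessionLog]],
    features_by_id: dict[int, np.ndarray],
    backbone,
    grid=DEFAULT_GRID,
    repeats: int = 10,
    train_cfg: TrainConfig | None = None,
) -> list[AnnotatorEvaluation]:
    """The N−1 evaluation protocol over simulated annotators on one scene.

    ``runs[i]`` is annotator i's (augmented, control) log pair. For each
    annotator the evaluation set is the union of the *control*-run labels of
    all other annotators, minus any cell the annotator themselves labeled in
    either run — so both of their curves share one evaluation set.
    """
    if len(runs) < 2:
        raise ValueError("no evaluation data: need at least 2 annotators")
    results = []
    for i, (aug_log, ctl_log) in enumerate(runs):
        own_cells = {e.cell_id for e in aug_log.events} | {
            e.cell_id for e in ctl_log.events
        }
        eval_labels_by_cell: dict[int, int] = {}
        for j, (_, other_ctl) in enumerate(runs):
            if j == i:
                continue
            for e in other_ctl.events:
                if e.cell_id not in own_cells:
                    eval_labels_by_cell[e.cell_id] = e.final_label
        if not eval_labels_by_cell:
            raise ValueError(f"annotator {i}: evaluation set is empty")
        eval_ids = sorted(eval_labels_by_cell)
        eval_X = np.vstack([features_by_id[c] for c in eval_ids])
        eval_y = np.array([eval_labels_by_cell[c] for c in eval_ids], dtype=int)

        # common random numbers: both curves use the same per-repeat training
        # seeds, so the (identical) initialization prefixes contribute
        # identically and the paired AUC difference reflects the runs alone
        curves = [
            learning_curve(
                log,
                features_by_id,
                eval_X,
                eval_y,
                backbone,
                grid=grid,
                repeats=repeats,
                train_cfg=train_cfg,
                base_seed=i,
            )
            for log in (aug_log, ctl_log)
        ]
        results.append(
            AnnotatorEvaluation(
                annotator=i,
                curve_augmented=curves[0],
                curve_control=curves[1],
                auc_ratio_percent=auc_ratio(curves[0], curves[1]),
            )
        )
    return results


def plot_learning_curves(curves: dict[str, LearningCurve], path) -> None:
    """Accuracy-vs-N plot of one or more labeled curves (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, curve in curves.items():
        ax.errorbar(curve.n_values, curve.accuracy, yerr=curve.sd, label=label, capsize=2)
    ax.set_xlabel("N training samples (labeling order preserved)")
    ax.set_ylabel("validation accuracy")
    ax.set_ylim(0.0, 1.05)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def curve_to_frame(curve: LearningCurve):
    import pandas as pd

    return pd.DataFrame(
        {"N": curve.n_values, "mean_accuracy": curve.accuracy, "sd": curve.sd}
    )


def summary_json(
    workload: WorkloadResult | None = None,
    augmented: LearningCurve | None = None,
    control: LearningCurve | None = None,
) -> dict:
    out: dict = {}
    if workload is not None:
        out["workload_fraction"] = workload.workload_fraction
        out["workload_reduction"] = workload.workload_reduction
    if augmented is not None:
        out["auc_augmented"] = effectiveness_auc(augmented)
    if control is not None:
        out["auc_control"] = effectiveness_auc(control)
    if augmented is not None and control is not None:
        out["auc_ratio_percent"] = auc_ratio(augmented, control)
    return out
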