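"""Reproducible end-to-end studies: the workload and effectiveness protocols
run over synthetic scenes with simulated annotators.

These are the entry points behind ``scripts/acceptance.py`` and the study
numbers quoted in the documentation. Problem sizes are chosen for a desk-scale
single-CPU run: patch-scale scenes for the workload study, slide-like scenes
(budget covers only a few percent of cells) for the effectiveness study.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import metrics, patchio, scenegen, session
from .backbone import pretrain_backbone

PRETRAIN_CORPUS_SIZE = 400


def _backbone_for(spec: scenegen.SceneSpec, seed: int):
    corpus_spec = dataclasses.replace(spec, seed=seed)
    corpus, _ = scenegen.generate_pretraining_corpus(corpus_spec, PRETRAIN_CORPUS_SIZE)
    return pretrain_backbone(corpus)


@dataclass
class WorkloadStudy:
    fractions: list[float]
    mean_fraction: float
    mean_reduction_percent: float


def run_workload_study(
    n_seeds: int = 10,
    error_rate: float = 0.0,
    base_seed: int = 0,
    scene_spec_factory=scenegen.separable_scene_spec,
) -> WorkloadStudy:
    """Full-loop workload protocol over independent scene seeds.

    Each seed renders a fresh scene, pretrains a backbone on its own corpus,
    and runs the workload session with the real classifier stack.
    """
    fractions = []
    for k in range(n_seeds):
        seed = base_seed + k
        spec = scene_spec_factory(seed=seed)
        scene = scenegen.generate_scene(spec)
        backbone = _backbone_for(spec, seed=10_000 + seed)
        det = scenegen.ground_truth_detections(scene)
        oracle = session.OracleSpec(error_rate=error_rate, seed=seed)
        cfg = session.SessionConfig(seed=seed)
        assistant = session.make_assistant(scene.image, det, backbone, model_seed=seed)
        log = session.run_workload_session(
            scene.image.shape[:2], det, scene.truth, oracle, cfg, assistant
        )
        fractions.append(metrics.workload_fraction(log).workload_fraction)
    mean_fraction = float(np.mean(fractions))
    return WorkloadStudy(
        fractions=fractions,
        mean_fraction=mean_fraction,
        mean_reduction_percent=100.0 * (1.0 - mean_fraction),
    )


@dataclass
class EffectivenessStudy:
    auc_augmented: list[float]
    auc_control: list[float]
    auc_ratios_percent: list[float]
    mean_auc_augmented: float = field(init=False)
    mean_auc_control: float = field(init=False)
    mean_auc_ratio_percent: float = field(init=False)

    def __post_init__(self):
        self.mean_auc_augmented = float(np.mean(self.auc_augmented))
        self.mean_auc_control = float(np.mean(self.auc_control))
        self.mean_auc_ratio_percent = float(np.mean(self.auc_ratios_percent))

    @property
    def paired_differences(self) -> np.ndarray:
        return np.asarray(self.auc_augmented) - np.asarray(self.auc_control)

    def one_sided_p_value(self) -> float:
        """p-value of the one-sided paired t-test for aug > control."""
        from scipy import stats

        d = self.paired_differences
        t = stats.ttest_1samp(d, 0.0, alternative="greater")
        return float(t.pvalue)


def run_effectiveness_study(
    scene_seeds=(0, 1, 2, 3, 4),
    n_annotators: int = 4,
    repeats: int = 5,
    error_rate: float = 0.05,
    scene_spec_factory=scenegen.slide_scale_spec,
) -> EffectivenessStudy:
    """Paired augmented-vs-control effectiveness protocol.

    Per scene, ``n_annotators`` simulated annotators each complete an
    augmented and a control run; learning curves follow the order-preserving
    prefix protocol and are evaluated on the pooled control labels of the
    other annotators (the N-1 rule), giving one paired AUC comparison per
    annotator.
    """
    aug_aucs: list[float] = []
    ctl_aucs: list[float] = []
    ratios: list[float] = []
    for seed in scene_seeds:
        spec = scene_spec_factory(seed=seed)
        scene = scenegen.generate_scene(spec)
        backbone = _backbone_for(spec, seed=10_000 + seed)
        det = scenegen.ground_truth_detections(scene)
        patches = patchio.extract_patches(scene.image, det)
        ids = sorted(patches)
        feats = backbone.transform(np.stack([patches[i] for i in ids]))
        features_by_id = {cid: feats[k] for k, cid in enumerate(ids)}

        runs = []
        for a in range(n_annotators):
            run_seed = seed * 100 + a
            oracle = session.OracleSpec(error_rate=error_rate, seed=run_seed)
            assistant = session.make_assistant(
                scene.image, det, backbone, model_seed=run_seed
            )
            cfg = session.SessionConfig(seed=run_seed, augmented=True)
            aug = session.run_effectiveness_session(
                scene.image.shape[:2], det, scene.truth, oracle, cfg, assistant
            )
            ctl = session.run_effectiveness_session(
                scene.image.shape[:2],
                det,
                scene.truth,
                oracle,
                dataclasses.replace(cfg, augmented=False),
                None,
            )
            runs.append((aug, ctl))

        for ev in metrics.cross_annotator_effectiveness(
            runs, features_by_id, backbone, repeats=repeats
        ):
            aug_aucs.append(metrics.effectiveness_auc(ev.curve_augmented))
            ctl_aucs.append(metrics.effectiveness_auc(ev.curve_control))
            ratios.append(ev.auc_ratio_percent)
    return EffectivenessStudy(
        auc_augmented=aug_aucs, auc_control=ctl_aucs, auc_ratios_percent=ratios
    )


@dataclass
class DetectorStudy:
    precision: float
    recall: float


def run_detector_study(n_seeds: int = 20, base_seed: int = 0) -> DetectorStudy:
    """Detector precision/recall against generator ground truth on
    non-overlapping 50-cell scenes."""
    from . import detect

    tp = fp = fn = 0
    for k in range(n_seeds):
        spec = dataclasses.replace(
            scenegen.SceneSpec(seed=base_seed + k), width=640, height=640, n_cells=50
        )
        scene = scenegen.generate_scene(spec)
        det = detect.detect_cells(scene.image)
        a, b, c = detect.match_to_ground_truth(det, scene.cells)
        tp, fp, fn = tp + a, fp + b, fn + c
    return DetectorStudy(
        precision=tp / max(tp + fp, 1), recall=tp / max(tp + fn, 1)
    )
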