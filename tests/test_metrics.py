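import dataclasses

import numpy as np
import pytest

from cellannotator import metrics, session
from cellannotator.backbone import StubBackbone
from cellannotator.metrics import LearningCurve
from conftest import separable_embeddings


def make_log(events):
    return session.SessionLog(
        events=events, config={}, retrain_indices=[], mode="workload"
    )


def suggestion_events(n_shown, n_corrected, n_initial=0):
    events = []
    idx = 0
    for _ in range(n_initial):
        events.append(session.AnnotationEvent(idx, idx, None, 1, session.HUMAN_INITIAL))
        idx += 1
    for i in range(n_shown):
        corrected = i < n_corrected
        events.append(
            session.AnnotationEvent(
                idx,
                idx,
                0 if corrected else 1,
                1,
                session.SUGGESTION_CORRECTED if corrected else session.SUGGESTION_ACCEPTED,
            )
        )
        idx += 1
    return events


class TestWorkloadFraction:
    def test_zero_corrections_full_reduction(self):
        result = metrics.workload_fraction(make_log(suggestion_events(180, 0)))
        assert result.workload_fraction == 0.0
        assert result.workload_reduction == 1.0

    def test_counting(self):
        result = metrics.workload_fraction(make_log(suggestion_events(180, 27)))
        assert result.workload_fraction == pytest.approx(0.15)
        assert result.workload_reduction == pytest.approx(0.85)

    def test_reduction_is_complement_of_fraction(self):
        # the reported convention: reduction = 1 - fraction, exactly
        result = metrics.workload_fraction(make_log(suggestion_events(200, 19)))
        assert result.workload_fraction + result.workload_reduction == 1.0
        assert 0.0 <= result.workload_fraction <= 1.0

    def test_initial_events_excluded_from_denominator(self):
        result = metrics.workload_fraction(
            make_log(suggestion_events(100, 10, n_initial=40))
        )
        assert result.suggestions_shown == 100

    def test_no_suggestions_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            metrics.workload_fraction(make_log(suggestion_events(0, 0, n_initial=5)))


def curve(n, acc):
    n = np.asarray(n, float)
    acc = np.asarray(acc, float)
    return LearningCurve(n_values=n, accuracy=acc, sd=np.zeros_like(acc), repeats=1)


class TestAuc:
    def test_flat_curve_closed_form(self):
        c = curve(range(0, 201, 10), [0.8] * 21)
        assert metrics.effectiveness_auc(c) == pytest.approx(0.8, abs=1e-12)

    def test_linear_curve_closed_form(self):
        n = np.arange(0, 201, 10)
        c = curve(n, 0.5 + 0.5 * n / 200)
        assert metrics.effectiveness_auc(c) == pytest.approx(0.75, abs=1e-12)

    def test_piecewise_linear_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(0)
        knots_n = np.array([0, 30, 80, 140, 200], dtype=float)
        knots_a = rng.uniform(0.4, 1.0, len(knots_n))
        c = curve(knots_n, knots_a)
        dense_n = np.linspace(0, 200, 200_001)
        dense_a = np.interp(dense_n, knots_n, knots_a)
        oracle = np.trapezoid(dense_a, dense_n) / 200.0
        assert metrics.effectiveness_auc(c) == pytest.approx(oracle, abs=1e-9)

    def test_single_point_curve_rejected(self):
        with pytest.raises(ValueError):
            metrics.effectiveness_auc(curve([100], [0.9]))

    def test_auc_monotone_under_pointwise_dominance(self):
        rng = np.random.default_rng(1)
        n = np.arange(0, 201, 20)
        low = rng.uniform(0.4, 0.8, len(n))
        high = low + rng.uniform(0.0, 0.2, len(n))
        assert metrics.effectiveness_auc(curve(n, high)) >= metrics.effectiveness_auc(
            curve(n, low)
        )


class TestAucRatio:
    def test_identical_curves_zero_percent(self):
        c = curve(range(0, 201, 10), [0.8] * 21)
        assert metrics.auc_ratio(c, c) == pytest.approx(0.0)

    def test_arithmetic(self):
        a = curve([0, 200], [0.790, 0.790])
        b = curve([0, 200], [0.750, 0.750])
        assert metrics.auc_ratio(a, b) == pytest.approx(100 * (0.790 / 0.750 - 1), abs=1e-9)
        assert metrics.auc_ratio(a, b) == pytest.approx(5.33, abs=0.01)

    def test_ratio_is_asymmetric(self):
        a = curve([0, 200], [0.9, 0.9])
        b = curve([0, 200], [0.6, 0.6])
        assert metrics.auc_ratio(a, b) != pytest.approx(-metrics.auc_ratio(b, a))

    def test_zero_control_rejected(self):
        a = curve([0, 200], [0.5, 0.5])
        z = curve([0, 200], [0.0, 0.0])
        with pytest.raises(ValueError):
            metrics.auc_ratio(a, z)


def _session_log_from_labels(pairs, mode="effectiveness"):
    events = [
        session.AnnotationEvent(i, cid, None, lab, session.HUMAN_INITIAL)
        for i, (cid, lab) in enumerate(pairs)
    ]
    return session.SessionLog(events=events, config={}, retrain_indices=[], mode=mode)


class TestLearningCurve:
    @pytest.fixture()
    def world(self):
        X_all, y_all = separable_embeddings(210, separation=4.0, seed=3)
        rng = np.random.default_rng(3)
        order = rng.permutation(len(X_all))
        train_idx, eval_idx = order[:300], order[300:]
        pairs = [(int(i), int(y_all[i])) for i in train_idx]
        feats = {int(i): X_all[i] for i in train_idx}
        eval_X, eval_y = X_all[eval_idx], y_all[eval_idx]
        bb = StubBackbone(lambda p: p.reshape(len(p), -1)[:, :32], 32)
        return pairs, feats, eval_X, eval_y, bb

    def test_untrainable_prefixes_score_chance(self, world):
        pairs, feats, eval_X, eval_y, bb = world
        log = _session_log_from_labels(pairs)
        c = metrics.learning_curve(
            log, feats, eval_X, eval_y, bb, grid=(0, 2, 100), repeats=2
        )
        assert c.accuracy[0] == 0.5  # N=0: nothing to train on
        assert c.sd[0] == 0.0

    def test_separable_data_reaches_high_accuracy(self, world):
        pairs, feats, eval_X, eval_y, bb = world
        log = _session_log_from_labels(pairs)
        c = metrics.learning_curve(
            log, feats, eval_X, eval_y, bb, grid=(0, 100, 200), repeats=3
        )
        assert c.accuracy[-1] >= 0.95

    def test_repeats_change_only_averaging(self, world):
        pairs, feats, eval_X, eval_y, bb = world
        log = _session_log_from_labels(pairs)
        kw = dict(grid=(0, 60), train_cfg=None, base_seed=0)
        c1 = metrics.learning_curve(log, feats, eval_X, eval_y, bb, repeats=1, **kw)
        c10 = metrics.learning_curve(log, feats, eval_X, eval_y, bb, repeats=4, **kw)
        assert np.array_equal(c1.n_values, c10.n_values)
        assert c1.repeats == 1 and c10.repeats == 4

    def test_empty_eval_rejected(self, world):
        pairs, feats, *_ , bb = world
        log = _session_log_from_labels(pairs)
        with pytest.raises(ValueError):
            metrics.learning_curve(log, feats, np.empty((0, 32)), [], bb)


def test_learning_curve_plot_written(tmp_path):
    c = curve(range(0, 201, 20), np.linspace(0.5, 0.95, 11))
    out = tmp_path / "curves.png"
    metrics.plot_learning_curves({"guided": c, "control": c}, out)
    assert out.stat().st_size > 0


class TestCrossAnnotator:
    def _runs(self, n_annotators, n_cells=400):
        rng = np.random.default_rng(9)
        feats = {i: rng.normal(0, 1, 8) for i in range(n_cells)}
        runs = []
        for a in range(n_annotators):
            cells = rng.choice(n_cells, size=120, replace=False)
            aug = _session_log_from_labels([(int(c), int(c % 2)) for c in cells[:60]])
            ctl = _session_log_from_labels([(int(c), int(c % 2)) for c in cells[60:]])
            runs.append((aug, ctl))
        return runs, feats

    def test_single_annotator_rejected(self):
        runs, feats = self._runs(1)
        bb = StubBackbone(lambda p: p.reshape(len(p), -1)[:, :8], 8)
        with pytest.raises(ValueError, match="at least 2"):
            metrics.cross_annotator_effectiveness(runs, feats, bb)

    def test_evaluation_excludes_own_cells_and_is_shared(self):
        runs, feats = self._runs(3)
        bb = StubBackbone(lambda p: p.reshape(len(p), -1)[:, :8], 8)
        results = metrics.cross_annotator_effectiveness(
            runs, feats, bb, grid=(0, 30, 60), repeats=1
        )
        assert len(results) == 3
        for i, r in enumerate(results):
            # both curves share the grid, so the AUC ratio is well defined
            assert np.array_equal(
                r.curve_augmented.n_values, r.curve_control.n_values
            )
            own = {e.cell_id for e in runs[i][0].events} | {
                e.cell_id for e in runs[i][1].events
            }
            eval_cells = set()
            for j, (_, octl) in enumerate(runs):
                if j != i:
                    eval_cells |= {e.cell_id for e in octl.events}
            eval_cells -= own
            # audit of the construction rule the metric implements
            assert eval_cells and not (eval_cells & own)
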