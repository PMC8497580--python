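import dataclasses

import numpy as np
import pytest

from cellannotator import metrics, scenegen, session


SMALL_CFG = session.SessionConfig(
    init_per_class=10,
    workload_patch_target=40,
    workload_patch_side=320,
    effectiveness_total=80,
    effectiveness_patch_side=160,
    seed=0,
)


@pytest.fixture(scope="module")
def sim(small_setup_module):
    return small_setup_module


@pytest.fixture(scope="module")
def small_setup_module(request):
    # reuse the session-scoped fixture through the request machinery
    return request.getfixturevalue("small_setup")


def _stub_run(setup, invert=False, error_rate=0.0, cfg=SMALL_CFG, seed=0):
    scene = setup["scene"]
    oracle = session.OracleSpec(error_rate=error_rate, seed=seed)
    assistant = session.StubAssistant(scene.truth, invert=invert)
    return session.run_workload_session(
        scene.image.shape[:2],
        setup["detections"],
        scene.truth,
        oracle,
        dataclasses.replace(cfg, seed=seed),
        assistant,
    )


class TestSimulatedDecisions:
    def test_exact_oracle_accepts_true_suggestions(self):
        rng = np.random.default_rng(0)
        oracle = session.OracleSpec(error_rate=0.0)
        final, source = session.simulate_decision(oracle, 1, 1, rng)
        assert (final, source) == (1, session.SUGGESTION_ACCEPTED)

    def test_exact_oracle_corrects_wrong_suggestions(self):
        rng = np.random.default_rng(0)
        oracle = session.OracleSpec(error_rate=0.0)
        final, source = session.simulate_decision(oracle, 0, 1, rng)
        assert (final, source) == (1, session.SUGGESTION_CORRECTED)

    def test_no_suggestion_gives_human_initial(self):
        rng = np.random.default_rng(0)
        oracle = session.OracleSpec(error_rate=0.0)
        final, source = session.simulate_decision(oracle, None, 0, rng)
        assert (final, source) == (0, session.HUMAN_INITIAL)

    def test_correction_rate_matches_binomial(self):
        """With correct suggestions, corrections happen exactly when the
        oracle's belief flips: rate ~ Binomial(n, eps)."""
        eps, n = 0.1, 10_000
        rng = np.random.default_rng(42)
        oracle = session.OracleSpec(error_rate=eps)
        corrected = sum(
            session.simulate_decision(oracle, 1, 1, rng)[1]
            == session.SUGGESTION_CORRECTED
            for _ in range(n)
        )
        se = np.sqrt(eps * (1 - eps) / n)
        assert abs(corrected / n - eps) <= 3 * se

    def test_belief_sampled_once_per_cell(self):
        truth = {i: i % 2 for i in range(50)}
        oracle = session.OracleSpec(error_rate=0.3, seed=7)
        assert session.sample_beliefs(truth, oracle) == session.sample_beliefs(
            truth, oracle
        )


class TestWorkloadSession:
    def test_perfect_stub_yields_zero_workload(self, sim):
        log = _stub_run(sim)
        assert metrics.workload_fraction(log).workload_fraction == 0.0

    def test_wrong_stub_yields_full_workload(self, sim):
        log = _stub_run(sim, invert=True)
        assert metrics.workload_fraction(log).workload_fraction == 1.0

    def test_event_count_and_retrain_schedule(self, sim):
        log = _stub_run(sim)
        init = 2 * SMALL_CFG.init_per_class
        n_patch_cells = len(log.events) - init
        assert n_patch_cells > 0
        # init events carry no suggestion, patch events all do
        assert all(e.source == session.HUMAN_INITIAL for e in log.events[:init])
        assert all(e.suggested_label is not None for e in log.events[init:])
        expected = [init + session.SessionConfig().retrain_interval * k
                    for k in range(n_patch_cells // 5 + 1)]
        assert log.retrain_indices == expected[: len(log.retrain_indices)]
        assert log.retrain_indices[0] == init

    def test_order_index_strictly_increasing(self, sim):
        log = _stub_run(sim)
        order = [e.order_index for e in log.events]
        assert order == list(range(len(order)))

    def test_no_cell_annotated_twice(self, sim):
        log = _stub_run(sim)
        ids = [e.cell_id for e in log.events]
        assert len(ids) == len(set(ids))

    def test_insufficient_class_cells_raise(self, backbone):
        spec = scenegen.separable_scene_spec(
            seed=4, width=512, height=512, n_cells=30, positive_fraction=0.1
        )
        scene = scenegen.generate_scene(spec)
        det = scenegen.ground_truth_detections(scene)
        with pytest.raises(ValueError, match="insufficient cells"):
            session.run_workload_session(
                scene.image.shape[:2],
                det,
                scene.truth,
                session.OracleSpec(error_rate=0.0, seed=0),
                dataclasses.replace(SMALL_CFG, init_per_class=20),
                session.StubAssistant(scene.truth),
            )


class TestEffectivenessSession:
    def _run(self, sim, augmented, seed=0):
        scene = sim["scene"]
        cfg = dataclasses.replace(SMALL_CFG, augmented=augmented, seed=seed)
        assistant = session.StubAssistant(scene.truth) if augmented else None
        return session.run_effectiveness_session(
            scene.image.shape[:2],
            sim["detections"],
            scene.truth,
            session.OracleSpec(error_rate=0.0, seed=seed),
            cfg,
            assistant,
        )

    def test_stops_at_exactly_total(self, sim):
        log = self._run(sim, augmented=True)
        assert len(log.events) == SMALL_CFG.effectiveness_total

    def test_control_has_no_model_interactions(self, sim):
        log = self._run(sim, augmented=False)
        assert len(log.events) == SMALL_CFG.effectiveness_total
        assert all(e.source == session.HUMAN_INITIAL for e in log.events)
        assert log.retrain_indices == []

    def test_augmented_retrain_count_matches_protocol(self, sim):
        log = self._run(sim, augmented=True)
        post_init = SMALL_CFG.effectiveness_total - 2 * SMALL_CFG.init_per_class
        assert len(log.retrain_indices) == post_init // 5 + 1

    def test_no_cell_annotated_twice(self, sim):
        for augmented in (True, False):
            ids = [e.cell_id for e in self._run(sim, augmented).events]
            assert len(ids) == len(set(ids))


class TestDeterminismAndSerialization:
    def test_workload_logs_byte_identical(self, sim):
        a = session.serialize_log(_stub_run(sim, seed=5))
        b = session.serialize_log(_stub_run(sim, seed=5))
        assert a.encode() == b.encode()

    def test_different_seeds_differ(self, sim):
        a = session.serialize_log(_stub_run(sim, seed=5))
        b = session.serialize_log(_stub_run(sim, seed=6))
        assert a != b

    def test_log_roundtrip(self, sim, tmp_path):
        log = _stub_run(sim)
        path = tmp_path / "run.jsonl"
        session.write_log(log, path)
        back = session.read_log(path)
        assert back.events == log.events
        assert back.retrain_indices == log.retrain_indices
        assert back.mode == log.mode
        # YAML config snapshot written alongside
        import yaml

        snapshot = yaml.safe_load((tmp_path / "run.config.yaml").read_text())
        assert snapshot["mode"] == "workload"
        assert snapshot["config"]["init_per_class"] == SMALL_CFG.init_per_class


def test_event_invariants_enforced():
    with pytest.raises(ValueError):
        session.AnnotationEvent(0, 1, None, 1, session.SUGGESTION_ACCEPTED)
    with pytest.raises(ValueError):
        session.AnnotationEvent(0, 1, 1, 1, session.SUGGESTION_CORRECTED)
    with pytest.raises(ValueError):
        session.AnnotationEvent(0, 1, 1, 1, session.HUMAN_INITIAL)


def test_real_assistant_loop_learns(small_setup):
    """End-to-end workload run with the real classifier stack: on a separable
    scene with an exact oracle the suggestions are mostly right."""
    scene = small_setup["scene"]
    assistant = session.ClassifierAssistant.__new__(session.ClassifierAssistant)
    # build via the public wiring helper
    assistant = session.make_assistant(
        scene.image, small_setup["detections"], small_setup["backbone"], model_seed=1
    )
    log = session.run_workload_session(
        scene.image.shape[:2],
        small_setup["detections"],
        scene.truth,
        session.OracleSpec(error_rate=0.0, seed=1),
        dataclasses.replace(SMALL_CFG, seed=1),
        assistant,
    )
    frac = metrics.workload_fraction(log).workload_fraction
    assert frac <= 0.3
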