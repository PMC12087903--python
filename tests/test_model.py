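"""Full-network forward contracts, training bookkeeping, evaluation, and
protocol structure."""

import json

import numpy as np
import pytest

from stgdan import (
    EmotionGraphModel,
    EvalReport,
    ModelConfig,
    WindowSample,
    make_fixture,
    make_windows,
)
from stgdan.training import (
    _subject_windows,
    evaluate,
    run_cross_subject,
    run_within_subject,
    train,
)


def _windows(n, T=3, N=4, F=2, C=2, seed=0, domain="source"):
    rng = np.random.default_rng(seed)
    return [
        WindowSample(rng.normal(size=(T, N, F)), center_index=1,
                     label=i % C, domain=domain)
        for i in range(n)
    ]


class TestForward:
    def test_output_shapes(self):
        cfg = ModelConfig(d=3, K=2, F_out=5)
        model = EmotionGraphModel(cfg, n_channels=62, n_bands=5, n_classes=3)
        out = model.forward(np.random.default_rng(0).normal(size=(4, 7, 62, 5)), lam=0.5)
        assert out["logits"].shape == (4, 3)
        assert out["features"].shape == (4, 64)
        assert out["domain_probs"].shape == (4, 2)
        assert out["A"].shape == (4, 62, 62)
        assert out["L_gcn"].shape == ()
        # extractor input is N*F_out = 310 at reference dimensions
        assert model.extractor.widths[0] == 310

    def test_identical_windows_identical_rows(self, rng):
        cfg = ModelConfig(d=1)
        model = EmotionGraphModel(cfg, 4, 3, 2)
        w = rng.normal(size=(3, 4, 3))
        out = model.forward(np.stack([w, w]), lam=0.3)
        for key in ("logits", "features", "domain_probs"):
            np.testing.assert_allclose(out[key].value[0], out[key].value[1], atol=1e-12)

    def test_attention_ablations_use_neutral_elements(self, rng):
        cfg = ModelConfig(d=1, ablation={"no_temporal_attention", "no_spatial_attention"})
        model = EmotionGraphModel(cfg, 4, 3, 2)
        X = rng.normal(size=(2, 3, 4, 3))
        out = model.forward(X)
        np.testing.assert_allclose(out["Q"].value, np.broadcast_to(np.eye(3), (2, 3, 3)))
        np.testing.assert_allclose(out["P"].value, np.ones((2, 4, 4)))

    def test_knn_ablation_zeroes_graph_loss(self, rng):
        cfg = ModelConfig(d=1, ablation={"knn_graph"}, knn_k=2)
        model = EmotionGraphModel(cfg, 5, 3, 2)
        out = model.forward(rng.normal(size=(2, 3, 5, 3)))
        assert float(out["L_gcn"].value) == 0.0
        np.testing.assert_allclose(out["A"].value.sum(-1), 1.0, atol=1e-9)

    def test_no_discriminator_drops_branch(self, rng):
        cfg = ModelConfig(d=1, ablation={"no_discriminator"})
        model = EmotionGraphModel(cfg, 4, 3, 2)
        assert model.forward(rng.normal(size=(1, 3, 4, 3)))["domain_probs"] is None

    def test_adjacency_rows_stochastic_in_pipeline(self, rng):
        model = EmotionGraphModel(ModelConfig(d=1), 6, 4, 3)
        out = model.forward(rng.normal(size=(3, 3, 6, 4)))
        A = out["A"].value
        assert np.all(A >= 0)
        np.testing.assert_allclose(A.sum(-1), 1.0, atol=1e-6)

    def test_shape_mismatch_names_stage(self, rng):
        model = EmotionGraphModel(ModelConfig(d=1), 4, 3, 2)
        with pytest.raises(ValueError, match="stage input"):
            model.forward(rng.normal(size=(2, 5, 4, 3)))

    def test_state_dict_round_trip(self, rng):
        cfg = ModelConfig(d=1, seed=4)
        m1 = EmotionGraphModel(cfg, 4, 3, 2)
        m2 = EmotionGraphModel(cfg.with_(seed=99), 4, 3, 2)
        m2.load_state_dict(m1.state_dict())
        X = rng.normal(size=(2, 3, 4, 3))
        np.testing.assert_array_equal(m1.forward(X)["logits"].value,
                                      m2.forward(X)["logits"].value)


class TestTrain:
    def test_empty_source_rejected(self):
        with pytest.raises(ValueError, match="source"):
            train([], _windows(4), ModelConfig(d=1))

    def test_empty_target_requires_no_discriminator(self):
        cfg = ModelConfig(d=1, max_epochs=1)
        with pytest.raises(ValueError, match="target"):
            train(_windows(8), [], cfg)
        model, log = train(_windows(8), [], cfg.with_(ablation={"no_discriminator"}))
        assert len(log) == 1
        assert "L_disc" not in log[0] and "lambda" not in log[0]

    def test_log_decomposition_identity(self):
        """Logged total always equals L_classifier + L_gcn - lambda*L_disc."""
        cfg = ModelConfig(d=1, max_epochs=3, batch_size=8)
        _, log = train(_windows(16, seed=1), _windows(8, seed=2, domain="target"), cfg)
        for entry in log:
            expected = (entry["L_classifier"] + entry["L_gcn"]
                        - entry["lambda"] * entry["L_disc"])
            assert entry["total"] == pytest.approx(expected, abs=1e-6)

    def test_same_seed_identical_loss_curves(self):
        cfg = ModelConfig(d=1, max_epochs=3, batch_size=8, seed=7)
        src, tgt = _windows(12, seed=1), _windows(6, seed=2, domain="target")
        _, log1 = train(src, tgt, cfg)
        _, log2 = train(src, tgt, cfg)
        assert log1 == log2

    def test_early_stopping_on_train_accuracy(self):
        cont = make_fixture("tiny_within", seed=0)
        cfg = ModelConfig(d=3, max_epochs=200, early_stop_train_acc=0.99,
                          ablation={"no_discriminator"})
        src = [w for t in cont.trials[:6] for w in make_windows(t, 3)]
        _, log = train(src, [], cfg)
        assert len(log) < 200
        assert log[-1]["train_accuracy"] >= 0.99


class TestEvaluate:
    def _perfect_model(self):
        """A model stub whose logits echo a fixed prediction list."""
        class Stub:
            C = 3

            def __init__(self, preds):
                self.preds = np.asarray(preds)

            def forward(self, X, lam=0.0):
                import stgdan.autodiff as ad
                logits = np.zeros((len(X), 3))
                logits[np.arange(len(X)), self.preds[: len(X)]] = 10.0
                self.preds = self.preds[len(X):]
                return {"logits": ad.tensor(logits)}
        return Stub

    def test_hand_counted_accuracy_four_of_six(self):
        windows = [WindowSample(np.zeros((1, 2, 2)), 0, label=l) for l in [0, 1, 2, 0, 1, 2]]
        stub = self._perfect_model()([0, 1, 2, 0, 2, 0])  # 4 of 6 correct
        res = evaluate(stub, windows)
        assert res["window_accuracy"] == pytest.approx(4 / 6)
        assert res["confusion"].sum() == 6

    def test_perfect_predictions_are_100(self):
        windows = [WindowSample(np.zeros((1, 2, 2)), 0, label=l) for l in [0, 1, 2]]
        res = evaluate(self._perfect_model()([0, 1, 2]), windows)
        assert res["window_accuracy"] == 1.0

    def test_majority_vote_per_trial(self):
        windows = [WindowSample(np.zeros((1, 2, 2)), 0, label=0, trial_key="a"),
                   WindowSample(np.zeros((1, 2, 2)), 1, label=0, trial_key="a"),
                   WindowSample(np.zeros((1, 2, 2)), 2, label=0, trial_key="a"),
                   WindowSample(np.zeros((1, 2, 2)), 0, label=1, trial_key="b")]
        # trial a: votes {0,0,1} -> 0 correct; trial b: vote {2} -> wrong
        res = evaluate(self._perfect_model()([0, 0, 1, 2]), windows)
        assert res["majority_accuracy"] == pytest.approx(0.5)

    def test_empty_windows_rejected(self):
        model = EmotionGraphModel(ModelConfig(d=1), 2, 2, 2)
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, [])


class TestProtocols:
    def test_within_subject_partition_exact(self):
        """Source/target trial sets are disjoint and exhaustive per subject."""
        cont = make_fixture("tiny_within", seed=1)
        m = 9
        src = cont.trials[:m]
        tgt = cont.trials[m:]
        assert len(src) + len(tgt) == len(cont.trials)
        assert not {id(t) for t in src} & {id(t) for t in tgt}

    def test_within_subject_report_bookkeeping(self):
        cont = make_fixture("tiny_within", seed=1)
        cfg = ModelConfig(d=3, max_epochs=2, source_trials=9)
        report = run_within_subject(cont, cfg)
        assert len(report.per_fold_accuracy) == 1
        assert report.fold_names == ["S00"]
        assert report.mean_accuracy == pytest.approx(np.mean(report.per_fold_accuracy))
        assert report.std_accuracy == pytest.approx(np.std(report.per_fold_accuracy))
        # confusion rows sum to the fold's target window count: 6 trials * 24
        assert np.asarray(report.confusion).sum() == 6 * (30 - 2 * 3)

    def test_within_subject_no_target_trials_rejected(self):
        cont = make_fixture("tiny_within", seed=1)
        cfg = ModelConfig(d=3, max_epochs=1, source_trials=15)
        with pytest.raises(ValueError, match="no target"):
            run_within_subject(cont, cfg)

    def test_loso_each_subject_target_once(self):
        cont = make_fixture("tiny_cross", seed=2)
        cfg = ModelConfig(d=1, max_epochs=2)
        report = run_cross_subject(cont, cfg)
        assert sorted(report.fold_names) == sorted(cont.subject_ids)
        assert len(report.per_fold_accuracy) == 4

    def test_loso_single_subject_rejected(self):
        cont = make_fixture("tiny_within", seed=0)
        with pytest.raises(ValueError, match="2 subjects"):
            run_cross_subject(cont, ModelConfig(d=1))

    def test_window_domains_and_counts(self):
        cont = make_fixture("tiny_cross", seed=0)
        trials = cont.trials_for("S00")
        wins = _subject_windows(trials, d=1, domain="target", key_prefix="S00")
        assert len(wins) == len(trials) * (18 - 2)
        assert all(w.domain == "target" for w in wins)
        assert len({w.trial_key for w in wins}) == len(trials)

    def test_report_json_round_trip(self):
        report = EvalReport.from_folds([50.0, 75.0], [np.eye(2, dtype=int)] * 2,
                                       {"d": 1}, ["a", "b"])
        payload = json.loads(report.to_json())
        assert payload["mean_accuracy"] == 62.5
        assert payload["fold_names"] == ["a", "b"]

    def test_uninformative_features_are_chance(self):
        """With zero class separation the labels are unlearnable and
        within-subject accuracy sits at 1/C within sampling noise."""
        from stgdan.simulate import SimConfig, generate_dataset
        cont, _ = generate_dataset(SimConfig(
            n_subjects=1, n_trials_per_subject=24, trial_length=12,
            n_channels=6, n_bands=3, n_classes=3, class_sep=0.0, seed=3))
        cfg = ModelConfig(d=1, max_epochs=15, source_trials=15,
                          ablation={"no_discriminator"})
        report = run_within_subject(cont, cfg)
        # 9 target trials; window votes are correlated within trial, so the
        # effective n is small — allow a generous band around 33.3%
        assert 10.0 < report.mean_accuracy < 60.0
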