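import numpy as np
import pytest

import methsubtype.train as train_mod
from methsubtype.losses import RampSchedule, assign_pseudo_labels, cross_entropy
from methsubtype.matrix import LabeledDataset, SubtypeVocabulary, UnlabeledDataset
from methsubtype.model import init_params, predict_proba
from methsubtype.simulate import SyntheticSpec, generate
from methsubtype.train import ModelBundle, TrainingConfig, finetune, fit, pretrain

from conftest import nearest_centroid_accuracy


def params_equal(a, b):
    return all(
        np.array_equal(x, y)
        for x, y in zip(a.weights + a.biases, b.weights + b.biases)
    )


def small_problem(seed=0, n=20, k=6):
    rng = np.random.default_rng(seed)
    X = rng.random((n, k))
    y = rng.integers(0, 2, n)
    Xu = rng.random((n // 2, k))
    return X, y, Xu


class TestPretrain:
    def test_zero_epochs_is_identity(self):
        X, y, _ = small_problem()
        p0 = init_params(6, (3,), 2, seed=0)
        p1, history = pretrain(p0, (X, y), TrainingConfig(epochs_pretrain=0, hidden_sizes=(3,)))
        assert params_equal(p0, p1)
        assert len(history) == 0

    def test_deterministic_given_seed(self):
        X, y, _ = small_problem()
        cfg = TrainingConfig(epochs_pretrain=30, hidden_sizes=(3,), seed=4)
        p0 = init_params(6, (3,), 2, seed=4)
        a, _ = pretrain(p0, (X, y), cfg)
        b, _ = pretrain(p0, (X, y), cfg)
        assert params_equal(a, b)

    def test_missing_values_rejected(self):
        X, y, _ = small_problem()
        X[0, 0] = np.nan
        p = init_params(6, (3,), 2, seed=0)
        with pytest.raises(ValueError, match="missing"):
            pretrain(p, (X, y), TrainingConfig(hidden_sizes=(3,), epochs_pretrain=1))

    def test_absent_vocabulary_class_warns_but_trains(self, toy_matrix):
        vocab = SubtypeVocabulary(("A", "B", "C"))
        complete = toy_matrix.copy()
        complete.values[np.isnan(complete.values)] = 0.5
        dataset = LabeledDataset(complete, np.array([0, 1]), vocab)
        p = init_params(3, (2,), 3, seed=0)
        _, history = pretrain(p, dataset, TrainingConfig(epochs_pretrain=2, hidden_sizes=(2,)))
        assert any("C" in w for w in history.warnings)

    def test_reaches_high_accuracy_on_separable_data(self, separable_2class):
        X, y = separable_2class
        # the oracle confirms the data itself is separable
        assert nearest_centroid_accuracy(X, y, X, y) >= 0.95
        cfg = TrainingConfig(
            lr_pretrain=1e-3, epochs_pretrain=300, hidden_sizes=(32, 16), seed=0
        )
        p = init_params(X.shape[1], cfg.hidden_sizes, 2, seed=0)
        p, _ = pretrain(p, (X, y), cfg)
        accuracy = (predict_proba(p, X).predicted == y).mean()
        assert accuracy >= 0.95

    def test_loss_decreases_over_training(self, separable_2class):
        X, y = separable_2class
        cfg = TrainingConfig(lr_pretrain=1e-3, epochs_pretrain=200, hidden_sizes=(8, 4), seed=1)
        p0 = init_params(X.shape[1], cfg.hidden_sizes, 2, seed=1)
        p1, _ = pretrain(p0, (X, y), cfg)
        loss_before = cross_entropy(predict_proba(p0, X).posteriors, y)
        loss_after = cross_entropy(predict_proba(p1, X).posteriors, y)
        assert loss_after <= loss_before

    def test_class_oversampling_changes_trajectory(self):
        X, y, _ = small_problem()
        p = init_params(6, (3,), 2, seed=0)
        cfg = TrainingConfig(epochs_pretrain=20, hidden_sizes=(3,), seed=0)
        cfg_over = TrainingConfig(
            epochs_pretrain=20, hidden_sizes=(3,), seed=0, class_oversample={1: 3}
        )
        a, _ = pretrain(p, (X, y), cfg)
        b, _ = pretrain(p, (X, y), cfg_over)
        assert not params_equal(a, b)


class TestFinetuneReductions:
    def setup_run(self, seed=7, epochs=40):
        X, y, Xu = small_problem(seed)
        p = init_params(6, (3, 2), 2, seed=seed)
        base = dict(
            lr_finetune=1e-3, epochs_finetune=epochs, hidden_sizes=(3, 2), seed=seed
        )
        return X, y, Xu, p, base

    def test_alpha_f_zero_equals_empty_unlabeled_bitwise(self):
        X, y, Xu, p, base = self.setup_run()
        cfg_zero = TrainingConfig(ramp=RampSchedule(alpha_f=0.0), **base)
        cfg_empty = TrainingConfig(**base)
        a, _ = finetune(p, (X, y), Xu, cfg_zero)
        b, _ = finetune(p, (X, y), None, cfg_empty)
        assert params_equal(a, b)

    def test_empty_unlabeled_equals_supervised_training_bitwise(self):
        X, y, _, p, base = self.setup_run()
        a, _ = finetune(p, (X, y), None, TrainingConfig(**base))
        sup_cfg = TrainingConfig(
            lr_pretrain=base["lr_finetune"],
            epochs_pretrain=base["epochs_finetune"],
            hidden_sizes=(3, 2),
            seed=base["seed"],
        )
        b, _ = pretrain(p, (X, y), sup_cfg)
        assert params_equal(a, b)

    def test_feature_mismatch_rejected(self):
        X, y, _, p, base = self.setup_run()
        Xu_bad = np.random.default_rng(0).random((4, 5))
        with pytest.raises(ValueError, match="features"):
            finetune(p, (X, y), Xu_bad, TrainingConfig(**base))


class TestFinetuneBehavior:
    def test_history_alpha_follows_the_ramp(self):
        X, y, Xu = small_problem()
        p = init_params(6, (3,), 2, seed=0)
        cfg = TrainingConfig(
            epochs_finetune=30,
            hidden_sizes=(3,),
            ramp=RampSchedule(t1=10, t2=20, alpha_f=0.05),
        )
        _, history = finetune(p, (X, y), Xu, cfg)
        frame = history.to_frame()
        assert len(frame) == 30
        assert (frame.loc[frame.epoch < 10, "alpha"] == 0).all()
        ramp = frame.loc[(frame.epoch >= 10) & (frame.epoch < 20), "alpha"].to_numpy()
        assert (np.diff(ramp) > 0).all()
        assert (frame.loc[frame.epoch >= 20, "alpha"] == 0.05).all()
        assert (frame.n_pseudo_included == Xu.shape[0]).all()

    def test_pseudo_labels_recomputed_from_current_params_each_epoch(self, monkeypatch):
        X, y, Xu = small_problem()
        p = init_params(6, (3,), 2, seed=0)
        calls = []
        real = assign_pseudo_labels

        def spy(params, unlabeled, confidence_threshold=None, epoch=0):
            pseudo = real(params, unlabeled, confidence_threshold, epoch)
            fresh = predict_proba(params, np.asarray(unlabeled)).predicted
            calls.append(np.array_equal(pseudo.labels, fresh))
            return pseudo

        monkeypatch.setattr(train_mod, "assign_pseudo_labels", spy)
        cfg = TrainingConfig(epochs_finetune=15, hidden_sizes=(3,), lr_finetune=1e-2)
        finetune(p, (X, y), Xu, cfg)
        assert len(calls) == 15  # one refresh per full-batch update
        assert all(calls)

    def test_confidence_threshold_reduces_included_count(self):
        X, y, Xu = small_problem()
        p = init_params(6, (3,), 2, seed=0)
        base = dict(epochs_finetune=5, hidden_sizes=(3,))
        _, hist_open = finetune(p, (X, y), Xu, TrainingConfig(**base))
        _, hist_tau = finetune(
            p, (X, y), Xu, TrainingConfig(confidence_threshold=0.999, **base)
        )
        open_counts = hist_open.to_frame().n_pseudo_included
        tau_counts = hist_tau.to_frame().n_pseudo_included
        assert (tau_counts <= open_counts).all()

    def test_minibatch_mode_runs_and_is_deterministic(self):
        X, y, Xu = small_problem(n=24)
        p = init_params(6, (3,), 2, seed=0)
        cfg = TrainingConfig(epochs_finetune=8, hidden_sizes=(3,), batch_size=8, seed=3)
        a, hist = finetune(p, (X, y), Xu, cfg)
        b, _ = finetune(p, (X, y), Xu, cfg)
        assert params_equal(a, b)
        assert len(hist) == 8


class TestFitPipeline:
    def test_finetune_zero_epochs_equals_pretrain_alone(self):
        labeled, unlabeled, _, _ = generate(SyntheticSpec(seed=3, n_labeled=30, n_unlabeled=20, n_test=5))
        cfg = TrainingConfig(
            lr_pretrain=1e-3, epochs_pretrain=40, epochs_finetune=0, hidden_sizes=(8, 4), seed=3
        )
        bundle, history = fit(labeled, unlabeled, cfg)
        p = init_params(labeled.matrix.n_probes, (8, 4), 3, seed=3)
        p, _ = pretrain(p, labeled, cfg)
        assert params_equal(bundle.params, p)
        assert set(history.to_frame().phase) == {"pretrain"}

    def test_full_pipeline_deterministic(self):
        labeled, unlabeled, _, _ = generate(SyntheticSpec(seed=5, n_labeled=20, n_unlabeled=15, n_test=5))
        cfg = TrainingConfig(
            lr_pretrain=1e-3, epochs_pretrain=20, epochs_finetune=25, hidden_sizes=(4, 3), seed=5
        )
        a, _ = fit(labeled, unlabeled, cfg)
        b, _ = fit(labeled, unlabeled, cfg)
        assert params_equal(a.params, b.params)

    def test_bundle_save_load_predict_round_trip(self, tmp_path):
        labeled, unlabeled, test, _ = generate(
            SyntheticSpec(seed=1, n_labeled=20, n_unlabeled=10, n_test=8)
        )
        cfg = TrainingConfig(
            lr_pretrain=1e-3, epochs_pretrain=15, epochs_finetune=10, hidden_sizes=(4, 3), seed=1
        )
        bundle, _ = fit(labeled, unlabeled, cfg)
        path = tmp_path / "model.npz"
        bundle.save(path)
        loaded = ModelBundle.load(path)
        assert loaded.cpg_ids == bundle.cpg_ids
        assert loaded.vocabulary.names == bundle.vocabulary.names
        a = bundle.predict(test.matrix)
        b = loaded.predict(test.matrix)
        assert a.equals(b)
        posterior_cols = list(bundle.vocabulary.names)
        assert np.allclose(a[posterior_cols].sum(axis=1), 1.0, atol=1e-6)
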