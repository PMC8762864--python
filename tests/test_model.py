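"""Classifier core: gradient correctness, optimisation regime contracts,
separability/null oracles, prediction semantics, serialisation."""

import numpy as np
import pytest

from m6acall._nn import BiLSTMNet
from m6acall.model import (
    EnsembleResults,
    ModelConfig,
    ModificationEnsemble,
    should_stop,
    train_submodel,
)
from m6acall.training import MotifDataset

FAST = ModelConfig(hidden_size=8, fc_sizes=(8, 4), batch_size=16, max_epochs=6,
                   level_augment_sd=0.0, seed=0)


def _dataset(n=400, shift=5.0, motif="GGACT", seed=0, permute_labels=False):
    """Synthetic motif dataset with realistic feature scales.

    Class 1 carries a centre-peaked current shift across the window plus
    longer dwell and lower quality at the centre — the signal structure
    the architecture is built for.  ``shift`` scales the centre shift;
    a plain threshold on the centre mean is the separability oracle.
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    profile = shift * np.array([0.25, 0.5, 1.0, 0.5, 0.25])
    level = rng.normal(100.0, 1.5, size=(n, 5)) + profile * y[:, None]
    dwell = rng.lognormal(0.12 * shift * y, 0.35, size=(5, n)).T
    qual = np.clip(rng.normal(12.0 - 0.6 * shift * y, 2.5, size=(5, n)).T, 1, 40)
    X = np.stack(
        [
            level,
            level + rng.normal(0, 0.4, size=(n, 5)),
            np.abs(rng.normal(1.5, 0.15, size=(n, 5))),
            dwell,
            qual,
        ],
        axis=2,
    )
    if permute_labels:
        y = rng.permutation(y)
    n_train = int(0.7 * n)
    return MotifDataset(
        motif=motif,
        X_train=X[:n_train], y_train=y[:n_train],
        X_test=X[n_train:], y_test=y[n_train:],
        ratio=0.7, trainable=True,
    )


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        net = BiLSTMNet(n_features=3, n_steps=3, hidden_size=4, n_layers=2,
                        fc_sizes=(6, 5), seed=1)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3, 3))
        y = rng.integers(0, 2, 5)
        _, grads = net.loss_and_grads(X, y)
        eps = 1e-6
        for name in ("l0f_Wx", "l1b_Wh", "l0b_b", "fc0_W", "fc2_b"):
            p = net.params[name]
            flat_idx = [(0,) * p.ndim, tuple(d - 1 for d in p.shape)]
            for idx in flat_idx:
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = net.loss_and_grads(X, y)
                p[idx] = orig - eps
                lm, _ = net.loss_and_grads(X, y)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_softmax_outputs_are_probabilities(self):
        net = BiLSTMNet(hidden_size=4, n_layers=1, fc_sizes=(4, 4), seed=0)
        probs = net.forward(np.random.default_rng(0).normal(size=(7, 5, 5)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs >= 0).all()


class TestEarlyStoppingAndSchedule:
    def test_constant_accuracy_stops_after_patience(self):
        assert not should_stop([0.8], 3)
        assert not should_stop([0.8, 0.8, 0.8], 3)
        assert should_stop([0.8, 0.8, 0.8, 0.8], 3)  # patience+1 epochs total

    def test_improvement_resets_patience(self):
        assert not should_stop([0.8, 0.7, 0.7, 0.9], 3)
        assert should_stop([0.8, 0.7, 0.7, 0.9, 0.85, 0.85, 0.85], 3)

    def test_lr_trace_follows_gamma_decay(self):
        sub = train_submodel(_dataset(300), FAST)
        trace = sub.history.lr_trace()
        expected = [5e-4 * 0.1**e for e in range(len(trace))]
        np.testing.assert_allclose(trace, expected, rtol=1e-12)

    def test_best_checkpoint_retained(self):
        sub = train_submodel(_dataset(300), FAST)
        accs = [e["val_accuracy"] for e in sub.history.epochs]
        assert sub.history.best_val_accuracy == max(accs)
        assert accs[sub.history.best_epoch] == max(accs)

    def test_epochs_run_respects_patience(self):
        cfg = ModelConfig(hidden_size=8, fc_sizes=(8, 4), batch_size=16,
                          max_epochs=30, level_augment_sd=0.0, seed=0)
        sub = train_submodel(_dataset(300), cfg)
        h = sub.history
        if h.epochs_run < cfg.max_epochs:  # stopped early
            assert h.epochs_run == h.best_epoch + cfg.patience + 1


class TestTraining:
    def test_separable_data_reaches_oracle_accuracy(self):
        """Large centre-mean shift: a plain threshold on that feature is a
        >=99% oracle, and the network must match it held-out."""
        shift = 8.0
        ds = _dataset(2000, shift=shift)
        thresh_acc = np.mean((ds.X_test[:, 2, 0] > 100 + shift / 2) == ds.y_test)
        assert thresh_acc >= 0.99
        cfg = ModelConfig(batch_size=16, max_epochs=6, level_augment_sd=0.0,
                          seed=0)
        sub = train_submodel(ds, cfg)
        p = sub.predict_proba(ds.X_test)
        acc = np.mean((p >= 0.5) == ds.y_test)
        assert acc >= 0.99

    def test_permuted_labels_give_chance_accuracy(self):
        ds = _dataset(1200, shift=5.0, permute_labels=True)
        sub = train_submodel(ds, FAST)
        p = sub.predict_proba(ds.X_test)
        acc = np.mean((p >= 0.5) == ds.y_test)
        se = np.sqrt(0.25 / len(ds.y_test))
        assert abs(acc - 0.5) <= 3 * se

    def test_single_class_refused(self):
        ds = _dataset(100)
        ds.y_train[:] = 1
        with pytest.raises(ValueError, match="single class"):
            train_submodel(ds, FAST)

    def test_training_deterministic_under_seed(self):
        ds = _dataset(200)
        p1 = train_submodel(ds, FAST).predict_proba(ds.X_test)
        p2 = train_submodel(ds, FAST).predict_proba(ds.X_test)
        np.testing.assert_array_equal(p1, p2)


@pytest.fixture(scope="module")
def fitted():
    ds = {"GGACT": _dataset(300, seed=1), "AAACA": _dataset(300, seed=2,
                                                            motif="AAACA")}
    return ModificationEnsemble(ds, FAST).fit(), ds


class TestPrediction:
    def test_same_event_same_probability(self, fitted):
        results, ds = fitted
        X = ds["GGACT"].X_test[:10]
        p1, _ = results.predict_proba(X, ["GGACT"] * 10)
        p2, _ = results.predict_proba(X, ["GGACT"] * 10)
        np.testing.assert_array_equal(p1, p2)

    def test_batch_order_invariance(self, fitted):
        results, ds = fitted
        X = np.concatenate([ds["GGACT"].X_test[:8], ds["AAACA"].X_test[:8]])
        motifs = ["GGACT"] * 8 + ["AAACA"] * 8
        p, _ = results.predict_proba(X, motifs)
        order = np.random.default_rng(0).permutation(16)
        p_shuf, _ = results.predict_proba(X[order], [motifs[i] for i in order])
        np.testing.assert_allclose(p_shuf, p[order], atol=1e-12)

    def test_unknown_motif_skipped_not_fabricated(self, fitted):
        results, ds = fitted
        X = ds["GGACT"].X_test[:6]
        motifs = ["GGACT"] * 3 + ["AGACT"] * 3  # no AGACT sub-model
        p, skipped = results.predict_proba(X, motifs)
        assert skipped.sum() == 3
        assert np.isnan(p[skipped]).all()
        assert np.isfinite(p[~skipped]).all()
        # conservation: predicted + skipped = input
        assert (~skipped).sum() + skipped.sum() == len(motifs)

    def test_save_load_round_trip(self, fitted, tmp_path):
        results, ds = fitted
        results.save(tmp_path / "model")
        back = EnsembleResults.load(tmp_path / "model")
        X = ds["GGACT"].X_test[:20]
        p1, _ = results.predict_proba(X, ["GGACT"] * 20)
        p2, _ = back.predict_proba(X, ["GGACT"] * 20)
        np.testing.assert_allclose(p1, p2, atol=1e-12)
        assert back.config == results.config


class TestEndToEndModelQuality:
    def test_per_motif_auc_on_simulated_test_split(self, recovery_report):
        """Every sub-model separates held-out simulated classes well."""
        assert (recovery_report.per_motif["auc"] >= 0.95).all()

    def test_scaler_centres_training_features(self, recovery_report):
        sub = next(iter(recovery_report.results.submodels.values()))
        assert sub.scaler_mean.shape == (5, 5)
        assert (sub.scaler_sd > 0).all()
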