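"""Per-motif classifier ensemble: model and results objects.

Each of the 12 RRACH 5-mers gets an independent binary classifier over
the 5x5 signal-feature window (a stacked bidirectional LSTM with a
three-layer fully connected head, see :mod:`m6acall._nn`).  Training uses
softmax/cross-entropy, Adam with an initial learning rate of 5e-4 decayed
by a factor 0.1 every epoch, and early stopping when validation accuracy
fails to improve for 3 consecutive epochs; the best-validation checkpoint
is retained.

The public surface follows the model/results idiom: build a
:class:`ModificationEnsemble` from per-motif datasets, ``fit()`` it, and
use the returned :class:`EnsembleResults` for prediction, evaluation,
summary tables and (de)serialisation.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._nn import AdamOptimizer, BiLSTMNet
from .training import MotifDataset

__all__ = [
    "ModelConfig",
    "TrainingHistory",
    "FittedSubmodel",
    "ModificationEnsemble",
    "EnsembleResults",
    "train_submodel",
    "should_stop",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one sub-model (shared across the ensemble).

    ``learning_rate``, ``lr_gamma`` (multiplicative per-epoch decay) and
    ``patience`` default to the published optimisation regime; hidden and
    fully connected widths, batch size and the validation fraction carved
    from the training split are this package's defaults, recorded in the
    model metadata.

    ``level_augment_sd`` (pA): during training, each batch's mean/median
    columns receive a per-event, per-position level offset drawn
    N(0, sd).  Baseline current levels vary with flanking sequence context
    from site to site; the classifiers must key on the modification's
    level *shift*, not on the absolute baselines of the (few) training
    sites, and this augmentation enforces that invariance.  Set 0 to
    disable.
    """

    hidden_size: int = 64
    n_hidden_layers: int = 3
    fc_sizes: tuple[int, int] = (64, 32)
    learning_rate: float = 5e-4
    lr_gamma: float = 0.1
    patience: int = 3
    max_epochs: int = 30
    batch_size: int = 16
    validation_fraction: float = 0.1
    normalize: bool = True
    class_balance: str = "none"  # none | class_weights | downsample (none: as published)
    level_augment_sd: float = 1.0
    log_dwell: bool = True  # dwell times are ~log-normal; train on log(dwell)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 < self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must be in (0, 0.5)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.class_balance not in ("none", "downsample"):
            raise ValueError("class_balance must be 'none' or 'downsample'")


@dataclass
class TrainingHistory:
    """Per-epoch log: learning rate, training loss, validation accuracy."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -np.inf
    epochs_run: int = 0

    def lr_trace(self) -> list[float]:
        return [e["lr"] for e in self.epochs]


def should_stop(val_accuracies: Sequence[float], patience: int) -> bool:
    """Early-stopping rule: stop once ``patience`` successive epochs have
    failed to improve on the running-best validation accuracy."""
    if len(val_accuracies) <= patience:
        return False
    best_idx = int(np.argmax(val_accuracies))
    return len(val_accuracies) - 1 - best_idx >= patience


@dataclass
class FittedSubmodel:
    """One trained per-motif classifier with its feature scaler."""

    motif: str
    net: BiLSTMNet
    scaler_mean: np.ndarray  # (window, 5)
    scaler_sd: np.ndarray
    history: TrainingHistory
    n_train: int
    n_val: int
    n_test: int
    log_dwell: bool = True

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Modification probability per event; X is (n, window, 5)."""
        X = _transform_features(np.asarray(X, dtype=float), self.log_dwell)
        Xn = (X - self.scaler_mean) / self.scaler_sd
        return self.net.forward(Xn)[:, 1]


_DWELL_COL = 3


def _transform_features(X: np.ndarray, log_dwell: bool) -> np.ndarray:
    """Feature transform applied identically at training and prediction."""
    if not log_dwell:
        return X
    X = X.copy()
    X[..., _DWELL_COL] = np.log(np.maximum(X[..., _DWELL_COL], 1e-9))
    return X


def _fit_scaler(X: np.ndarray, enabled: bool) -> tuple[np.ndarray, np.ndarray]:
    if not enabled or len(X) == 0:
        shape = X.shape[1:] if X.ndim == 3 else (1,)
        return np.zeros(shape), np.ones(shape)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-8] = 1.0
    return mean, sd


def train_submodel(dataset: MotifDataset, cfg: ModelConfig) -> FittedSubmodel:
    """Train one per-motif classifier.

    A validation subset (``cfg.validation_fraction`` of the training
    partition) drives early stopping; the checkpoint with the best
    validation accuracy is retained.  Deterministic under a fixed config
    seed and single-threaded execution.
    """
    X, y = _transform_features(dataset.X_train, cfg.log_dwell), dataset.y_train
    if len(np.unique(y)) < 2:
        raise ValueError(f"motif {dataset.motif}: training data has a single class")
    ss = np.random.SeedSequence([cfg.seed, _motif_seed(dataset.motif)])
    split_rng, init_seed_seq, shuffle_seq = ss.spawn(3)

    if cfg.class_balance == "downsample":
        rng = np.random.default_rng(split_rng)
        n_min = min(int((y == 0).sum()), int((y == 1).sum()))
        keep = np.concatenate([
            rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
            for c in (0, 1)
        ])
        keep.sort()
        X, y = X[keep], y[keep]

    rng = np.random.default_rng(split_rng)
    order = rng.permutation(len(y))
    n_val = max(1, int(round(cfg.validation_fraction * len(y))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    X_val, y_val = X[val_idx], y[val_idx]
    X_tr, y_tr = X[train_idx], y[train_idx]
    if len(np.unique(y_tr)) < 2:
        raise ValueError(f"motif {dataset.motif}: training subset lost a class")

    scaler_mean, scaler_sd = _fit_scaler(X, cfg.normalize)
    X_tr = (X_tr - scaler_mean) / scaler_sd
    X_val = (X_val - scaler_mean) / scaler_sd

    net = BiLSTMNet(
        n_features=X.shape[2],
        n_steps=X.shape[1],
        hidden_size=cfg.hidden_size,
        n_layers=cfg.n_hidden_layers,
        fc_sizes=cfg.fc_sizes,
        seed=int(init_seed_seq.generate_state(1)[0] % (2**31)),
    )
    opt = AdamOptimizer(net.params)
    shuffle_rng = np.random.default_rng(shuffle_seq)
    # mean/median columns, in scaled units, for level augmentation
    aug_scale = None
    if cfg.level_augment_sd > 0:
        aug_scale = cfg.level_augment_sd / scaler_sd[:, :2]  # (window, 2)
    history = TrainingHistory()
    best_params = net.get_params()
    val_accs: list[float] = []
    for epoch in range(cfg.max_epochs):
        lr = cfg.learning_rate * cfg.lr_gamma**epoch
        perm = shuffle_rng.permutation(len(y_tr))
        losses = []
        for start in range(0, len(y_tr), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            Xb = X_tr[idx]
            if aug_scale is not None:
                # common-mode (whole-window) plus per-position level offsets
                common = shuffle_rng.normal(size=(len(idx), 1, 1))
                per_pos = shuffle_rng.normal(size=(len(idx), Xb.shape[1], 1))
                offsets = common + 0.5 * per_pos
                Xb = Xb.copy()
                Xb[:, :, :2] += offsets * aug_scale
            loss, grads = net.loss_and_grads(Xb, y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"motif {dataset.motif}: non-finite loss at epoch {epoch}"
                )
            opt.step(net.params, grads, lr)
            losses.append(loss)
        val_pred = net.forward(X_val)[:, 1] >= 0.5
        val_acc = float(np.mean(val_pred == y_val))
        val_accs.append(val_acc)
        history.epochs.append(
            {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses)),
             "val_accuracy": val_acc}
        )
        if val_acc > history.best_val_accuracy:
            history.best_val_accuracy = val_acc
            history.best_epoch = epoch
            best_params = net.get_params()
        if should_stop(val_accs, cfg.patience):
            break
    history.epochs_run = len(history.epochs)
    net.set_params(best_params)
    return FittedSubmodel(
        motif=dataset.motif,
        net=net,
        scaler_mean=scaler_mean,
        scaler_sd=scaler_sd,
        history=history,
        n_train=len(y_tr),
        n_val=len(y_val),
        n_test=dataset.n_test,
        log_dwell=cfg.log_dwell,
    )


def _motif_seed(motif: str) -> int:
    """Stable small integer per motif (base-4 encoding of the 5-mer)."""
    return sum("ACGT".index(b) * 4**i for i, b in enumerate(motif))


class ModificationEnsemble:
    """The 12-sub-model classifier ensemble, before fitting.

    Parameters
    ----------
    datasets
        Mapping motif -> :class:`~m6acall.training.MotifDataset`.  Motifs
        flagged untrainable (single-class) are skipped and recorded.
    config
        Shared :class:`ModelConfig`.
    """

    def __init__(
        self,
        datasets: Mapping[str, MotifDataset],
        config: ModelConfig | None = None,
    ) -> None:
        self.datasets = dict(datasets)
        self.config = config or ModelConfig()

    @classmethod
    def from_labeled_events(
        cls,
        labeled: pd.DataFrame,
        config: ModelConfig | None = None,
        ratio: float = 0.7,
        split_seed: int = 0,
    ) -> "ModificationEnsemble":
        """Build directly from a labeled-event table (see training module)."""
        from .training import build_datasets

        return cls(build_datasets(labeled, ratio=ratio, seed=split_seed), config)

    def fit(self, verbose: bool = False) -> "EnsembleResults":
        """Train every trainable sub-model; returns the results object."""
        fitted: dict[str, FittedSubmodel] = {}
        skipped: list[str] = []
        for motif in sorted(self.datasets):
            ds = self.datasets[motif]
            if not ds.trainable:
                skipped.append(motif)
                continue
            sub = train_submodel(ds, self.config)
            if verbose:
                h = sub.history
                print(
                    f"{motif}: {h.epochs_run} epochs, best val acc "
                    f"{h.best_val_accuracy:.4f} (epoch {h.best_epoch})"
                )
            fitted[motif] = sub
        return EnsembleResults(
            submodels=fitted,
            config=self.config,
            untrainable_motifs=tuple(skipped),
            datasets=self.datasets,
        )


class EnsembleResults:
    """A fitted ensemble: per-motif parameters, scalers and histories.

    Prediction refuses motifs absent from the ensemble — events with an
    unknown motif are skipped and tallied, never given a fabricated
    probability.
    """

    def __init__(
        self,
        submodels: dict[str, FittedSubmodel],
        config: ModelConfig,
        untrainable_motifs: tuple[str, ...] = (),
        datasets: Mapping[str, MotifDataset] | None = None,
    ) -> None:
        self.submodels = submodels
        self.config = config
        self.untrainable_motifs = untrainable_motifs
        self.datasets = dict(datasets) if datasets else None

    @property
    def motifs(self) -> tuple[str, ...]:
        return tuple(sorted(self.submodels))

    def predict_proba(
        self, X: np.ndarray, motifs: Sequence[str]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-event modification probabilities, routed by motif.

        Returns (probabilities, skipped_mask); skipped events (motif not
        in the ensemble) carry NaN.  Batch order does not affect values.
        """
        X = np.asarray(X, dtype=float)
        motifs = np.asarray(motifs)
        probs = np.full(len(motifs), np.nan)
        skipped = np.ones(len(motifs), dtype=bool)
        for motif in np.unique(motifs):
            sub = self.submodels.get(str(motif))
            if sub is None:
                continue
            sel = motifs == motif
            probs[sel] = sub.predict_proba(X[sel])
            skipped[sel] = False
        return probs, skipped

    def predict_events(self, labeled: pd.DataFrame) -> pd.DataFrame:
        """Predict a labeled/extracted event table (25 feature columns).

        Adds a ``probability`` column; unknown-motif rows are dropped into
        the tally accessible via the returned frame's ``attrs['skipped']``.
        """
        from .training import FEATURE_NAMES, _feature_columns

        window = self.config_window()
        X = labeled[_feature_columns(window)].to_numpy(dtype=float)
        X = X.reshape(-1, window, len(FEATURE_NAMES))
        probs, skipped = self.predict_proba(X, labeled["motif"].to_numpy())
        out = labeled[["transcript_id", "position", "motif", "read_id"]].copy()
        out["probability"] = probs
        out = out[~skipped].reset_index(drop=True)
        out.attrs["skipped"] = int(skipped.sum())
        return out

    def config_window(self) -> int:
        if self.submodels:
            return next(iter(self.submodels.values())).net.n_steps
        return 5

    def evaluate(self) -> pd.DataFrame:
        """Held-out metrics per motif (needs the original datasets).

        Returns a motif x {n_test, accuracy, recall, precision, f1, auc}
        table computed on each motif's testing partition.
        """
        from .metrics import ConfusionCounts, classification_metrics, roc_auc

        if self.datasets is None:
            raise ValueError("evaluate() requires the training datasets")
        rows = []
        for motif in self.motifs:
            ds = self.datasets[motif]
            sub = self.submodels[motif]
            p = sub.predict_proba(ds.X_test)
            pred = (p >= 0.5).astype(int)
            y = ds.y_test
            cc = ConfusionCounts(
                tp=int(((pred == 1) & (y == 1)).sum()),
                fp=int(((pred == 1) & (y == 0)).sum()),
                tn=int(((pred == 0) & (y == 0)).sum()),
                fn=int(((pred == 0) & (y == 1)).sum()),
            )
            m = classification_metrics(cc)
            _, auc = roc_auc(p, y)
            rows.append(
                {"motif": motif, "n_test": len(y), "accuracy": m.accuracy,
                 "recall": m.recall, "precision": m.precision, "f1": m.f1,
                 "auc": auc}
            )
        return pd.DataFrame(rows).set_index("motif")

    def summary(self) -> str:
        """Human-readable fit summary (one row per motif)."""
        lines = [
            "Modification classifier ensemble",
            "=" * 64,
            f"motifs fitted: {len(self.submodels)}   "
            f"untrainable: {len(self.untrainable_motifs)}",
            f"config: hidden={self.config.hidden_size}x{self.config.n_hidden_layers} "
            f"(bidirectional), fc={self.config.fc_sizes}, lr={self.config.learning_rate}, "
            f"gamma={self.config.lr_gamma}/epoch, patience={self.config.patience}",
            "-" * 64,
            f"{'motif':8s}{'n_train':>9s}{'n_val':>7s}{'epochs':>8s}"
            f"{'best_ep':>9s}{'val_acc':>9s}",
        ]
        for motif in self.motifs:
            sub = self.submodels[motif]
            h = sub.history
            lines.append(
                f"{motif:8s}{sub.n_train:9d}{sub.n_val:7d}{h.epochs_run:8d}"
                f"{h.best_epoch:9d}{h.best_val_accuracy:9.4f}"
            )
        return "\n".join(lines)

    # -- serialisation --------------------------------------------------------

    def save(self, directory: str | os.PathLike) -> None:
        """One .npz per motif plus a JSON manifest (config, histories)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "config": asdict(self.config),
            "motifs": list(self.motifs),
            "untrainable_motifs": list(self.untrainable_motifs),
            "histories": {},
        }
        for motif, sub in self.submodels.items():
            arrays = {f"param_{k}": v for k, v in sub.net.params.items()}
            arrays["scaler_mean"] = sub.scaler_mean
            arrays["scaler_sd"] = sub.scaler_sd
            arrays["meta"] = np.array(
                [sub.n_train, sub.n_val, sub.n_test,
                 sub.net.hidden_size, sub.net.n_layers, sub.net.n_steps,
                 sub.net.n_features, *sub.net.fc_sizes, int(sub.log_dwell)]
            )
            np.savez(directory / f"{motif}.npz", **arrays)
            manifest["histories"][motif] = {
                "epochs": sub.history.epochs,
                "best_epoch": sub.history.best_epoch,
                "best_val_accuracy": sub.history.best_val_accuracy,
                "epochs_run": sub.history.epochs_run,
            }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "EnsembleResults":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        raw_cfg = manifest["config"]
        raw_cfg["fc_sizes"] = tuple(raw_cfg["fc_sizes"])
        config = ModelConfig(**raw_cfg)
        submodels = {}
        for motif in manifest["motifs"]:
            data = np.load(directory / f"{motif}.npz")
            meta = data["meta"].astype(int)
            net = BiLSTMNet(
                n_features=int(meta[6]), n_steps=int(meta[5]),
                hidden_size=int(meta[3]), n_layers=int(meta[4]),
                fc_sizes=(int(meta[7]), int(meta[8])), seed=0,
            )
            net.set_params(
                {k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")}
            )
            h = manifest["histories"][motif]
            history = TrainingHistory(
                epochs=h["epochs"], best_epoch=h["best_epoch"],
                best_val_accuracy=h["best_val_accuracy"], epochs_run=h["epochs_run"],
            )
            submodels[motif] = FittedSubmodel(
                motif=motif, net=net,
                scaler_mean=data["scaler_mean"], scaler_sd=data["scaler_sd"],
                history=history,
                n_train=int(meta[0]), n_val=int(meta[1]), n_test=int(meta[2]),
                log_dwell=bool(meta[9]),
            )
        return cls(
            submodels=submodels,
            config=config,
            untrainable_motifs=tuple(manifest["untrainable_motifs"]),
        )
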