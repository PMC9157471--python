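"""Four-layer bidirectional LSTM window classifier, implemented in numpy.

The architecture is, in order: an embedding layer over the four nucleotide
tokens (integer codes 1–4; row 0 of the table is a reserved padding index),
a dropout layer on the embedded sequence, a bidirectional LSTM whose two
final hidden states are concatenated, and a dense 3-way softmax head.
Training minimises categorical cross-entropy with the Adam optimiser and
records per-epoch loss/accuracy for both the training set and the held-out
set. Everything — initialisation, shuffling, dropout — is driven by a
single integer seed, so a run is exactly reproducible.

The LSTM uses the standard gate equations (input i, forget f, output o,
cell candidate g; the fused weight matrices order the blocks i|f|o|g so
one sigmoid covers the first three and one tanh the last):

    z_t = x_t Wx + h_{t-1} Wh + b
    c_t = sigmoid(z_f) * c_{t-1} + sigmoid(z_i) * tanh(z_g)
    h_t = sigmoid(z_o) * tanh(c_t)

Gradients are hand-derived backpropagation-through-time; correctness is
pinned by a finite-difference check in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .dataset_builder import DatasetSplit

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier.

    ``epochs_per_round × rounds`` gives the total number of training epochs
    (default 10 × 5 = 50). ``recurrent_units`` is per direction.
    """

    window_length: int = 60
    vocab_size: int = 4
    embedding_dim: int = 8
    recurrent_units: int = 60
    dropout_rate: float = 0.2
    n_classes: int = 3
    epochs_per_round: int = 10
    rounds: int = 5
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    early_stopping_patience: Optional[int] = None
    restore_best_weights: bool = True
    dtype: str = "float32"

    @property
    def total_epochs(self) -> int:
        return self.epochs_per_round * self.rounds

    def validate(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be ≥ 2")
        if self.vocab_size != 4:
            raise ValueError("vocab_size must be 4 (nucleotide tokens)")
        if self.embedding_dim < 1 or self.recurrent_units < 1:
            raise ValueError("embedding_dim and recurrent_units must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes != 3:
            raise ValueError("n_classes must be 3 (donor/acceptor/no-site)")
        if self.epochs_per_round < 1 or self.rounds < 1:
            raise ValueError("epochs_per_round and rounds must be ≥ 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be ≥ 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")


@dataclass
class TrainingHistory:
    """Per-epoch series mirroring the usual loss/accuracy training curves."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)

    def append(self, tl: float, ta: float, vl: float, va: float) -> None:
        self.train_loss.append(float(tl))
        self.train_accuracy.append(float(ta))
        self.test_loss.append(float(vl))
        self.test_accuracy.append(float(va))

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self) + 1),
                "train_loss": self.train_loss,
                "train_acc": self.train_accuracy,
                "test_loss": self.test_loss,
                "test_acc": self.test_accuracy,
            }
        )

    def plot(self, path=None):
        """Loss and accuracy curves for train and held-out series."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax_loss, ax_acc) = plt.subplots(1, 2, figsize=(9, 3.5))
        epochs = np.arange(1, len(self) + 1)
        ax_loss.plot(epochs, self.train_loss, label="train")
        ax_loss.plot(epochs, self.test_loss, label="test")
        ax_loss.set_xlabel("epoch"); ax_loss.set_ylabel("loss"); ax_loss.legend()
        ax_acc.plot(epochs, self.train_accuracy, label="train")
        ax_acc.plot(epochs, self.test_accuracy, label="test")
        ax_acc.set_xlabel("epoch"); ax_acc.set_ylabel("accuracy"); ax_acc.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # stable everywhere: sigmoid(x) = (tanh(x/2) + 1) / 2
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class TrainedSpliceModel:
    """The classifier: parameters, config and (after training) history."""

    #: parameter names; LSTM weights are stacked over the two directions
    #: (axis 0: forward, backward) with fused gate blocks ordered i|f|o|g
    PARAM_NAMES = ("E", "Wx", "Wh", "b", "Wd", "bd")

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        self.history = TrainingHistory()
        self.trained = False
        dt = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        d, H, C = config.embedding_dim, config.recurrent_units, config.n_classes
        V = config.vocab_size + 1  # +1 reserved padding row at index 0

        def glorot(*shape):
            lim = np.sqrt(6.0 / (shape[-2] + shape[-1]))
            return rng.uniform(-lim, lim, size=shape).astype(dt)

        bias = np.zeros((2, 4 * H), dtype=dt)
        bias[:, H : 2 * H] = 1.0  # forget-gate bias init
        self.params: dict[str, np.ndarray] = {
            "E": rng.uniform(-0.05, 0.05, (V, d)).astype(dt),
            "Wx": glorot(2, d, 4 * H),
            "Wh": glorot(2, H, 4 * H),
            "b": bias,
            "Wd": glorot(2 * H, C),
            "bd": np.zeros(C, dtype=dt),
        }

    # ---- bookkeeping -----------------------------------------------------

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    @staticmethod
    def expected_parameter_count(config: ModelConfig) -> int:
        """Closed-form count: embedding (V+1)·d, two LSTM directions of
        4H·(d + H + 1) each, dense 2H·C + C."""
        d, H, C = config.embedding_dim, config.recurrent_units, config.n_classes
        return (config.vocab_size + 1) * d + 2 * (4 * H * (d + H + 1)) + (2 * H * C + C)

    # ---- forward / backward ----------------------------------------------

    def _validate_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.config.window_length:
            raise ValueError(
                f"expected (n, {self.config.window_length}) integer batch, "
                f"got shape {X.shape}"
            )
        if X.min() < 1 or X.max() > self.config.vocab_size:
            raise ValueError("encoded values must lie in 1..4")
        return X.astype(np.int64)

    def _lstm(self, Xe: np.ndarray):
        """Run forward and backward directions in one stacked loop.

        ``Xs[0]`` is the embedded sequence, ``Xs[1]`` the time-reversed
        copy; both are stepped t = 0..T-1 against their own weight slice,
        so the two final hidden states summarise the window read from the
        left and from the right.
        """
        B, T, d = Xe.shape
        H = self.config.recurrent_units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        dt = Xe.dtype
        Xs = np.stack([Xe, Xe[:, ::-1, :]])  # (2, B, T, d)
        Xp = (Xs.reshape(2, B * T, d) @ Wx).reshape(2, B, T, 4 * H)
        Xp += b[:, None, None, :]
        hs = np.zeros((T + 1, 2, B, H), dtype=dt)
        cs = np.zeros((T + 1, 2, B, H), dtype=dt)
        gates = np.empty((T, 2, B, 4 * H), dtype=dt)
        for t in range(T):
            z = Xp[:, :, t, :] + hs[t] @ Wh  # (2, B, 4H)
            z[..., : 3 * H] = _sigmoid(z[..., : 3 * H])  # i | f | o
            z[..., 3 * H :] = np.tanh(z[..., 3 * H :])  # g
            i, f = z[..., :H], z[..., H : 2 * H]
            o, g = z[..., 2 * H : 3 * H], z[..., 3 * H :]
            cs[t + 1] = f * cs[t] + i * g
            hs[t + 1] = o * np.tanh(cs[t + 1])
            gates[t] = z
        hcat = np.concatenate([hs[T, 0], hs[T, 1]], axis=1)  # (B, 2H)
        return hcat, (Xs, hs, cs, gates)

    def _lstm_backward(self, dh_last: np.ndarray, cache):
        """BPTT through both directions; ``dh_last`` has shape (2, B, H)."""
        Xs, hs, cs, gates = cache
        _, B, T, d = Xs.shape
        H = self.config.recurrent_units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dt = Xs.dtype
        WhT = np.ascontiguousarray(Wh.transpose(0, 2, 1))
        dzs = np.empty((T, 2, B, 4 * H), dtype=dt)
        dh = dh_last.astype(dt)
        dc = np.zeros((2, B, H), dtype=dt)
        for t in range(T - 1, -1, -1):
            z = gates[t]
            i, f = z[..., :H], z[..., H : 2 * H]
            o, g = z[..., 2 * H : 3 * H], z[..., 3 * H :]
            tc = np.tanh(cs[t + 1])
            dc = dc + dh * o * (1.0 - tc * tc)
            dz = dzs[t]
            dz[..., :H] = dc * g * i * (1 - i)
            dz[..., H : 2 * H] = dc * cs[t] * f * (1 - f)
            dz[..., 2 * H : 3 * H] = dh * tc * o * (1 - o)
            dz[..., 3 * H :] = dc * i * (1 - g * g)
            dc = dc * f
            dh = dz @ WhT
        grads = {
            "Wh": np.einsum("tpbh,tpbk->phk", hs[:-1], dzs, optimize=True),
            "b": dzs.sum(axis=(0, 2)),
            "Wx": np.einsum("pbtd,tpbk->pdk", Xs, dzs, optimize=True),
        }
        dXs = np.einsum("tpbk,pdk->pbtd", dzs, Wx, optimize=True)
        dXe = dXs[0] + dXs[1][:, ::-1, :]
        return dXe, grads

    def _forward(self, X: np.ndarray, train: bool = False, rng=None):
        cfg = self.config
        dt = np.dtype(cfg.dtype)
        Xe = self.params["E"][X]  # (B, T, d)
        mask = None
        if train and cfg.dropout_rate > 0:
            keep = 1.0 - cfg.dropout_rate
            mask = (rng.random(Xe.shape) < keep).astype(dt) / dt.type(keep)
            Xe = Xe * mask
        hcat, lstm_cache = self._lstm(Xe)
        logits = hcat @ self.params["Wd"] + self.params["bd"]
        probs = _softmax(logits.astype(np.float64))
        cache = (X, mask, lstm_cache, hcat)
        return probs, cache

    def _backward(self, probs: np.ndarray, Y: np.ndarray, cache):
        X, mask, lstm_cache, hcat = cache
        cfg = self.config
        dt = np.dtype(cfg.dtype)
        B = X.shape[0]
        H = cfg.recurrent_units
        dlogits = ((probs - Y) / B).astype(dt)
        grads = {
            "Wd": hcat.T @ dlogits,
            "bd": dlogits.sum(axis=0),
        }
        dhcat = dlogits @ self.params["Wd"].T
        dh_last = np.stack([dhcat[:, :H], dhcat[:, H:]])
        dXe, lstm_grads = self._lstm_backward(dh_last, lstm_cache)
        grads.update(lstm_grads)
        if mask is not None:
            dXe = dXe * mask
        dE = np.zeros_like(self.params["E"])
        np.add.at(dE, X.reshape(-1), dXe.reshape(-1, cfg.embedding_dim))
        grads["E"] = dE
        return grads

    # ---- public API ------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-probability matrix (n × 3); rows sum to 1."""
        X = self._validate_input(X)
        probs, _ = self._forward(X, train=False)
        return probs

    def predict_labels(self, X: np.ndarray, tie_to_no_site: bool = True) -> np.ndarray:
        """Argmax labels; exact probability ties resolve to no-site (2)."""
        probs = self.predict_proba(X)
        labels = probs.argmax(axis=1)
        if tie_to_no_site:
            ties = probs[np.arange(len(probs)), labels] == probs[:, 2]
            labels[ties] = 2
        return labels


def build_model(config: ModelConfig | None = None) -> TrainedSpliceModel:
    """Instantiate the (untrained) four-layer classifier."""
    return TrainedSpliceModel(config if config is not None else ModelConfig())


def _check_one_hot(Y: np.ndarray, n_classes: int) -> None:
    Y = np.asarray(Y)
    if Y.ndim != 2 or Y.shape[1] != n_classes:
        raise ValueError(f"labels must be one-hot with {n_classes} columns")
    if not (np.isin(Y, (0.0, 1.0)).all() and (Y.sum(axis=1) == 1).all()):
        raise ValueError("label matrix is not one-hot")


def evaluate(
    model: TrainedSpliceModel, test_X: np.ndarray, test_Y: np.ndarray,
    batch_size: int = 512,
) -> tuple[float, float]:
    """Mean categorical cross-entropy and argmax accuracy on a labelled set."""
    _check_one_hot(test_Y, model.config.n_classes)
    test_X = model._validate_input(test_X)
    if len(test_X) != len(test_Y):
        raise ValueError("X and Y row counts differ")
    losses, correct = [], 0
    for start in range(0, len(test_X), batch_size):
        xb = test_X[start : start + batch_size]
        yb = test_Y[start : start + batch_size]
        probs, _ = model._forward(xb, train=False)
        eps = 1e-12
        losses.append(-np.sum(yb * np.log(probs + eps)))
        correct += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())
    return float(np.sum(losses) / len(test_X)), correct / len(test_X)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-7
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.beta2**self.t) / (1 - self.beta1**self.t)
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= (lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)).astype(
                params[k].dtype
            )


def compile_and_train(
    model: TrainedSpliceModel,
    split: DatasetSplit,
    config: ModelConfig | None = None,
) -> TrainedSpliceModel:
    """Train with categorical cross-entropy, Adam and an accuracy metric.

    Runs ``rounds × epochs_per_round`` epochs, evaluating the held-out set
    after every epoch to populate the history's test series. The reported
    per-epoch training loss/accuracy are running averages over minibatches,
    as training frameworks conventionally report them. With
    ``early_stopping_patience`` set, training stops once held-out accuracy
    has not improved for that many consecutive epochs.
    """
    cfg = config if config is not None else model.config
    cfg.validate()
    _check_one_hot(split.train_Y, cfg.n_classes)
    _check_one_hot(split.test_Y, cfg.n_classes)
    train_X = model._validate_input(split.train_X)
    train_Y = np.asarray(split.train_Y, dtype=np.float64)
    if train_X.shape[0] != train_Y.shape[0]:
        raise ValueError("train X and Y row counts differ")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5E]))
    optimizer = _Adam(model.params, cfg.learning_rate)
    n = len(train_X)
    best_acc, stale = -1.0, 0
    best_params = None
    for epoch in range(cfg.total_epochs):
        perm = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = train_X[idx], train_Y[idx]
            probs, cache = model._forward(xb, train=True, rng=rng)
            eps = 1e-12
            batch_loss = -np.sum(yb * np.log(probs + eps))
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, batch offset {start}; "
                    "consider lowering the learning rate"
                )
            epoch_loss += batch_loss
            epoch_correct += int((probs.argmax(1) == yb.argmax(1)).sum())
            grads = model._backward(probs, yb, cache)
            optimizer.step(model.params, grads)
        train_loss = epoch_loss / n
        train_acc = epoch_correct / n
        test_loss, test_acc = evaluate(model, split.test_X, split.test_Y)
        model.history.append(train_loss, train_acc, test_loss, test_acc)
        logger.info(
            "epoch %d/%d loss=%.4f acc=%.4f test_loss=%.4f test_acc=%.4f",
            epoch + 1, cfg.total_epochs, train_loss, train_acc, test_loss, test_acc,
        )
        if cfg.early_stopping_patience is not None:
            if test_acc > best_acc + 1e-4:
                best_acc, stale = test_acc, 0
                if cfg.restore_best_weights:
                    best_params = {k: v.copy() for k, v in model.params.items()}
            else:
                stale += 1
                if stale >= cfg.early_stopping_patience:
                    logger.info("early stop after epoch %d", epoch + 1)
                    break
    if best_params is not None:
        model.params = best_params
    model.trained = True
    return model


def save_model(model: TrainedSpliceModel, path: str | Path) -> Path:
    """Persist weights, config and history to a single ``.npz`` file."""
    path = Path(path)
    meta = {
        "config": asdict(model.config),
        "history": asdict(model.history),
        "trained": model.trained,
    }
    with open(path, "wb") as handle:
        np.savez_compressed(handle, __meta__=json.dumps(meta), **model.params)
    return path


def load_model(path: str | Path) -> TrainedSpliceModel:
    try:
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            params = {k: data[k] for k in TrainedSpliceModel.PARAM_NAMES}
    except Exception as exc:
        raise ValueError(f"cannot load model from {path}: {exc}") from exc
    config = ModelConfig(**meta["config"])
    model = TrainedSpliceModel(config)
    model.params = params
    model.history = TrainingHistory(**meta["history"])
    model.trained = bool(meta["trained"])
    return model
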