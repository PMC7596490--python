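"""The 1D-conv + LSTM ventilatory-threshold window classifier.

Architecture: stacked (1D convolution -> ReLU -> 1D max pooling) blocks
abstract the raw 30-s voltage trace, an LSTM summarizes the reduced
sequence, the demographic covariates (age, sex, exercise time) are
concatenated to the LSTM summary (switchable to pre-LSTM injection), and
dense layers map to a single sigmoid probability that the window lies at
or after VT.  Training minimizes binary cross entropy with RMSprop and
keeps the weights from the epoch with the lowest validation loss.

Layer sizes, learning rate, and batch size are configuration with two
presets: ``paper_scale`` sized for 1000-Hz windows and ``desk_scale`` for
fast 250-Hz runs on one CPU.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .windows import LabeledWindow

__all__ = ["NetworkConfig", "VTNet", "TrainedModel", "build_network", "train",
           "predict_window", "make_dummy_ecg", "save_checkpoint",
           "load_checkpoint"]


@dataclass
class NetworkConfig:
    conv_blocks: tuple[tuple[int, int, int], ...] = ((16, 7, 4), (32, 7, 4),
                                                     (32, 7, 4))
    lstm_units: int = 32
    dense_units: int = 16
    covariate_merge_point: str = "post_lstm"   # or "pre_lstm"
    epochs: int = 60
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    batch_size: int = 64
    seed: int = 0
    input_length: int = 30_000                 # window_s * fs samples
    n_covariates: int = 3
    scale_preset: str = "paper_scale"
    dtype: str = "float32"                     # float64 for gradient checks

    @classmethod
    def paper_scale(cls, **overrides) -> "NetworkConfig":
        """Sized for 30-s windows at the native 1000-Hz sampling rate."""
        return cls(**{**dict(scale_preset="paper_scale"), **overrides})

    @classmethod
    def desk_scale(cls, fs: float = 250.0, **overrides) -> "NetworkConfig":
        """Small preset for single-CPU runs on 250-Hz windows.

        The receptive fields bracket the cardiac scales: one step after the
        first pool is 40 ms at 250 Hz, so the second conv kernel (17 taps)
        spans ~680 ms — a full RR interval, letting filters measure beat
        spacing rather than just detect beats — and the third block spans
        several beats, exposing rhythm modulation to the LSTM.
        """
        defaults = dict(
            conv_blocks=((8, 7, 10), (16, 17, 5), (24, 9, 4)),
            lstm_units=24, dense_units=16,
            input_length=int(round(30.0 * fs)),
            epochs=35, learning_rate=2e-3, weight_decay=1e-4,
            scale_preset="desk_scale",
        )
        return cls(**{**defaults, **overrides})

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        length = self.input_length
        for filters, kernel, pool in self.conv_blocks:
            length = (length - kernel + 1) // pool
            if length < 1:
                raise ValueError("conv/pool stack reduces the sequence below "
                                 "one step; shrink kernels or pools")
        if self.covariate_merge_point not in ("post_lstm", "pre_lstm"):
            raise ValueError("covariate_merge_point must be post_lstm or pre_lstm")


class VTNet:
    """The classifier: voltage sequence + covariates -> probability."""

    def __init__(self, config: NetworkConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.convs: list[tuple[nn.Conv1D, nn.ReLU, nn.MaxPool1D]] = []
        cin = 1
        for j, (filters, kernel, pool) in enumerate(config.conv_blocks):
            self.convs.append((nn.Conv1D(cin, filters, kernel, rng,
                                         compute_dx=(j > 0)),
                               nn.ReLU(), nn.MaxPool1D(pool)))
            cin = filters
        lstm_in = cin
        if config.covariate_merge_point == "pre_lstm":
            lstm_in += config.n_covariates
        self.lstm = nn.LSTM(lstm_in, config.lstm_units, rng)
        head_in = config.lstm_units
        if config.covariate_merge_point == "post_lstm":
            head_in += config.n_covariates
        self.dense1 = nn.Dense(head_in, config.dense_units, rng)
        self.relu1 = nn.ReLU()
        self.dense2 = nn.Dense(config.dense_units, 1, rng)
        dt = np.dtype(config.dtype)
        for layer in self.layers:
            layer.params = {k: v.astype(dt) for k, v in layer.params.items()}

    @property
    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for conv, relu, pool in self.convs:
            out.extend([conv, relu, pool])
        out.extend([self.lstm, self.dense1, self.relu1, self.dense2])
        return out

    def forward(self, X: np.ndarray, C: np.ndarray) -> np.ndarray:
        """Probabilities for a batch: X (B, L) voltage, C (B, 3) covariates."""
        if X.shape[1] != self.config.input_length:
            raise ValueError(f"input length {X.shape[1]} != configured "
                             f"{self.config.input_length}")
        dt = np.dtype(self.config.dtype)
        B = X.shape[0]
        # All-zero voltage (the dummy-ECG ablation) makes the sequence path
        # identical for every window: run it once and broadcast.  The
        # gradient of shared activations is the sum of the per-row upstream
        # gradients, so this is exact, not an approximation.
        self._collapsed = (B > 1 and
                           self.config.covariate_merge_point == "post_lstm"
                           and not np.any(X))
        h = np.asarray(X[:1] if self._collapsed else X, dtype=dt)[:, :, None]
        for conv, relu, pool in self.convs:
            h = pool.forward(relu.forward(conv.forward(h)))
        C = np.asarray(C, dtype=dt)
        if self.config.covariate_merge_point == "pre_lstm":
            h = np.concatenate(
                [h, np.repeat(C[:, None, :], h.shape[1], axis=1)], axis=2)
        s = self.lstm.forward(h)
        if self._collapsed:
            s = np.repeat(s, B, axis=0)
        if self.config.covariate_merge_point == "post_lstm":
            s = np.concatenate([s, C], axis=1)
        self._n_cov = C.shape[1]
        z = self.dense2.forward(self.relu1.forward(self.dense1.forward(s)))
        self._logits = z[:, 0]
        return nn.sigmoid(self._logits)

    def backward(self, p: np.ndarray, y: np.ndarray,
                 sample_weight: np.ndarray | None = None) -> None:
        """Backprop of (optionally weighted) mean BCE; call after ``forward``."""
        B = len(y)
        dz = (p - y) / B
        if sample_weight is not None:
            dz = dz * sample_weight
        dz = dz[:, None]
        ds = self.dense1.backward(self.relu1.backward(self.dense2.backward(dz)))
        if self.config.covariate_merge_point == "post_lstm":
            ds = ds[:, : -self._n_cov]
        if self._collapsed:
            ds = ds.sum(axis=0, keepdims=True)
        dh = self.lstm.backward(ds)
        if self.config.covariate_merge_point == "pre_lstm":
            dh = dh[:, :, : -self._n_cov]
        for conv, relu, pool in reversed(self.convs):
            dh = conv.backward(relu.backward(pool.backward(dh)))

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [copy.deepcopy(layer.params) for layer in self.layers]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, w in zip(self.layers, weights):
            layer.params = copy.deepcopy(w)

    def predict(self, X: np.ndarray, C: np.ndarray,
                batch_size: int = 256) -> np.ndarray:
        """Batched inference (pure function of the inputs and weights)."""
        out = np.empty(len(X))
        for lo in range(0, len(X), batch_size):
            sl = slice(lo, lo + batch_size)
            out[sl] = self.forward(X[sl], C[sl])
        return out


@dataclass
class TrainedModel:
    model: VTNet
    config: NetworkConfig
    best_epoch: int                      # 1-based epoch of lowest val loss
    history: pd.DataFrame                # epoch, train_loss, val_loss

    def predict(self, X: np.ndarray, C: np.ndarray) -> np.ndarray:
        return self.model.predict(X, C)


def build_network(config: NetworkConfig) -> VTNet:
    return VTNet(config)


def train(model: VTNet, derivation: tuple, validation: tuple,
          config: NetworkConfig | None = None,
          class_weighting: bool = False) -> TrainedModel:
    """Train for ``config.epochs`` epochs, returning the best-epoch weights.

    ``derivation`` and ``validation`` are ``(X, C, y)`` triples.  The
    validation loss is snapshotted every epoch and the weights from the
    epoch with the lowest validation loss are restored into the returned
    model.  Optional inverse-frequency class weights counter label
    imbalance.  All randomness (shuffling) derives from ``config.seed``.
    """
    config = config or model.config
    Xd, Cd, yd = derivation
    Xv, Cv, yv = validation
    if len(Xd) == 0 or len(Xv) == 0:
        raise ValueError("derivation and validation sets must be non-empty")
    if len(np.unique(yd)) < 2:
        raise ValueError("derivation labels are single-class; "
                         "binary cross entropy is degenerate")
    w_pos = w_neg = 1.0
    if class_weighting:
        n_pos = float(yd.sum())
        n_neg = float(len(yd) - n_pos)
        w_pos = len(yd) / (2.0 * n_pos)
        w_neg = len(yd) / (2.0 * n_neg)
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.RMSprop(model.layers, learning_rate=config.learning_rate,
                     weight_decay=config.weight_decay)
    history = []
    best_loss, best_epoch, best_weights = np.inf, -1, None
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(Xd))
        train_losses = []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo: lo + config.batch_size]
            p = model.forward(Xd[idx], Cd[idx])
            yb = yd[idx]
            train_losses.append(nn.bce_loss(p, yb))
            weights = np.where(yb == 1, w_pos, w_neg) if class_weighting else None
            model.backward(p, yb, sample_weight=weights)
            opt.step()
        val_p = model.predict(Xv, Cv)
        val_loss = nn.bce_loss(val_p, yv)
        history.append((epoch, float(np.mean(train_losses)), val_loss))
        if val_loss < best_loss:
            best_loss, best_epoch = val_loss, epoch
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    hist = pd.DataFrame(history, columns=["epoch", "train_loss", "val_loss"])
    return TrainedModel(model=model, config=config, best_epoch=best_epoch,
                        history=hist)


def predict_window(trained: TrainedModel, record: dict) -> float:
    """Probability for a single assembled input record."""
    p = trained.model.predict(record["voltage"][None, :],
                              record["covariates"][None, :])
    return float(p[0])


def make_dummy_ecg(windows: list[LabeledWindow]) -> list[LabeledWindow]:
    """Zero every voltage sample, keeping labels and covariates (the
    dummy-ECG ablation that isolates what the covariates alone explain)."""
    return [
        LabeledWindow(session_id=w.session_id, window_index=w.window_index,
                      start_time=w.start_time,
                      voltage=np.zeros_like(w.voltage), label=w.label,
                      age=w.age, sex=w.sex, exercise_time=w.exercise_time)
        for w in windows
    ]


def save_checkpoint(trained: TrainedModel, path: str | Path) -> None:
    """Weights as .npz next to a JSON config sidecar and a CSV training log."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, layer_params in enumerate(trained.model.get_weights()):
        for k, v in layer_params.items():
            arrays[f"{i}:{k}"] = v
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = asdict(trained.config)
    sidecar["best_epoch"] = trained.best_epoch
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    trained.history.to_csv(path.with_suffix(".log.csv"), index=False)


def load_checkpoint(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    best_epoch = sidecar.pop("best_epoch")
    sidecar["conv_blocks"] = tuple(tuple(b) for b in sidecar["conv_blocks"])
    config = NetworkConfig(**sidecar)
    model = VTNet(config)
    data = np.load(path.with_suffix(".npz"))
    weights = model.get_weights()
    for key in data.files:
        i, name = key.split(":")
        weights[int(i)][name] = data[key]
    model.set_weights(weights)
    history = pd.read_csv(path.with_suffix(".log.csv"))
    return TrainedModel(model=model, config=config, best_epoch=best_epoch,
                        history=history)
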