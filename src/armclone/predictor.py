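"""CNN-LSTM decoder: windowed shoulder angles in, elbow angles out.

The network is a single 1-D convolution over a sliding window of the
three shoulder channels (S_rot, S_flex, S_abd), followed by stacked
LSTM layers and a dense head that regresses the two elbow channels
(E_pron, E_flex) at the window's final sample — a causal decoder suited
to online prosthesis control.  Training minimizes mean-squared error
with Adam; inputs and targets are z-normalized per channel with
statistics fitted on the training set only.

Windows never span trial boundaries, and the validation split used for
early stopping is made by whole trials to avoid window-level leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn import LSTM, Adam, Conv1D, Dense, Relu
from .subjects import MotionDataset

__all__ = [
    "WindowConfig",
    "PredictorConfig",
    "TrainedPredictor",
    "make_windows",
    "train_predictor",
    "predict_elbow",
    "predict_dataset",
    "save_predictor",
    "load_predictor",
]

SHOULDER_CH = (0, 1, 2)  # S_rot, S_flex, S_abd
ELBOW_CH = (3, 4)  # E_pron, E_flex


class TrainingFailureError(RuntimeError):
    pass


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window extraction: 1 s windows at 50 Hz by default."""

    window_len: int = 50
    stride: int = 1

    def __post_init__(self):
        if self.window_len < 1 or self.stride < 1:
            raise ValueError("window_len and stride must be >= 1")


@dataclass(frozen=True)
class PredictorConfig:
    """Architecture and optimization settings.

    The default architecture is one 1-D conv layer and two 256-unit
    LSTM layers with a dense output; smaller settings train much faster
    and are adequate for the low-dimensional reaching synergy.
    """

    conv_filters: int = 64
    conv_kernel: int = 3
    lstm_units: int = 256
    lstm_layers: int = 2
    learning_rate: float = 1e-3
    max_epochs: int = 200
    batch_size: int = 64
    patience: int = 15
    val_fraction: float = 0.10
    seed: int = 0

    def scaled(self, **kw) -> "PredictorConfig":
        return replace(self, **kw)


class _ConvLSTMNet:
    """conv1d -> relu -> LSTM x L -> dense(last step)."""

    def __init__(self, cfg: PredictorConfig, n_in: int, n_out: int, rng):
        self.conv = Conv1D(n_in, cfg.conv_filters, cfg.conv_kernel, rng)
        self.relu = Relu()
        self.lstms = []
        c = cfg.conv_filters
        for _ in range(cfg.lstm_layers):
            self.lstms.append(LSTM(c, cfg.lstm_units, rng))
            c = cfg.lstm_units
        self.head = Dense(c, n_out, rng)
        self.layers = [self.conv, self.relu, *self.lstms, self.head]
        self.params = [p for lay in self.layers for p in lay.params]
        self.grads = [g for lay in self.layers for g in lay.grads]

    def zero_grads(self):
        for g in self.grads:
            g[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.relu.forward(self.conv.forward(x))
        for lstm in self.lstms:
            h = lstm.forward(h)
        self._last_t = h.shape[1] - 1
        return self.head.forward(h[:, self._last_t, :])

    def backward(self, dy: np.ndarray):
        dh_last = self.head.backward(dy)
        b = dy.shape[0]
        for i, lstm in enumerate(reversed(self.lstms)):
            if i == 0:
                dh = np.zeros((b, self._last_t + 1, dh_last.shape[-1]))
                dh[:, self._last_t, :] = dh_last
            dh = lstm.backward(dh)
        self.conv.backward(self.relu.backward(dh))


@dataclass
class TrainedPredictor:
    """Fitted decoder: network, normalization state and training history."""

    net: _ConvLSTMNet = field(repr=False)
    config: PredictorConfig
    window: WindowConfig
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    history: dict = field(default_factory=dict, repr=False)


def make_windows(
    dataset: MotionDataset, wc: WindowConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(windows, targets): shoulder windows and the elbow angles at each
    window's final sample.  Windows are per trial and never cross trial
    boundaries; trials shorter than the window are skipped.
    """
    xs, ys = [], []
    skipped = 0
    for tr in dataset.trials:
        n = tr.n_samples
        if n < wc.window_len:
            skipped += 1
            continue
        sh = tr.angles[:, SHOULDER_CH]
        el = tr.angles[:, ELBOW_CH]
        ends = np.arange(wc.window_len - 1, n, wc.stride)
        starts = ends - wc.window_len + 1
        idx = starts[:, None] + np.arange(wc.window_len)[None, :]
        xs.append(sh[idx])
        ys.append(el[ends])
    if skipped:
        import warnings

        warnings.warn(f"skipped {skipped} trial(s) shorter than the window")
    if not xs:
        raise ValueError("no trial is long enough for the window")
    return np.concatenate(xs, axis=0), np.concatenate(ys, axis=0)


def _trial_split(n_trials: int, val_fraction: float, rng) -> np.ndarray:
    """Boolean mask of validation trials (at least one if fraction > 0)."""
    n_val = int(round(n_trials * val_fraction))
    if val_fraction > 0 and n_trials > 1:
        n_val = max(1, n_val)
    mask = np.zeros(n_trials, bool)
    if n_val:
        mask[rng.choice(n_trials, size=n_val, replace=False)] = True
    return mask


def train_predictor(
    train: MotionDataset,
    cfg: PredictorConfig = PredictorConfig(),
    wc: WindowConfig = WindowConfig(),
) -> TrainedPredictor:
    """Fit the decoder on a motion dataset by windowed MSE regression.

    Early stopping monitors MSE on a validation split made of whole
    held-out trials (``val_fraction``); with a single training trial the
    training loss is monitored instead.  Deterministic for a fixed
    config seed in single-threaded execution.
    """
    if not train.trials:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    n_trials = len(train.trials)
    val_mask = _trial_split(n_trials, cfg.val_fraction, rng)
    if val_mask.all():
        val_mask[:] = False
    tr_ds = MotionDataset(
        [t for t, v in zip(train.trials, val_mask) if not v],
        provenance=train.provenance,
        grid=train.grid,
        timing=train.timing,
    )
    x_tr, y_tr = make_windows(tr_ds, wc)
    if val_mask.any():
        va_ds = MotionDataset(
            [t for t, v in zip(train.trials, val_mask) if v],
            provenance=train.provenance,
            grid=train.grid,
            timing=train.timing,
        )
        x_va, y_va = make_windows(va_ds, wc)
    else:
        x_va = y_va = None

    x_mean = x_tr.mean(axis=(0, 1))
    x_scale = x_tr.std(axis=(0, 1))
    x_scale[x_scale < 1e-8] = 1.0
    y_mean = y_tr.mean(axis=0)
    y_scale = y_tr.std(axis=0)
    y_scale[y_scale < 1e-8] = 1.0

    xn = (x_tr - x_mean) / x_scale
    yn = (y_tr - y_mean) / y_scale

    net = _ConvLSTMNet(cfg, n_in=3, n_out=2, rng=rng)
    opt = Adam(net.params, lr=cfg.learning_rate)

    def eval_mse(x, y):
        out = []
        for k in range(0, len(x), 512):
            out.append(net.forward((x[k : k + 512] - x_mean) / x_scale))
        pred = np.concatenate(out) * y_scale + y_mean
        return float(np.mean((pred - y) ** 2))

    history = {"train_mse": [], "val_mse": []}
    best = np.inf
    best_params = [p.copy() for p in net.params]
    bad_epochs = 0
    n = len(xn)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for k in range(0, n, cfg.batch_size):
            sl = order[k : k + cfg.batch_size]
            xb, yb = xn[sl], yn[sl]
            net.zero_grads()
            pred = net.forward(xb)
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingFailureError(f"non-finite loss in epoch {epoch}")
            net.backward(2.0 * err / err.size)
            opt.step(net.grads)
            ep_loss += loss * len(sl)
        history["train_mse"].append(ep_loss / n)
        monitor = eval_mse(x_va, y_va) if x_va is not None else history["train_mse"][-1]
        history["val_mse"].append(monitor)
        if monitor < best - 1e-12:
            best = monitor
            best_params = [p.copy() for p in net.params]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.patience:
                break
    for p, bp in zip(net.params, best_params):
        p[...] = bp

    return TrainedPredictor(
        net=net,
        config=cfg,
        window=wc,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        history=history,
    )


def predict_elbow(model: TrainedPredictor, shoulder_series: np.ndarray) -> np.ndarray:
    """Per-sample elbow predictions for a (n, 3) shoulder series.

    One prediction per sample from index window_len - 1 onward; earlier
    samples are edge-padded with the first prediction so the output
    length equals the input length.  Inference is deterministic.
    """
    x = np.asarray(shoulder_series, float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("shoulder_series must have shape (n, 3)")
    w = model.window.window_len
    n = len(x)
    if n < w:
        raise ValueError(f"series length {n} shorter than window {w}")
    starts = np.arange(0, n - w + 1)
    idx = starts[:, None] + np.arange(w)[None, :]
    wins = (x[idx] - model.x_mean) / model.x_scale
    preds = []
    for k in range(0, len(wins), 512):
        preds.append(model.net.forward(wins[k : k + 512]))
    pred = np.concatenate(preds) * model.y_scale + model.y_mean
    return np.concatenate([np.tile(pred[0], (w - 1, 1)), pred], axis=0)


def save_predictor(model: TrainedPredictor, out_dir) -> None:
    """Persist weights (npz) plus a JSON sidecar with config and norms."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p for i, p in enumerate(model.net.params)}
    np.savez(out / "weights.npz", **arrays)
    meta = {
        "config": model.config.__dict__,
        "window": model.window.__dict__,
        "x_mean": model.x_mean.tolist(),
        "x_scale": model.x_scale.tolist(),
        "y_mean": model.y_mean.tolist(),
        "y_scale": model.y_scale.tolist(),
        "history": model.history,
    }
    (out / "predictor.json").write_text(json.dumps(meta, indent=1))


def load_predictor(model_dir) -> TrainedPredictor:
    import json
    from pathlib import Path

    src = Path(model_dir)
    meta = json.loads((src / "predictor.json").read_text())
    cfg = PredictorConfig(**meta["config"])
    wc = WindowConfig(**meta["window"])
    net = _ConvLSTMNet(cfg, n_in=3, n_out=2, rng=np.random.default_rng(0))
    with np.load(src / "weights.npz") as arrays:
        for i, p in enumerate(net.params):
            p[...] = arrays[f"p{i}"]
    return TrainedPredictor(
        net=net,
        config=cfg,
        window=wc,
        x_mean=np.asarray(meta["x_mean"]),
        x_scale=np.asarray(meta["x_scale"]),
        y_mean=np.asarray(meta["y_mean"]),
        y_scale=np.asarray(meta["y_scale"]),
        history=meta["history"],
    )


def predict_dataset(model: TrainedPredictor, dataset: MotionDataset) -> MotionDataset:
    """Replace each trial's elbow channels with the model's predictions."""
    from dataclasses import replace as dc_replace

    out = []
    for tr in dataset.trials:
        angles = tr.angles.copy()
        angles[:, list(ELBOW_CH)] = predict_elbow(model, tr.angles[:, SHOULDER_CH])
        out.append(dc_replace(tr, angles=angles))
    return MotionDataset(
        trials=out, provenance="predicted", grid=dataset.grid, timing=dataset.timing
    )
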