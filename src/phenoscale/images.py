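"""Image-based leaf-area estimation.

Top-view frames taken every 10 minutes inside a daylight window are cropped
(fixed horizontal/vertical margins), resized to the model-input resolution
of 128 x 128, scaled to [0, 1], and regressed against the day's leaf-area
label with a small 2-D convolutional network (MAE objective, Adam, batch
normalisation). All frames of a date share one label; at test time the
per-frame predictions of a date are averaged and the daily means are scored
against the label curve with R^2 and RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from . import nn
from .errors import EvaluationError, ParameterError
from .metrics import compute_metrics
from .types import CanopyImage, LabelTable

DEFAULT_WINDOW = (time(8, 0), time(16, 0))
DEFAULT_MARGINS = (80, 300)
INPUT_SIZE = 128


@dataclass
class ImageTensor:
    """Preprocessed model input: 128x128x3 floats in [0, 1]."""

    pixels: np.ndarray
    dat: int
    timestamp: datetime


def select_time_window(
    manifest: pd.DataFrame, window: Tuple[time, time] = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Rows of ``manifest`` whose clock time lies in the closed window
    (default 08:00-16:00, both endpoints included)."""
    ts = pd.to_datetime(manifest["timestamp"])
    clock = ts.dt.time
    keep = (clock >= window[0]) & (clock <= window[1])
    out = manifest.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        import logging

        logging.getLogger(__name__).warning("time window selected no images")
    return out


def preprocess_image(
    image: CanopyImage,
    margins: Tuple[int, int] = DEFAULT_MARGINS,
    out_size: int = INPUT_SIZE,
) -> ImageTensor:
    """Symmetric margin crop, bilinear resize to ``out_size`` square,
    channel scaling to [0, 1]."""
    px = image.pixels
    h, w = px.shape[:2]
    mx, my = margins
    if w <= 2 * mx or h <= 2 * my:
        raise ParameterError(
            f"image {w}x{h} too small for margins {margins} (nothing left to crop)"
        )
    cropped = px[my : h - my, mx : w - mx]
    if cropped.shape[0] != out_size or cropped.shape[1] != out_size:
        resized = np.asarray(
            Image.fromarray(cropped).resize((out_size, out_size), Image.BILINEAR)
        )
    else:
        resized = cropped
    return ImageTensor(
        pixels=resized.astype(np.float64) / 255.0,
        dat=image.dat,
        timestamp=image.timestamp,
    )


def augment(
    tensor: ImageTensor,
    seed: int,
    max_shift: float = 0.10,
    max_rotation: float = 15.0,
    flip_h: Optional[bool] = None,
    flip_v: Optional[bool] = None,
    shift: Optional[Tuple[float, float]] = None,
    angle: Optional[float] = None,
) -> ImageTensor:
    """Flip / shift / rotate augmentation; the label (the tensor's DAT)
    never changes.

    Unset choices are sampled from ``seed``: each flip with probability
    1/2, translation uniform within +-``max_shift`` of the side length,
    rotation uniform within +-``max_rotation`` degrees. Borders fill by
    reflection. Deterministic given (tensor, seed, explicit choices).
    """
    rng = np.random.default_rng(seed)
    fh = bool(rng.integers(2)) if flip_h is None else flip_h
    fv = bool(rng.integers(2)) if flip_v is None else flip_v
    if shift is None:
        side = tensor.pixels.shape[0]
        shift = tuple(rng.uniform(-max_shift, max_shift, size=2) * side)
    if angle is None:
        angle = float(rng.uniform(-max_rotation, max_rotation))
    px = tensor.pixels
    if fh:
        px = px[:, ::-1]
    if fv:
        px = px[::-1, :]
    if shift != (0.0, 0.0):
        px = ndimage.shift(px, (shift[0], shift[1], 0.0), order=1, mode="reflect")
    if angle != 0.0:
        px = ndimage.rotate(
            px, angle, axes=(0, 1), reshape=False, order=1, mode="reflect"
        )
    return ImageTensor(
        pixels=np.clip(px, 0.0, 1.0), dat=tensor.dat, timestamp=tensor.timestamp
    )


@dataclass(frozen=True)
class RegressorSpec:
    """Architecture and training settings of the canopy regressor.

    The loss is mean absolute error and the optimizer Adam by design;
    labels are z-scored internally during training and inverted at
    prediction time.
    """

    conv_filters: Tuple[int, ...] = (16, 32, 64, 64)
    kernel: int = 3
    stride: int = 2
    head_width: int = 64
    lr: float = 2e-3
    batch_size: int = 16
    epochs: int = 80
    augment_prob: float = 0.0
    seed: int = 0


def _build_network(spec: RegressorSpec, rng) -> nn.Sequential:
    layers = []
    c_in = 3
    for c_out in spec.conv_filters:
        layers += [
            nn.Conv2D(c_in, c_out, spec.kernel, spec.stride, rng),
            nn.BatchNorm(c_out),
            nn.ReLU(),
        ]
        c_in = c_out
    layers += [
        nn.GlobalAvgPool(),
        nn.Dense(c_in, spec.head_width, rng),
        nn.ReLU(),
        nn.Dense(spec.head_width, 1, rng),
    ]
    return nn.Sequential(layers)


def split_by_dat(
    dats: Sequence[int], train_fraction: float, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Random train/validation split stratified by DAT so both splits span
    the whole season (default split 7:3)."""
    if not (0.0 < train_fraction < 1.0):
        raise ParameterError("train_fraction must be in (0, 1)")
    dats = np.asarray(dats)
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for d in np.unique(dats):
        idx = np.nonzero(dats == d)[0]
        rng.shuffle(idx)
        n_tr = int(round(train_fraction * len(idx)))
        n_tr = min(max(n_tr, 1), len(idx))
        train_idx.extend(idx[:n_tr])
        val_idx.extend(idx[n_tr:])
    return np.sort(np.array(train_idx, int)), np.sort(np.array(val_idx, int))


class CanopyRegressor:
    """Convolutional regressor from preprocessed frames to daily leaf area.

    Parameters
    ----------
    tensors : sequence of ImageTensor
    labels : LabelTable
        Daily labels; every frame receives its date's label.
    spec : RegressorSpec

    ``fit()`` returns a :class:`CanopyRegressorResults`.
    """

    def __init__(
        self,
        tensors: Sequence[ImageTensor],
        labels: LabelTable,
        spec: RegressorSpec = RegressorSpec(),
    ):
        if len(tensors) == 0:
            raise ParameterError("no tensors")
        self.tensors = list(tensors)
        self.spec = spec
        self.dats = np.array([t.dat for t in tensors], dtype=int)
        if len(np.unique(self.dats)) < 2:
            raise ParameterError("need >= 2 distinct DATs to train")
        self.labels = labels
        self.y = np.array([labels.label_for(int(d)) for d in self.dats])
        self.x = np.stack([t.pixels for t in tensors]).astype(np.float32)

    def fit(self, train_fraction: float = 0.7, seed: Optional[int] = None):
        seed = self.spec.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        net = _build_network(self.spec, rng).astype(np.float32)
        tr, va = split_by_dat(self.dats, train_fraction, seed)
        mu = float(self.y[tr].mean())
        sd = float(self.y[tr].std()) or 1.0
        x_tr = self.x[tr]
        if self.spec.augment_prob > 0:
            arng = np.random.default_rng(seed + 1)
            x_tr = x_tr.copy()
            for i in range(len(x_tr)):
                if arng.random() < self.spec.augment_prob:
                    t = ImageTensor(x_tr[i], 0, datetime(2000, 1, 1))
                    x_tr[i] = augment(t, seed=int(arng.integers(2**31 - 1))).pixels
        history = nn.fit(
            net,
            x_tr,
            ((self.y[tr] - mu) / sd).astype(np.float32),
            self.x[va] if len(va) else None,
            ((self.y[va] - mu) / sd).astype(np.float32) if len(va) else None,
            epochs=self.spec.epochs,
            batch_size=self.spec.batch_size,
            lr=self.spec.lr,
            seed=seed,
        )
        return CanopyRegressorResults(
            model=self, network=net, label_mean=mu, label_sd=sd, history=history,
            train_idx=tr, val_idx=va,
        )


@dataclass
class CanopyRegressorResults:
    """Trained canopy regressor with its training history."""

    model: CanopyRegressor
    network: nn.Sequential
    label_mean: float
    label_sd: float
    history: dict
    train_idx: np.ndarray
    val_idx: np.ndarray

    def predict(self, tensors: Sequence[ImageTensor]) -> np.ndarray:
        """Per-frame leaf-area predictions in cm^2."""
        x = np.stack([t.pixels for t in tensors]).astype(np.float32)
        z = nn.predict_batched(self.network, x, self.model.spec.batch_size)
        return z.ravel() * self.label_sd + self.label_mean

    def predict_daily(self, tensors: Sequence[ImageTensor]) -> pd.DataFrame:
        """Mean/min/max of per-frame predictions per DAT."""
        pred = self.predict(tensors)
        dats = np.array([t.dat for t in tensors], dtype=int)
        df = pd.DataFrame({"dat": dats, "pred": pred})
        g = df.groupby("dat")["pred"]
        out = g.agg(mean="mean", min="min", max="max").reset_index()
        return out.sort_values("dat").reset_index(drop=True)

    def save_weights(self, path):
        """Checkpoint the network (weights, normalisation statistics and
        label scaling) to an ``.npz`` file."""
        state = self.network.get_state()
        state["label_mean"] = np.array(self.label_mean)
        state["label_sd"] = np.array(self.label_sd)
        np.savez(path, **state)

    def load_weights(self, path):
        """Restore a checkpoint written by :meth:`save_weights` into this
        results object's (architecturally identical) network."""
        state = dict(np.load(path))
        self.label_mean = float(state.pop("label_mean"))
        self.label_sd = float(state.pop("label_sd"))
        self.network.set_state(state)

    def summary(self) -> str:
        h = self.history
        lines = [
            "Canopy leaf-area regressor (2-D conv, MAE/Adam)",
            f"  conv filters: {self.model.spec.conv_filters}",
            f"  train/val frames: {len(self.train_idx)}/{len(self.val_idx)}",
            f"  epochs: {len(h['train_mae'])}",
            f"  final train MAE (z): {h['train_mae'][-1]:.4f}",
        ]
        if h["val_mae"]:
            lines.append(f"  final val MAE (z):   {h['val_mae'][-1]:.4f}")
        return "\n".join(lines)


def permuted_labels(labels: LabelTable, seed: int, max_abs_corr: float = 0.05) -> LabelTable:
    """Null-control labels: the label values permuted across DATs.

    A naive random permutation of a monotone label curve retains chance
    correlation with the original (SD ≈ 1/sqrt(n)), which would leak real
    signal into the control; permutations are therefore resampled until the
    Pearson correlation with the originals is below ``max_abs_corr``.
    """
    rng = np.random.default_rng(seed)
    y = labels.leaf_area_label
    yc = y - y.mean()
    denom = float(yc @ yc)
    for _ in range(10_000):
        perm = rng.permutation(len(y))
        if denom == 0 or abs(float(yc @ yc[perm]) / denom) < max_abs_corr:
            return LabelTable(dat=labels.dat, leaf_area_label=y[perm])
    raise ParameterError("could not find a decorrelated permutation")


def evaluate_daily(predictions: pd.DataFrame, labels: LabelTable) -> dict:
    """R^2 and RMSE of daily-mean predictions against the label curve on
    the DATs present in both."""
    lab = pd.Series(labels.leaf_area_label, index=labels.dat)
    common = np.intersect1d(predictions["dat"].to_numpy(), lab.index.to_numpy())
    if len(common) < 2:
        raise EvaluationError("need >= 2 overlapping DATs to evaluate")
    pred = predictions.set_index("dat")["mean"].loc[common].to_numpy()
    m = compute_metrics(pred, lab.loc[common].to_numpy())
    return {"r2": m["r2"], "rmse": m["rmse"], "n": int(len(common))}
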