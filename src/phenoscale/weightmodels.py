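"""Learned daily-weight models and the cross-season bias experiment.

For an impartial comparison with the closed-form calculation, a day's
input is its raw 144-step system-weight sequence and the target is that
day's calculated crop fresh weight. Two model families are provided: a
linear least-squares baseline on the 144-vector and a sequence network
(default: a single-head self-attention encoder over a strided 1-D conv
embedding, with a dense head; a plain 1-D conv stack is available behind
the same interface). Inputs and targets are standardized with
training-season statistics only — precisely the mechanism that cannot
transfer a between-season weight offset, which the cross-season
evaluation demonstrates as mean bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import nn
from .errors import DatasetError, ParameterError, ProtocolError
from .metrics import compute_metrics
from .simulate.sensors import STEPS_PER_DAY, records_to_frame
from .types import DaySequenceSample, FreshWeightSeries, SensorRecord


def build_sequence_dataset(
    records: Sequence[SensorRecord],
    fw: FreshWeightSeries,
    start_dat: int = 1,
) -> List[DaySequenceSample]:
    """One sample per complete day present in both the gap-free stream and
    the fresh-weight series; incomplete or unmatched days are dropped with
    a warning."""
    import logging

    logger = logging.getLogger(__name__)
    df = records_to_frame(records)
    if len(df) == 0 or (df["valid"] == 0).any():
        raise DatasetError("need a non-empty, gap-free stream")
    ts = pd.to_datetime(df["timestamp"])
    df = df.assign(date=ts.dt.date)
    day0 = df["date"].min()
    fw_by_dat = dict(zip(fw.dat.tolist(), fw.crop_fresh_weight.tolist()))
    samples: List[DaySequenceSample] = []
    for date, grp in df.groupby("date"):
        dat = start_dat + (date - day0).days
        if len(grp) != STEPS_PER_DAY:
            logger.warning("day %s dropped: %d of %d records", date, len(grp), STEPS_PER_DAY)
            continue
        if dat not in fw_by_dat:
            logger.warning("day %s (DAT %d) dropped: no fresh-weight target", date, dat)
            continue
        samples.append(
            DaySequenceSample(
                dat=dat,
                weights=grp["weight_kg"].to_numpy(dtype=float),
                target=float(fw_by_dat[dat]),
            )
        )
    if not samples:
        raise DatasetError("no complete days shared by stream and targets")
    return samples


def _xy(samples: Sequence[DaySequenceSample]) -> Tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.weights for s in samples])
    y = np.array([s.target for s in samples])
    return x, y


@dataclass
class _Standardizer:
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def from_data(cls, x):
        sd = x.std(axis=0)
        return cls(mean=x.mean(axis=0), sd=np.where(sd > 0, sd, 1.0))

    def __call__(self, x):
        return (x - self.mean) / self.sd


class LinearDailyWeightModel:
    """Least-squares map from the standardized 144-vector to the target.

    Uses the minimum-norm solution (numpy lstsq); an explicit ridge
    penalty is available for ill-conditioned inputs.
    """

    def __init__(self, samples: Sequence[DaySequenceSample], ridge: float = 0.0):
        if len(samples) < 10:
            raise ParameterError("need >= 10 training samples")
        self.samples = list(samples)
        self.ridge = ridge

    def fit(self, seed: int = 0) -> "DailyWeightResults":
        x, y = _xy(self.samples)
        xs = _Standardizer.from_data(x)
        ys_mu, ys_sd = float(y.mean()), float(y.std()) or 1.0
        xt = xs(x)
        a = np.hstack([xt, np.ones((len(xt), 1))])
        yt = (y - ys_mu) / ys_sd
        if self.ridge > 0:
            g = np.eye(a.shape[1]) * self.ridge
            g[-1, -1] = 0.0
            coef = np.linalg.solve(a.T @ a + g, a.T @ yt)
        else:
            coef, *_ = np.linalg.lstsq(a, yt, rcond=None)
        predict = lambda xq: (np.hstack([xs(xq), np.ones((len(xq), 1))]) @ coef) * ys_sd + ys_mu
        return DailyWeightResults(
            kind="linear", predict_fn=predict, x_std=xs, coef=coef, history=None
        )


@dataclass(frozen=True)
class SequenceModelSpec:
    """Sequence-network settings: ``flavor`` is "attention" (conv embed +
    self-attention encoder + dense head) or "conv" (1-D conv stack)."""

    flavor: str = "attention"
    d_model: int = 16
    kernel: int = 5
    stride: int = 2
    head_width: int = 32
    lr: float = 1e-3
    batch_size: int = 16
    epochs: int = 200
    seed: int = 0


def _build_sequence_net(spec: SequenceModelSpec, rng) -> nn.Sequential:
    layers = [
        nn.Conv1D(1, spec.d_model, spec.kernel, spec.stride, rng),
        nn.BatchNorm(spec.d_model),
        nn.ReLU(),
    ]
    if spec.flavor == "attention":
        t_embed = (STEPS_PER_DAY + spec.stride - 1) // spec.stride
        layers += [
            nn.PositionalEncoding(t_embed, spec.d_model),
            nn.SelfAttention(spec.d_model, rng),
            nn.LayerNorm(spec.d_model),
        ]
    elif spec.flavor == "conv":
        layers += [
            nn.Conv1D(spec.d_model, spec.d_model, spec.kernel, spec.stride, rng),
            nn.BatchNorm(spec.d_model),
            nn.ReLU(),
        ]
    else:
        raise ParameterError(f"unknown sequence-model flavor {spec.flavor!r}")
    layers += [
        nn.GlobalAvgPool(),
        nn.Dense(spec.d_model, spec.head_width, rng),
        nn.ReLU(),
        nn.Dense(spec.head_width, 1, rng),
    ]
    return nn.Sequential(layers)


class SequenceDailyWeightModel:
    """Deep sequence regressor (MAE loss, Adam) over the 144-step day."""

    def __init__(
        self,
        samples: Sequence[DaySequenceSample],
        spec: SequenceModelSpec = SequenceModelSpec(),
    ):
        if len(samples) < 10:
            raise ParameterError("need >= 10 training samples")
        self.samples = list(samples)
        self.spec = spec

    def fit(self, seed: Optional[int] = None) -> "DailyWeightResults":
        seed = self.spec.seed if seed is None else seed
        x, y = _xy(self.samples)
        xs = _Standardizer.from_data(x)
        ys_mu, ys_sd = float(y.mean()), float(y.std()) or 1.0
        rng = np.random.default_rng(seed)
        net = _build_sequence_net(self.spec, rng)
        history = nn.fit(
            net,
            xs(x)[..., None],
            (y - ys_mu) / ys_sd,
            epochs=self.spec.epochs,
            batch_size=self.spec.batch_size,
            lr=self.spec.lr,
            seed=seed,
        )
        predict = (
            lambda xq: nn.predict_batched(
                net, xs(xq)[..., None], self.spec.batch_size
            ).ravel()
            * ys_sd
            + ys_mu
        )
        return DailyWeightResults(
            kind=self.spec.flavor, predict_fn=predict, x_std=xs, coef=None, history=history
        )


@dataclass
class DailyWeightResults:
    """Fitted daily-weight model; ``predict`` maps (n, 144) weight
    sequences (kg) to daily crop fresh weights (kg)."""

    kind: str
    predict_fn: object
    x_std: _Standardizer
    coef: Optional[np.ndarray]
    history: Optional[dict]

    def predict(self, samples_or_x) -> np.ndarray:
        if len(samples_or_x) and isinstance(samples_or_x[0], DaySequenceSample):
            x, _ = _xy(samples_or_x)
        else:
            x = np.asarray(samples_or_x, dtype=float)
        return self.predict_fn(x)

    def evaluate(self, samples: Sequence[DaySequenceSample]) -> dict:
        x, y = _xy(samples)
        pred = self.predict_fn(x)
        m = compute_metrics(pred, y)
        m["mean_bias"] = float(np.mean(pred - y))
        return m


def cross_season_eval(
    model,
    train_season: Sequence[DaySequenceSample],
    test_season: Sequence[DaySequenceSample],
    seed: int = 0,
) -> dict:
    """Fit on one season, evaluate on another: r2, rmse, mae, mean_bias
    (mean of prediction minus target, kg).

    The two seasons must be distinct sample sets (sharing sample objects is
    a protocol error); identically *distributed* seasons are fine and give
    near-zero bias.
    """
    train_ids = {id(s) for s in train_season}
    if any(id(s) in train_ids for s in test_season):
        raise ProtocolError("train and test seasons share samples")
    res = model.fit(seed=seed)
    return res.evaluate(test_season)


def dataset_to_frame(samples: Sequence[DaySequenceSample]) -> pd.DataFrame:
    x, y = _xy(samples)
    cols = {f"w_{i + 1:04d}": x[:, i] for i in range(x.shape[1])}
    return pd.DataFrame({"dat": [s.dat for s in samples], **cols, "target": y})
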