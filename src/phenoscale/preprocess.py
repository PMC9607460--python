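"""Sensor-stream preprocessing: gap interpolation and daily aggregation.

The fresh-weight calculation consumes one record per day: the 24-hour mean
system weight and the mean volumetric water content over a nighttime
window. Night VWC is used because irrigation and transpiration are radiation
driven — at night the water store is quiet, so weight change and VWC change
track each other and the water weight can be excluded cleanly.
"""

from __future__ import annotations

import logging
from datetime import time, timedelta
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import GapError
from .simulate.sensors import STEPS_PER_DAY, frame_to_records, records_to_frame
from .types import DailyAggregate, SensorRecord

logger = logging.getLogger(__name__)

_CHANNELS = ["temp_c", "rad_wm2", "vwc", "weight_kg"]


def interpolate_gaps(records: Sequence[SensorRecord]) -> List[SensorRecord]:
    """Replace invalid records by linear interpolation between the nearest
    valid neighbours, per channel; timestamps and ordering are unchanged and
    every output record is valid.

    Raises :class:`GapError` if no record is valid, or if the stream starts
    or ends with an invalid record (interpolation would be unbounded).
    """
    df = records_to_frame(records)
    if len(df) == 0:
        return []
    valid = df["valid"].astype(bool)
    if not valid.any():
        raise GapError("all records invalid; nothing to interpolate from")
    if not (bool(valid.iloc[0]) and bool(valid.iloc[-1])):
        raise GapError("stream must start and end with valid records")
    for col in _CHANNELS:
        s = df[col].where(valid, np.nan)
        df[col] = s.interpolate(method="linear", limit_direction="both")
    df["valid"] = 1
    return frame_to_records(df)


def aggregate_daily(
    records: Sequence[SensorRecord],
    night_window: Tuple[time, time] = (time(22, 0), time(4, 0)),
    start_dat: int = 1,
    min_weight_samples: int = 120,
    min_night_fraction: float = 0.75,
) -> List[DailyAggregate]:
    """Collapse a gap-free stream into one aggregate per calendar day.

    The night window may wrap midnight; wrapped samples (after midnight)
    are attributed to the day that just ended — the night "belongs" to the
    preceding growth day. The window is closed at the start and open at the
    end, so 22:00–04:00 on a 10-minute grid holds 36 samples. Days with
    fewer than ``min_weight_samples`` weight samples or less than
    ``min_night_fraction`` of the night window are dropped with a warning.
    DAT indices count from ``start_dat`` at the first calendar day.
    """
    if any(not r.valid for r in records):
        raise GapError("aggregate_daily expects a gap-free stream; interpolate first")
    df = records_to_frame(records)
    if len(df) == 0:
        return []
    ts = pd.to_datetime(df["timestamp"])
    df = df.assign(date=ts.dt.date, clock=ts.dt.time)
    day0 = df["date"].min()

    w_start, w_end = night_window
    if w_start <= w_end:  # non-wrapping window
        in_night = (df["clock"] >= w_start) & (df["clock"] < w_end)
        night_day = df["date"]
        window_minutes = (
            (w_end.hour * 60 + w_end.minute) - (w_start.hour * 60 + w_start.minute)
        )
    else:  # wraps midnight
        pre = df["clock"] >= w_start
        post = df["clock"] < w_end
        in_night = pre | post
        night_day = df["date"].where(
            ~post, (ts - timedelta(days=1)).dt.date
        )
        window_minutes = (24 * 60 - (w_start.hour * 60 + w_start.minute)) + (
            w_end.hour * 60 + w_end.minute
        )
    window_points = window_minutes // 10
    min_night = int(np.ceil(min_night_fraction * window_points))

    weight_g = df.groupby("date")["weight_kg"].agg(["mean", "size"])
    night_df = df.loc[in_night].assign(night_date=night_day[in_night])
    vwc_g = night_df.groupby("night_date")["vwc"].agg(["mean", "size"])

    out: List[DailyAggregate] = []
    for date, wrow in weight_g.iterrows():
        if date not in vwc_g.index:
            logger.warning("day %s dropped: no night VWC samples", date)
            continue
        vrow = vwc_g.loc[date]
        if wrow["size"] < min_weight_samples or vrow["size"] < min_night:
            logger.warning(
                "day %s dropped: %d weight / %d night samples below minimum",
                date,
                int(wrow["size"]),
                int(vrow["size"]),
            )
            continue
        out.append(
            DailyAggregate(
                dat=start_dat + (date - day0).days,
                mean_system_weight=float(wrow["mean"]),
                night_mean_vwc=float(vrow["mean"]),
                n_weight_samples=int(wrow["size"]),
                n_night_vwc_samples=int(vrow["size"]),
            )
        )
    out.sort(key=lambda a: a.dat)
    return out


def aggregates_to_frame(aggs: Sequence[DailyAggregate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dat": [a.dat for a in aggs],
            "mean_weight_kg": [a.mean_system_weight for a in aggs],
            "night_vwc": [a.night_mean_vwc for a in aggs],
            "n_w": [a.n_weight_samples for a in aggs],
            "n_v": [a.n_night_vwc_samples for a in aggs],
        }
    )


def frame_to_aggregates(df: pd.DataFrame) -> List[DailyAggregate]:
    return [
        DailyAggregate(
            dat=int(r.dat),
            mean_system_weight=float(r.mean_weight_kg),
            night_mean_vwc=float(r.night_vwc),
            n_weight_samples=int(r.n_w),
            n_night_vwc_samples=int(r.n_v),
        )
        for r in df.itertuples()
    ]
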