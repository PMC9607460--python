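"""Crop fresh weight from total system weight and substrate moisture.

The monitored system's load cell carries crop, substrate and water, so

    crop fresh weight = system weight - (substrate dry weight + water weight)
    water weight      = VWC x substrate volume        (1 g mL^-1)

evaluated once per day on the 24-h mean system weight and the nighttime mean
volumetric water content. Root mass, which destructive sampling cannot
recover from the slab, is imputed for reference series via two allometric
ratios: RS (root dry / shoot dry) and DF (root dry / root fresh).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EvaluationError, ParameterError
from .metrics import compute_metrics
from .types import DailyAggregate, FreshWeightSeries, RatioSet, SubstrateSpec


def water_weight(vwc: float, substrate_volume: float) -> float:
    """Water mass in kg held by a slab of ``substrate_volume`` litres at
    volumetric water content ``vwc`` (water density 1 g mL^-1, so litres of
    water equal kilograms)."""
    vwc = float(vwc)
    if not (0.0 <= vwc <= 1.0):
        raise ParameterError(f"vwc {vwc} outside [0, 1]")
    if substrate_volume <= 0:
        raise ParameterError("substrate_volume must be positive")
    return vwc * substrate_volume


def crop_fresh_weight(agg: DailyAggregate, substrate: SubstrateSpec) -> float:
    """One day's crop fresh weight in kg.

    May be negative on miscalibrated inputs; callers flag rather than clip
    such values, since they signal calibration faults the monitoring use
    case must surface.
    """
    return (
        agg.mean_system_weight
        - substrate.dry_weight / 1000.0
        - water_weight(agg.night_mean_vwc, substrate.volume)
    )


def fresh_weight_series(
    aggregates: Sequence[DailyAggregate], substrate: SubstrateSpec
) -> FreshWeightSeries:
    """Apply the daily calculation over a whole season of aggregates."""
    dat = np.array([a.dat for a in aggregates], dtype=int)
    ww = np.array([water_weight(a.night_mean_vwc, substrate.volume) for a in aggregates])
    fw = np.array([crop_fresh_weight(a, substrate) for a in aggregates])
    return FreshWeightSeries(dat=dat, crop_fresh_weight=fw, water_weight=ww)


def root_fresh_weight(shoot_dry: float, ratios: RatioSet) -> float:
    """Impute root fresh weight (g) from shoot dry weight (g):
    root dry = shoot dry x RS; root fresh = root dry / DF."""
    if shoot_dry < 0:
        raise ParameterError("shoot_dry must be >= 0")
    return shoot_dry * ratios.rs_ratio / ratios.df_ratio


def build_reference_series(
    destructive_samples: pd.DataFrame, ratios: RatioSet
) -> pd.DataFrame:
    """Validation reference from destructive samples.

    ``destructive_samples`` columns: dat, shoot_fresh_kg, shoot_dry_g (a
    replicate column may be present). Per sample the imputed root fresh
    weight is added to the shoot fresh weight; replicates are aggregated to
    mean +- SD per DAT. Returns a DataFrame (dat, total_fresh_kg, sd_kg, n).
    """
    if len(destructive_samples) == 0:
        raise ParameterError("destructive sample table is empty")
    df = destructive_samples.copy()
    df["total_fresh_kg"] = df["shoot_fresh_kg"] + df["shoot_dry_g"].map(
        lambda s: root_fresh_weight(s, ratios)
    ) / 1000.0
    g = df.groupby("dat")["total_fresh_kg"]
    out = g.agg(total_fresh_kg="mean", sd_kg="std", n="size").reset_index()
    out["sd_kg"] = out["sd_kg"].fillna(0.0)
    return out.sort_values("dat").reset_index(drop=True)


def evaluate_series(
    estimate: FreshWeightSeries, reference: pd.DataFrame, value_col: str = "total_fresh_kg"
) -> dict:
    """R^2 and RMSE (kg) of the daily estimate on the DATs present in both
    the estimate and the reference table (columns: dat, ``value_col``)."""
    ref = reference.set_index("dat")[value_col]
    common = np.intersect1d(estimate.dat, ref.index.to_numpy())
    if len(common) < 2:
        raise EvaluationError("need >= 2 overlapping DATs to evaluate")
    est_by_dat = pd.Series(estimate.crop_fresh_weight, index=estimate.dat)
    m = compute_metrics(est_by_dat.loc[common].to_numpy(), ref.loc[common].to_numpy())
    return {"r2": m["r2"], "rmse": m["rmse"], "n": int(len(common))}


def series_to_frame(series: FreshWeightSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dat": series.dat,
            "fw_kg": series.crop_fresh_weight,
            "water_kg": series.water_weight,
            "flag": series.flagged.astype(int),
        }
    )
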