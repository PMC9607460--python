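"""Mechanistic water-balance simulation of the 10-minute sensor streams.

The monitored system is a load cell carrying crop + substrate + water.
Radiation drives both transpiration (water leaves the slab) and the
irrigation controller (a radiation-integral scheme: every time accumulated
radiation reaches a threshold, a fixed dose is delivered through the
drippers). Excess water above the slab's holding capacity drains away
instantly. Volumetric water content is the water volume per slab volume;
at 1 g mL^-1 the same number, times the slab volume, is the water mass —
the identity the downstream fresh-weight calculation inverts.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from ..errors import ConfigurationError, ParameterError
from ..types import CropGroundTruth, IrrigationPolicy, SensorRecord, SubstrateSpec

STEPS_PER_DAY = 144  # 10-minute grid
STEP_SECONDS = 600.0


@dataclass(frozen=True)
class SensorSimConfig:
    """Weather and noise settings of one simulated season.

    ``daily_radiation_mj`` is the mean daily radiation integral inside the
    greenhouse (MJ m^-2 day^-1); day-to-day totals vary lognormally with
    coefficient of variation ``radiation_day_cv``. ``transpiration_coeff``
    converts radiation per unit leaf area into water loss
    (g of water per MJ m^-2 per m^2 of leaf).
    """

    start_date: datetime = datetime(2020, 2, 26)
    daily_radiation_mj: float = 10.0
    radiation_day_cv: float = 0.25
    sunrise_hour: float = 6.0
    sunset_hour: float = 18.0
    transpiration_coeff: float = 200.0
    temp_day: float = 28.0
    temp_night: float = 18.0
    weight_sd: float = 0.05  # kg
    vwc_sd: float = 0.01
    initial_store_fraction: float = 1.0  # of holding capacity


def _daylight_profile(cfg: SensorSimConfig) -> np.ndarray:
    """Unit-integral half-sinusoid over the 144-step day (per-step weights)."""
    hours = np.arange(STEPS_PER_DAY) / 6.0  # step midpoints ignored; grid hours
    span = cfg.sunset_hour - cfg.sunrise_hour
    x = (hours - cfg.sunrise_hour) / span
    w = np.where((x > 0) & (x < 1), np.sin(np.pi * x), 0.0)
    s = w.sum()
    return w / s if s > 0 else w


def simulate_sensors(
    truth: Sequence[CropGroundTruth],
    substrate: SubstrateSpec,
    policy: IrrigationPolicy,
    config: SensorSimConfig = SensorSimConfig(),
    seed: int = 0,
) -> List[SensorRecord]:
    """10-minute sensor stream for a whole season. See
    :func:`simulate_sensors_with_log` for the irrigation event log."""
    records, _ = simulate_sensors_with_log(truth, substrate, policy, config, seed)
    return records


def simulate_sensors_with_log(
    truth: Sequence[CropGroundTruth],
    substrate: SubstrateSpec,
    policy: IrrigationPolicy,
    config: SensorSimConfig = SensorSimConfig(),
    seed: int = 0,
) -> Tuple[List[SensorRecord], pd.DataFrame]:
    """Simulate the stream and also return the irrigation event log
    (DataFrame: timestamp, dat, dose_g).

    The controller accumulates radiation from midnight; each event subtracts
    the threshold from the accumulator (carry-over semantics), so the number
    of events on a day equals floor(daily radiation / threshold). Noise
    (gaussian, SDs in ``config``) applies to the reported weight and VWC
    only, never to the hidden water balance.
    """
    if len(truth) == 0:
        raise ParameterError("truth trajectory is empty")
    if config.weight_sd < 0 or config.vwc_sd < 0:
        raise ParameterError("noise SDs must be >= 0")
    dose_g = policy.dose_per_dripper * substrate.drippers  # 1 g mL^-1
    if dose_g > substrate.capacity_g:
        raise ConfigurationError(
            f"irrigation dose {dose_g} g exceeds substrate holding capacity "
            f"{substrate.capacity_g} g; no event could ever fit"
        )

    rng = np.random.default_rng(seed)
    n_days = len(truth)
    fw = np.array([t.crop_fresh_weight for t in truth])
    la_m2 = np.array(
        [t.leaf_area for t in truth]
    ) / 1.0e4 * substrate.plants_per_slab

    # centered within-day interpolation of fresh weight: the mean over a
    # day's 144 steps equals that day's ground-truth value exactly, so
    # daily averaging introduces no growth-trend bias
    fw_slope = np.gradient(fw) if n_days > 1 else np.zeros(1)

    day_weights = _daylight_profile(config)
    sigma = np.sqrt(np.log1p(config.radiation_day_cv**2))
    day_totals = config.daily_radiation_mj * np.exp(
        rng.normal(-0.5 * sigma**2, sigma, size=n_days)
    )

    store = config.initial_store_fraction * substrate.capacity_g
    records: List[SensorRecord] = []
    events = []
    span = config.sunset_hour - config.sunrise_hour

    for di in range(n_days):
        acc = 0.0  # controller resets at midnight
        # per-step radiation in W m^-2 (step energy MJ -> mean power)
        step_mj = day_totals[di] * day_weights
        rad_wm2 = step_mj * 1.0e6 / STEP_SECONDS
        for si in range(STEPS_PER_DAY):
            ts = config.start_date + timedelta(days=di, seconds=si * STEP_SECONDS)
            hour = si / 6.0
            # irrigation controller
            acc += step_mj[si]
            # tiny relative slack so float accumulation cannot miss a
            # crossing that exact arithmetic would hit
            while acc >= policy.radiation_threshold * (1.0 - 1e-9):
                acc -= policy.radiation_threshold
                store += dose_g
                events.append(
                    {"timestamp": ts, "dat": truth[di].dat, "dose_g": dose_g}
                )
            # transpiration, throttled when the slab runs dry
            avail = min(1.0, store / (0.25 * substrate.capacity_g))
            transp = config.transpiration_coeff * step_mj[si] * la_m2[di] * avail
            store -= min(transp, store)
            # instant drainage of excess
            store = min(store, substrate.capacity_g)

            fw_now = fw[di] + fw_slope[di] * (si - (STEPS_PER_DAY - 1) / 2.0) / STEPS_PER_DAY
            vwc_true = store / substrate.volume_cm3
            weight_true = fw_now + substrate.dry_weight / 1000.0 + store / 1000.0

            vwc = vwc_true
            weight = weight_true
            if config.vwc_sd > 0:
                vwc = float(np.clip(vwc + rng.normal(0.0, config.vwc_sd), 0.0, 1.0))
            if config.weight_sd > 0:
                weight = weight + rng.normal(0.0, config.weight_sd)

            day_frac = np.clip((hour - config.sunrise_hour) / span, 0.0, 1.0)
            temp = config.temp_night + (config.temp_day - config.temp_night) * float(
                np.sin(np.pi * day_frac)
            )

            records.append(
                SensorRecord(
                    timestamp=ts,
                    air_temperature=temp,
                    solar_radiation=float(rad_wm2[si]),
                    vwc=float(vwc),
                    system_weight=float(weight),
                    valid=True,
                )
            )
    return records, pd.DataFrame(events, columns=["timestamp", "dat", "dose_g"])


def records_to_frame(records: Sequence[SensorRecord]) -> pd.DataFrame:
    """Tabulate records with the package's CSV column dialect."""
    return pd.DataFrame(
        {
            "timestamp": [r.timestamp for r in records],
            "temp_c": [r.air_temperature for r in records],
            "rad_wm2": [r.solar_radiation for r in records],
            "vwc": [r.vwc for r in records],
            "weight_kg": [r.system_weight for r in records],
            "valid": [int(r.valid) for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> List[SensorRecord]:
    ts = pd.to_datetime(df["timestamp"])
    return [
        SensorRecord(
            timestamp=t.to_pydatetime(),
            air_temperature=float(a),
            solar_radiation=float(r),
            vwc=float(v),
            system_weight=float(w),
            valid=bool(int(g)),
        )
        for t, a, r, v, w, g in zip(
            ts, df["temp_c"], df["rad_wm2"], df["vwc"], df["weight_kg"], df["valid"]
        )
    ]
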