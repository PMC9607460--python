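"""Domain types shared across the monitoring pipeline.

All weights are per monitored system (one substrate slab plus the plants it
hosts) unless a name says otherwise; leaf area is per plant in cm^2.
Canonical internal units are grams and cm^3; the public API speaks kg and L
(water density is taken as 1 g mL^-1, so litres of water convert to kg
one-to-one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class CropGroundTruth:
    """Hidden simulator truth for one day.

    dat: days after transplanting; crop_fresh_weight in kg per system
    (shoot + root + fruit, everything the load cell would carry);
    shoot/root dry weights in g per system; leaf_area in cm^2 per plant.
    """

    dat: int
    crop_fresh_weight: float
    shoot_dry_weight: float
    root_dry_weight: float
    leaf_area: float
    topping_dat: Optional[int] = None


@dataclass(frozen=True)
class SubstrateSpec:
    """A stone-wool slab and its plumbing.

    dry_weight in g, volume in L, water_capacity the maximum volumetric
    water content the slab can hold (fraction of its volume).
    """

    dry_weight: float = 656.5
    volume: float = 12.0
    water_capacity: float = 0.80
    plants_per_slab: int = 4
    drippers: int = 4

    def __post_init__(self):
        if not (0.0 < self.water_capacity <= 1.0):
            raise ParameterError("water_capacity must be in (0, 1]")
        if self.volume <= 0 or self.dry_weight <= 0:
            raise ParameterError("substrate volume and dry_weight must be positive")
        if self.plants_per_slab < 1 or self.drippers < 1:
            raise ParameterError("plants_per_slab and drippers must be >= 1")

    @property
    def volume_cm3(self) -> float:
        return self.volume * 1000.0

    @property
    def capacity_g(self) -> float:
        """Maximum grams of water the slab holds (1 g cm^-3)."""
        return self.water_capacity * self.volume_cm3


@dataclass(frozen=True)
class IrrigationPolicy:
    """Radiation-integral irrigation controller settings.

    Every time the accumulated solar radiation reaches
    ``radiation_threshold`` (MJ m^-2), one event delivers
    ``dose_per_dripper`` mL through each dripper.
    """

    radiation_threshold: float = 0.5
    dose_per_dripper: float = 66.0

    def __post_init__(self):
        if self.radiation_threshold <= 0 or self.dose_per_dripper <= 0:
            raise ParameterError("irrigation threshold and dose must be positive")


@dataclass
class SensorRecord:
    """One 10-minute observation of the greenhouse and the load cell."""

    timestamp: datetime
    air_temperature: float
    solar_radiation: float  # W m^-2
    vwc: float  # volumetric water content, fraction
    system_weight: float  # kg
    valid: bool = True


@dataclass(frozen=True)
class CanopyImage:
    """Top-view RGB frame, 8-bit channels."""

    pixels: np.ndarray  # H x W x 3 uint8
    timestamp: datetime
    dat: int


@dataclass(frozen=True)
class DailyAggregate:
    """Per-day input of the fresh-weight calculation: the 24-h mean system
    weight and the nighttime mean VWC."""

    dat: int
    mean_system_weight: float  # kg
    night_mean_vwc: float  # fraction
    n_weight_samples: int
    n_night_vwc_samples: int


@dataclass(frozen=True)
class RatioSet:
    """Allometric ratios used to impute root mass.

    rs_ratio: root dry weight / shoot dry weight.
    df_ratio: root dry weight / root fresh weight.
    """

    rs_ratio: float
    df_ratio: float

    def __post_init__(self):
        if self.rs_ratio <= 0:
            raise ParameterError("rs_ratio must be positive")
        if not (0.0 < self.df_ratio < 1.0):
            raise ParameterError("df_ratio must be in (0, 1)")


@dataclass
class FreshWeightSeries:
    """Daily crop fresh weight recovered from the weight/VWC streams."""

    dat: np.ndarray  # int
    crop_fresh_weight: np.ndarray  # kg
    water_weight: np.ndarray  # kg
    flagged: np.ndarray = field(default=None)  # True where computed weight < 0

    def __post_init__(self):
        self.dat = np.asarray(self.dat, dtype=int)
        self.crop_fresh_weight = np.asarray(self.crop_fresh_weight, dtype=float)
        self.water_weight = np.asarray(self.water_weight, dtype=float)
        if self.flagged is None:
            self.flagged = self.crop_fresh_weight < 0
        self.flagged = np.asarray(self.flagged, dtype=bool)


@dataclass(frozen=True)
class SigmoidCoefficients:
    """Coefficients of the leaf-area-vs-DAT growth curve.

    The primary form is the standard logistic
    ``leaf_area = L / (1 + exp(-k (DAT - x0))) + b`` with asymptote ``L``
    (cm^2), rate ``k`` (per day), midpoint ``x0`` (DAT) and baseline ``b``
    (cm^2).
    """

    L: float
    k: float
    x0: float
    b: float

    def __post_init__(self):
        if self.L <= 0 or self.k <= 0:
            raise ParameterError("sigmoid L and k must be positive")


@dataclass
class LabelTable:
    """One leaf-area label per DAT over a contiguous span; all images taken
    on the same date share the day's label."""

    dat: np.ndarray
    leaf_area_label: np.ndarray

    def __post_init__(self):
        self.dat = np.asarray(self.dat, dtype=int)
        self.leaf_area_label = np.asarray(self.leaf_area_label, dtype=float)
        if len(self.dat) != len(self.leaf_area_label):
            raise ParameterError("dat and label arrays must have equal length")

    def label_for(self, dat: int) -> float:
        idx = np.nonzero(self.dat == dat)[0]
        if len(idx) == 0:
            raise KeyError(f"no label for DAT {dat}")
        return float(self.leaf_area_label[idx[0]])


@dataclass
class DaySequenceSample:
    """One day's intra-day system-weight sequence and its calculated daily
    crop fresh weight target (both kg)."""

    dat: int
    weights: np.ndarray  # length 144
    target: float


def as_truth_frame(truth: Sequence[CropGroundTruth]):
    """Tabulate a ground-truth trajectory as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "dat": [t.dat for t in truth],
            "fw_kg": [t.crop_fresh_weight for t in truth],
            "shoot_dw_g": [t.shoot_dry_weight for t in truth],
            "root_dw_g": [t.root_dry_weight for t in truth],
            "la_cm2": [t.leaf_area for t in truth],
        }
    )
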