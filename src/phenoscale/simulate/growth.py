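"""Ground-truth crop trajectories.

Fresh weight and leaf area both follow logistic curves over days after
transplanting (DAT). Fresh weight can take step decreases at listed harvest
or pruning days; leaf area stops increasing after topping (removal of the
shoot apical meristems) and may decay slightly as lower leaves are pruned.

Dry-matter bookkeeping: a fixed dry-matter fraction converts fresh weight to
total dry weight, which is partitioned between shoot and root so that
root dry weight = shoot dry weight x rs_ratio exactly. Root fresh weight is
root dry weight / df_ratio, mirroring how the analysis imputes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ..errors import ParameterError
from ..types import CropGroundTruth, RatioSet


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth parameters of one simulated season.

    Weights are per monitored system (slab + plants), leaf area per plant.
    ``events`` lists (dat, drop_kg) step decreases of fresh weight from
    harvests or hard pruning. ``noise_sd`` is a multiplicative lognormal
    day-to-day jitter on fresh weight (0 = deterministic trajectory).
    """

    fw_asymptote: float = 3.2  # kg per system
    fw_rate: float = 0.08  # per day
    fw_midpoint: float = 45.0  # DAT
    la_asymptote: float = 5000.0  # cm^2 per plant
    la_rate: float = 0.10
    la_midpoint: float = 50.0
    la_baseline: float = 100.0
    topping_dat: Optional[int] = None
    events: Tuple[Tuple[int, float], ...] = ()
    dry_matter_fraction: float = 0.10
    rs_ratio: float = 0.20
    df_ratio: float = 0.25
    noise_sd: float = 0.0
    start_dat: int = 1

    def __post_init__(self):
        for name in ("fw_asymptote", "fw_rate", "la_asymptote", "la_rate"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not (0 < self.dry_matter_fraction < 1):
            raise ParameterError("dry_matter_fraction must be in (0, 1)")

    @property
    def ratios(self) -> RatioSet:
        return RatioSet(rs_ratio=self.rs_ratio, df_ratio=self.df_ratio)


def _logistic(x, L, k, x0, b=0.0):
    return L / (1.0 + np.exp(-k * (np.asarray(x, dtype=float) - x0))) + b


def simulate_growth(
    params: GrowthParams, n_days: int, seed: int
) -> List[CropGroundTruth]:
    """Simulate one record per day for ``n_days`` days starting at
    ``params.start_dat``.

    Deterministic given (params, seed). Fresh weight is clipped to stay
    strictly positive after event drops.
    """
    if n_days < 2:
        raise ParameterError("n_days must be >= 2")
    rng = np.random.default_rng(seed)
    dats = np.arange(params.start_dat, params.start_dat + n_days)

    fw = _logistic(dats, params.fw_asymptote, params.fw_rate, params.fw_midpoint)
    if params.noise_sd > 0:
        fw = fw * np.exp(rng.normal(0.0, params.noise_sd, size=fw.shape))
    # step decreases persist from the event day onward
    for ev_dat, drop in params.events:
        fw = np.where(dats >= ev_dat, fw - drop, fw)
    fw = np.maximum(fw, 0.05)

    la = _logistic(
        dats, params.la_asymptote, params.la_rate, params.la_midpoint, params.la_baseline
    )
    if params.topping_dat is not None:
        la_top = _logistic(
            params.topping_dat,
            params.la_asymptote,
            params.la_rate,
            params.la_midpoint,
            params.la_baseline,
        )
        after = dats > params.topping_dat
        # gentle post-topping decline: 0.2% of the topped value per day
        decay = 1.0 - 0.002 * (dats - params.topping_dat)
        la = np.where(after, la_top * np.maximum(decay, 0.8), la)

    total_dw_g = fw * 1000.0 * params.dry_matter_fraction
    shoot_dw = total_dw_g / (1.0 + params.rs_ratio)
    root_dw = shoot_dw * params.rs_ratio

    return [
        CropGroundTruth(
            dat=int(d),
            crop_fresh_weight=float(w),
            shoot_dry_weight=float(s),
            root_dry_weight=float(r),
            leaf_area=float(a),
            topping_dat=params.topping_dat,
        )
        for d, w, s, r, a in zip(dats, fw, shoot_dw, root_dw, la)
    ]


def shoot_fresh_weight(truth: CropGroundTruth, ratios: RatioSet) -> float:
    """Shoot fresh weight in kg: total minus the root fresh weight implied
    by the simulator's own ratios (root fresh = root dry / df_ratio)."""
    root_fresh_kg = truth.root_dry_weight / ratios.df_ratio / 1000.0
    return truth.crop_fresh_weight - root_fresh_kg


def destructive_samples(
    truth: Sequence[CropGroundTruth],
    ratios: RatioSet,
    sample_dats: Sequence[int],
    n_replicates: int,
    noise_cv: float,
    seed: int,
):
    """Emulate destructive investigations: on each sampling day, harvest
    ``n_replicates`` plants-worth of noisy measurements.

    Returns a DataFrame (dat, replicate, shoot_fresh_kg, shoot_dry_g,
    leaf_area_cm2). Noise is multiplicative lognormal with coefficient of
    variation ``noise_cv`` per replicate, mimicking plant-to-plant spread.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    by_dat = {t.dat: t for t in truth}
    rows = []
    sigma = np.sqrt(np.log1p(noise_cv**2))
    for dat in sample_dats:
        if dat not in by_dat:
            raise ParameterError(f"sampling day {dat} outside simulated span")
        t = by_dat[dat]
        sfw = shoot_fresh_weight(t, ratios)
        for rep in range(n_replicates):
            f = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=3))
            rows.append(
                {
                    "dat": dat,
                    "replicate": rep,
                    "shoot_fresh_kg": sfw * f[0],
                    "shoot_dry_g": t.shoot_dry_weight * f[1],
                    "leaf_area_cm2": t.leaf_area * f[2],
                }
            )
    return pd.DataFrame(rows)
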