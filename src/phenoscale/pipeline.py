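"""End-to-end experiment orchestration.

A full experiment simulates two seasons (train and test), runs both
estimation tracks — the closed-form fresh-weight calculation and the two
learned tracks (canopy-image leaf-area regressor, daily-weight sequence
models) — and writes a report bundle: metrics JSON, trajectory figures and
provenance (config hash, seed, package versions). Stages are file-based and
re-runnable individually; every stochastic stage receives a seed derived
deterministically from the global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from datetime import datetime, time
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io
from .errors import ParameterError, PipelineError
from .freshweight import (
    build_reference_series,
    evaluate_series,
    fresh_weight_series,
    series_to_frame,
)
from .images import (
    CanopyRegressor,
    RegressorSpec,
    evaluate_daily,
    preprocess_image,
    select_time_window,
)
from .leafarea import SigmoidGrowthModel
from .metrics import compute_metrics  # noqa: F401  (shared metrics surface)
from .preprocess import aggregate_daily, aggregates_to_frame, interpolate_gaps
from .simulate import (
    CameraSpec,
    GrowthParams,
    SensorSimConfig,
    default_capture_times,
    destructive_samples,
    inject_missing,
    simulate_camera_day,
    simulate_growth,
    simulate_sensors,
)
from .types import FreshWeightSeries, IrrigationPolicy, LabelTable, SubstrateSpec
from .weightmodels import (
    LinearDailyWeightModel,
    SequenceDailyWeightModel,
    SequenceModelSpec,
    build_sequence_dataset,
    cross_season_eval,
    dataset_to_frame,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "calc_fw", "labels", "train_la", "train_fw", "report")


@dataclass(frozen=True)
class SeasonConfig:
    """Everything that defines one simulated cultivation period."""

    name: str = "A"
    n_days: int = 100
    growth: GrowthParams = field(default_factory=GrowthParams)
    substrate: SubstrateSpec = field(default_factory=SubstrateSpec)
    policy: IrrigationPolicy = field(default_factory=IrrigationPolicy)
    sensors: SensorSimConfig = field(default_factory=SensorSimConfig)
    camera: CameraSpec = field(default_factory=CameraSpec)
    images_per_day: int = 4
    capture_window: Tuple[float, float] = (8.0, 16.0)
    n_investigations: int = 5
    n_replicates: int = 4
    sample_noise_cv: float = 0.08
    gap_rate: float = 0.0
    max_gap_len: int = 6


def default_train_season() -> SeasonConfig:
    """Spring-style season: 4 plants per slab, lighter substrate."""
    return SeasonConfig(name="A", n_days=100)


def default_test_season() -> SeasonConfig:
    """Winter-style season: 3 plants per slab, heavier substrate, less
    light, topping partway through — deliberately shifted conditions."""
    return SeasonConfig(
        name="B",
        n_days=80,
        growth=GrowthParams(
            fw_asymptote=2.8,
            fw_rate=0.09,
            fw_midpoint=40.0,
            la_asymptote=4200.0,
            la_rate=0.09,
            la_midpoint=45.0,
            la_baseline=80.0,
            topping_dat=70,
        ),
        substrate=SubstrateSpec(dry_weight=887.2, plants_per_slab=3, drippers=3),
        sensors=SensorSimConfig(
            start_date=datetime(2020, 8, 25), daily_radiation_mj=7.0
        ),
        camera=CameraSpec(n_plants=3, illumination=0.85),
    )


@dataclass(frozen=True)
class ExperimentConfig:
    train_season: SeasonConfig = field(default_factory=default_train_season)
    test_season: SeasonConfig = field(default_factory=default_test_season)
    night_window: Tuple[int, int] = (22, 4)  # clock hours
    margins: Tuple[int, int] = (80, 300)
    input_size: int = 128
    outlier_sd: float = 2.5
    regressor: RegressorSpec = field(default_factory=RegressorSpec)
    sequence_model: SequenceModelSpec = field(default_factory=SequenceModelSpec)
    split_fraction: float = 0.7
    seed: int = 0
    outdir: str = "phenoscale_run"

    def __post_init__(self):
        if not (0.0 < self.split_fraction < 1.0):
            raise ParameterError("split_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# config (de)serialisation


def config_to_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for season in ("train_season", "test_season"):
        d[season]["sensors"]["start_date"] = cfg.__getattribute__(
            season
        ).sensors.start_date.strftime("%Y-%m-%dT%H:%M:%S")
    return d


def _season_from_dict(d: dict) -> SeasonConfig:
    d = dict(d)
    if "growth" in d:
        g = dict(d["growth"])
        if "events" in g:
            g["events"] = tuple(tuple(e) for e in g["events"])
        d["growth"] = GrowthParams(**g)
    if "substrate" in d:
        d["substrate"] = SubstrateSpec(**d["substrate"])
    if "policy" in d:
        d["policy"] = IrrigationPolicy(**d["policy"])
    if "sensors" in d:
        s = dict(d["sensors"])
        if isinstance(s.get("start_date"), str):
            s["start_date"] = datetime.fromisoformat(s["start_date"])
        d["sensors"] = SensorSimConfig(**s)
    if "camera" in d:
        d["camera"] = CameraSpec(**d["camera"])
    if "capture_window" in d:
        d["capture_window"] = tuple(d["capture_window"])
    return SeasonConfig(**d)


def config_from_dict(d: dict) -> ExperimentConfig:
    d = dict(d)
    for season in ("train_season", "test_season"):
        if season in d:
            d[season] = _season_from_dict(d[season])
    if "regressor" in d:
        r = dict(d["regressor"])
        if "conv_filters" in r:
            r["conv_filters"] = tuple(r["conv_filters"])
        d["regressor"] = RegressorSpec(**r)
    if "sequence_model" in d:
        d["sequence_model"] = SequenceModelSpec(**d["sequence_model"])
    for key in ("night_window", "margins"):
        if key in d:
            d[key] = tuple(d[key])
    return ExperimentConfig(**d)


def load_config(path) -> ExperimentConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()) or {})


def save_config(cfg: ExperimentConfig, path):
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def config_hash(cfg: ExperimentConfig) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config_to_dict(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]


def stage_seed(cfg: ExperimentConfig, stage: str, season: str = "") -> int:
    """Deterministic per-stage seed derived from the global seed."""
    h = hashlib.sha256(f"{cfg.seed}:{stage}:{season}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# stages


def _seasons(cfg: ExperimentConfig):
    return (cfg.train_season, cfg.test_season)


def _sdir(cfg: ExperimentConfig, season: SeasonConfig) -> Path:
    p = Path(cfg.outdir) / f"season_{season.name}"
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, stage_needed: str):
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path}; run stage '{stage_needed}' first",
            stage=stage_needed,
        )
    return path


def stage_simulate(cfg: ExperimentConfig):
    for season in _seasons(cfg):
        sdir = _sdir(cfg, season)
        truth = simulate_growth(
            season.growth, season.n_days, stage_seed(cfg, "growth", season.name)
        )
        io.write_truth_csv(truth, sdir / "truth.csv")

        records = simulate_sensors(
            truth,
            season.substrate,
            season.policy,
            season.sensors,
            stage_seed(cfg, "sensors", season.name),
        )
        if season.gap_rate > 0:
            records = inject_missing(
                records,
                season.gap_rate,
                season.max_gap_len,
                stage_seed(cfg, "gaps", season.name),
            )
        io.write_sensor_csv(records, sdir / "sensors.csv")

        dats = [t.dat for t in truth]
        sample_dats = np.unique(
            np.linspace(dats[2], dats[-3], season.n_investigations).round().astype(int)
        )
        samples = destructive_samples(
            truth,
            season.growth.ratios,
            sample_dats,
            season.n_replicates,
            season.sample_noise_cv,
            stage_seed(cfg, "destructive", season.name),
        )
        samples.to_csv(sdir / "destructive.csv", index=False)

        times = default_capture_times(
            int(season.capture_window[0]),
            int(season.capture_window[1]),
            season.images_per_day,
        )
        images = []
        for di, t in enumerate(truth):
            date = season.sensors.start_date + pd.Timedelta(days=di)
            images.extend(
                simulate_camera_day(
                    t,
                    season.camera,
                    date,
                    stage_seed(cfg, f"camera{di}", season.name),
                    capture_times=times,
                )
            )
        io.write_images(images, sdir / "images")
    logger.info("simulate: wrote both seasons under %s", cfg.outdir)


def _load_aggregates(cfg, season):
    sdir = _sdir(cfg, season)
    from .preprocess import frame_to_aggregates

    return frame_to_aggregates(
        pd.read_csv(_require(sdir / "daily.csv", "preprocess"))
    )


def stage_preprocess(cfg: ExperimentConfig):
    w = cfg.night_window
    window = (time(w[0] % 24, 0), time(w[1] % 24, 0))
    for season in _seasons(cfg):
        sdir = _sdir(cfg, season)
        records = io.read_sensor_csv(_require(sdir / "sensors.csv", "simulate"))
        records = interpolate_gaps(records)
        io.write_sensor_csv(records, sdir / "sensors_filled.csv")
        aggs = aggregate_daily(
            records, night_window=window, start_dat=season.growth.start_dat
        )
        aggregates_to_frame(aggs).to_csv(sdir / "daily.csv", index=False)


def stage_calc_fw(cfg: ExperimentConfig):
    for season in _seasons(cfg):
        sdir = _sdir(cfg, season)
        aggs = _load_aggregates(cfg, season)
        series = fresh_weight_series(aggs, season.substrate)
        series_to_frame(series).to_csv(sdir / "freshweight.csv", index=False)

        truth = pd.read_csv(_require(sdir / "truth.csv", "simulate"))
        m_truth = evaluate_series(
            series, truth.rename(columns={"fw_kg": "total_fresh_kg"})
        )
        dest = pd.read_csv(_require(sdir / "destructive.csv", "simulate"))
        reference = build_reference_series(dest, season.growth.ratios)
        ref_scaled = reference.copy()
        m_ref = evaluate_series(series, ref_scaled)
        io.write_json(
            {"vs_truth": m_truth, "vs_reference": m_ref},
            sdir / "freshweight_metrics.json",
        )


def stage_labels(cfg: ExperimentConfig):
    for season in _seasons(cfg):
        sdir = _sdir(cfg, season)
        dest = pd.read_csv(_require(sdir / "destructive.csv", "simulate"))
        model = SigmoidGrowthModel.from_dataframe(dest)
        res = model.fit(outlier_sd=cfg.outlier_sd)
        truth = pd.read_csv(_require(sdir / "truth.csv", "simulate"))
        table = res.label_table(range(int(truth.dat.min()), int(truth.dat.max()) + 1))
        pd.DataFrame({"dat": table.dat, "la_cm2": table.leaf_area_label}).to_csv(
            sdir / "labels.csv", index=False
        )
        io.write_json(res.to_dict(), sdir / "label_fit.json")


def _load_tensors(cfg: ExperimentConfig, season: SeasonConfig):
    sdir = _sdir(cfg, season)
    image_dir = _require(sdir / "images", "simulate")
    manifest = pd.read_csv(_require(image_dir / "manifest.csv", "simulate"))
    manifest = select_time_window(manifest)
    tensors = []
    for row in manifest.itertuples():
        img = io.read_image(image_dir, row.filename, row.dat, row.timestamp)
        tensors.append(preprocess_image(img, cfg.margins, cfg.input_size))
    return tensors


def _load_labels(cfg: ExperimentConfig, season: SeasonConfig) -> LabelTable:
    sdir = _sdir(cfg, season)
    df = pd.read_csv(_require(sdir / "labels.csv", "labels"))
    return LabelTable(dat=df.dat.to_numpy(), leaf_area_label=df.la_cm2.to_numpy())


def stage_train_la(cfg: ExperimentConfig):
    train_tensors = _load_tensors(cfg, cfg.train_season)
    labels_a = _load_labels(cfg, cfg.train_season)
    spec = dataclasses.replace(cfg.regressor, seed=stage_seed(cfg, "train_la"))
    model = CanopyRegressor(train_tensors, labels_a, spec)
    res = model.fit(train_fraction=cfg.split_fraction)

    test_tensors = _load_tensors(cfg, cfg.test_season)
    labels_b = _load_labels(cfg, cfg.test_season)
    daily = res.predict_daily(test_tensors)
    metrics = evaluate_daily(daily, labels_b)

    out = Path(cfg.outdir)
    res.save_weights(out / "leafarea_model.npz")
    daily.to_csv(out / "leafarea_predictions.csv", index=False)
    pd.DataFrame(res.history).to_csv(out / "leafarea_history.csv", index=False)
    io.write_json(metrics, out / "leafarea_metrics.json")
    _plot_leafarea(daily, labels_b, out / "fig_leafarea.png")
    return metrics


def _fw_series_from_csv(sdir: Path) -> FreshWeightSeries:
    df = pd.read_csv(_require(sdir / "freshweight.csv", "calc_fw"))
    return FreshWeightSeries(
        dat=df.dat.to_numpy(), crop_fresh_weight=df.fw_kg.to_numpy(),
        water_weight=df.water_kg.to_numpy(),
    )


def stage_train_fw(cfg: ExperimentConfig):
    datasets = {}
    for season in _seasons(cfg):
        sdir = _sdir(cfg, season)
        records = io.read_sensor_csv(_require(sdir / "sensors_filled.csv", "preprocess"))
        fw = _fw_series_from_csv(sdir)
        datasets[season.name] = build_sequence_dataset(
            records, fw, start_dat=season.growth.start_dat
        )
        dataset_to_frame(datasets[season.name]).to_csv(
            sdir / "day_sequences.csv", index=False
        )
    train, test = (datasets[s.name] for s in _seasons(cfg))
    seed = stage_seed(cfg, "train_fw")
    results = {
        "linear": cross_season_eval(LinearDailyWeightModel(train), train, test, seed=seed),
        cfg.sequence_model.flavor: cross_season_eval(
            SequenceDailyWeightModel(train, cfg.sequence_model), train, test, seed=seed
        ),
    }
    io.write_json(results, Path(cfg.outdir) / "dailyweight_metrics.json")
    return results


def stage_report(cfg: ExperimentConfig):
    out = Path(cfg.outdir)
    report = {"provenance": provenance(cfg)}
    for season in _seasons(cfg):
        p = _sdir(cfg, season) / "freshweight_metrics.json"
        if p.exists():
            report[f"freshweight_{season.name}"] = io.read_json(p)
        p = _sdir(cfg, season) / "label_fit.json"
        if p.exists():
            report[f"label_fit_{season.name}"] = io.read_json(p)
    for name in ("leafarea_metrics", "dailyweight_metrics"):
        p = out / f"{name}.json"
        if p.exists():
            report[name] = io.read_json(p)
    io.write_json(report, out / "report.json")
    for season in _seasons(cfg):
        sdir = _sdir(cfg, season)
        if (sdir / "freshweight.csv").exists() and (sdir / "truth.csv").exists():
            _plot_freshweight(
                pd.read_csv(sdir / "truth.csv"),
                pd.read_csv(sdir / "freshweight.csv"),
                out / f"fig_freshweight_{season.name}.png",
            )
    return report


def provenance(cfg: ExperimentConfig) -> dict:
    import scipy

    return {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
    }


_STAGE_FN = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "calc_fw": stage_calc_fw,
    "labels": stage_labels,
    "train_la": stage_train_la,
    "train_fw": stage_train_fw,
    "report": stage_report,
}


def run_pipeline(cfg: ExperimentConfig, stages: Optional[Sequence[str]] = None) -> dict:
    """Run the selected stages (default: all) in dependency order and
    return the report dict (empty until the report stage runs)."""
    selected = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or ()) - set(STAGES)
    if unknown:
        raise ParameterError(f"unknown stages: {sorted(unknown)}")
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    save_config(cfg, Path(cfg.outdir) / "config.yaml")
    report = {}
    for s in selected:
        logger.info("stage %s", s)
        out = _STAGE_FN[s](cfg)
        if s == "report":
            report = out
    return report


# ---------------------------------------------------------------------------
# figures (advisory; no acceptance number is ever read off a figure)


def _plot_freshweight(truth: pd.DataFrame, fw: pd.DataFrame, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(truth.dat, truth.fw_kg, label="ground truth", color="k")
    ax.plot(fw.dat, fw.fw_kg, label="calculated", color="tab:green", alpha=0.8)
    ax.set_xlabel("days after transplanting")
    ax.set_ylabel("crop fresh weight (kg/system)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_leafarea(daily: pd.DataFrame, labels: LabelTable, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(labels.dat, labels.leaf_area_label, color="k", label="label curve")
    ax.plot(daily.dat, daily["mean"], color="tab:green", label="daily mean prediction")
    ax.fill_between(daily.dat, daily["min"], daily["max"], color="tab:green", alpha=0.2)
    ax.set_xlabel("days after transplanting")
    ax.set_ylabel("leaf area (cm$^2$/plant)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
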