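"""CSV / PNG / JSON artifact dialects shared by the pipeline stages.

Sensor streams: timestamp (ISO-8601), temp_c, rad_wm2, vwc, weight_kg,
valid (0/1). Ground truth: dat, fw_kg, shoot_dw_g, root_dw_g, la_cm2.
Daily aggregates: dat, mean_weight_kg, night_vwc, n_w, n_v. Images:
``cam_<DAT>_<HHMM>.png`` plus a manifest CSV mapping filename to dat and
timestamp.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .simulate.sensors import frame_to_records, records_to_frame
from .types import CanopyImage, SensorRecord


def write_sensor_csv(records: Sequence[SensorRecord], path):
    df = records_to_frame(records)
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def read_sensor_csv(path) -> List[SensorRecord]:
    return frame_to_records(pd.read_csv(path))


def write_truth_csv(truth, path):
    from .types import as_truth_frame

    as_truth_frame(truth).to_csv(path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_images(images: Sequence[CanopyImage], directory) -> pd.DataFrame:
    """Write frames as PNG and return (and save) the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        name = f"cam_{img.dat:03d}_{img.timestamp:%H%M}.png"
        Image.fromarray(img.pixels).save(directory / name)
        rows.append(
            {
                "filename": name,
                "dat": img.dat,
                "timestamp": img.timestamp.strftime("%Y-%m-%dT%H:%M:%S"),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def read_image(directory, filename, dat, timestamp) -> CanopyImage:
    px = np.asarray(Image.open(Path(directory) / filename).convert("RGB"))
    ts = pd.Timestamp(timestamp).to_pydatetime()
    return CanopyImage(pixels=px, timestamp=ts, dat=int(dat))


def load_images(directory, manifest: pd.DataFrame | None = None) -> List[CanopyImage]:
    directory = Path(directory)
    if manifest is None:
        manifest = pd.read_csv(directory / "manifest.csv")
    return [
        read_image(directory, r.filename, r.dat, r.timestamp)
        for r in manifest.itertuples()
    ]


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def read_json(path):
    return json.loads(Path(path).read_text())
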