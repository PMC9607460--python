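"""Synthetic top-view canopy camera.

Frames are a soil/gutter-coloured background with randomly placed green
ellipses standing in for leaves. The number of ellipses grows with leaf
area, so the green projected area is a monotone, saturating function of
leaf area (overlap increases as the canopy closes) — exactly the signal an
image-based leaf-area estimator is expected to exploit. Leaves are drawn
sequentially from a seeded generator, so for a fixed seed a larger leaf
area draws a superset of the smaller area's leaves and pixel-level
monotonicity holds by construction. No photorealism is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, time, timedelta
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ..errors import ParameterError
from ..types import CanopyImage, CropGroundTruth

BACKGROUND_RGB = (105, 92, 80)  # dry substrate / gutter grey-brown
LEAF_RGB = (40, 130, 45)


@dataclass(frozen=True)
class CameraSpec:
    """Virtual camera: sensor size, plants in view, optics of no interest.

    ``px_per_cm2`` converts leaf area to projected pixels; the default puts
    a closed canopy of 4 plants around 40% frame coverage at 1280x720.
    ``mean_leaf_cm2`` sets individual leaf ellipse size.
    """

    height: int = 720
    width: int = 1280
    n_plants: int = 4
    illumination: float = 1.0
    px_per_cm2: float = 18.0
    mean_leaf_cm2: float = 110.0

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ParameterError("camera height and width must be positive")


def render_canopy_image(
    leaf_area: float,
    camera: CameraSpec,
    seed: int,
    timestamp: Optional[datetime] = None,
    dat: int = 0,
) -> CanopyImage:
    """Render one frame for ``leaf_area`` cm^2 per plant.

    Deterministic given (leaf_area, camera, seed). ``camera.illumination``
    scales channel brightness, mimicking time-of-day light changes.
    """
    if leaf_area < 0:
        raise ParameterError("leaf_area must be >= 0")
    rng = np.random.default_rng(seed)
    H, W = camera.height, camera.width
    img = np.empty((H, W, 3), dtype=np.float32)
    base = np.array(BACKGROUND_RGB, dtype=np.float32)
    # mild background texture
    img[:] = base
    img += rng.normal(0.0, 6.0, size=(H, W, 1)).astype(np.float32)

    total_px = leaf_area * camera.n_plants * camera.px_per_cm2
    leaf_px = camera.mean_leaf_cm2 * camera.px_per_cm2
    n_leaves = int(np.ceil(total_px / leaf_px)) if total_px > 0 else 0

    yy = np.arange(H, dtype=np.float32)
    xx = np.arange(W, dtype=np.float32)
    leaf_rgb = np.array(LEAF_RGB, dtype=np.float32)
    for _ in range(n_leaves):
        cy = rng.uniform(0, H)
        cx = rng.uniform(0, W)
        area = leaf_px * rng.uniform(0.6, 1.4)
        aspect = rng.uniform(0.5, 1.0)
        a = np.sqrt(area / (np.pi * aspect))  # semi-major, px
        b = a * aspect
        theta = rng.uniform(0, np.pi)
        hue_jitter = rng.normal(0.0, 10.0, size=3)
        y0, y1 = int(max(0, cy - a - 1)), int(min(H, cy + a + 2))
        x0, x1 = int(max(0, cx - a - 1)), int(min(W, cx + a + 2))
        if y1 <= y0 or x1 <= x0:
            continue
        dy = yy[y0:y1, None] - cy
        dx = xx[None, x0:x1] - cx
        ct, st = np.cos(theta), np.sin(theta)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        patch = img[y0:y1, x0:x1]
        patch[mask] = leaf_rgb + hue_jitter

    img *= camera.illumination
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    if timestamp is None:
        timestamp = datetime(2020, 1, 1, 12, 0)
    return CanopyImage(pixels=pixels, timestamp=timestamp, dat=dat)


def green_fraction(image: CanopyImage | np.ndarray) -> float:
    """Fraction of pixels classified as vegetation (green channel dominant
    by a margin that the background never reaches)."""
    px = image.pixels if isinstance(image, CanopyImage) else image
    px = px.astype(np.int16)
    g = (px[..., 1] > px[..., 0] + 10) & (px[..., 1] > px[..., 2] + 10)
    return float(g.mean())


def simulate_camera_day(
    truth_day: CropGroundTruth,
    camera: CameraSpec,
    date: datetime,
    seed: int,
    capture_times: Sequence[time] = (),
    illumination_jitter: float = 0.15,
) -> List[CanopyImage]:
    """All frames of one day at the given capture clock times.

    Per-frame illumination varies around ``camera.illumination`` with a
    seeded lognormal factor of coefficient of variation
    ``illumination_jitter`` (light changes through the day).
    """
    rng = np.random.default_rng(seed)
    out = []
    sigma = np.sqrt(np.log1p(illumination_jitter**2))
    for t in capture_times:
        illum = camera.illumination * float(
            np.exp(rng.normal(-0.5 * sigma**2, sigma))
        )
        cam = CameraSpec(
            height=camera.height,
            width=camera.width,
            n_plants=camera.n_plants,
            illumination=illum,
            px_per_cm2=camera.px_per_cm2,
            mean_leaf_cm2=camera.mean_leaf_cm2,
        )
        ts = datetime.combine(date.date(), t)
        out.append(
            render_canopy_image(
                truth_day.leaf_area,
                cam,
                seed=int(rng.integers(0, 2**31 - 1)),
                timestamp=ts,
                dat=truth_day.dat,
            )
        )
    return out


def default_capture_times(
    start_hour: int = 8, end_hour: int = 16, per_day: int = 5
) -> List[time]:
    """Evenly spaced capture clock times inside the daylight window."""
    hours = np.linspace(start_hour, end_hour, per_day)
    return [time(int(h), int(round((h % 1) * 60)) % 60) for h in hours]
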