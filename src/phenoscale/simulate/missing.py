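"""Injection of wireless-upload data losses into a sensor stream.

Real streams lose short contiguous runs of records; the injector marks
non-overlapping runs invalid until the requested fraction of the stream is
missing. The first and last records are never invalidated so that linear
interpolation is always bounded by valid neighbours.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from ..errors import ParameterError
from ..types import SensorRecord


def inject_missing(
    records: Sequence[SensorRecord],
    gap_rate: float,
    max_gap_len: int = 6,
    seed: int = 0,
) -> List[SensorRecord]:
    """Return a copy of ``records`` with ~``gap_rate`` of them flagged
    invalid, in contiguous runs of length <= ``max_gap_len``.

    The invalid count is exactly round(gap_rate * n) whenever enough
    non-overlapping interior slots exist. Deterministic given seed.
    """
    if not (0.0 <= gap_rate < 0.5):
        raise ParameterError("gap_rate must be in [0, 0.5)")
    if max_gap_len < 1:
        raise ParameterError("max_gap_len must be >= 1")
    n = len(records)
    out = [
        SensorRecord(
            timestamp=r.timestamp,
            air_temperature=r.air_temperature,
            solar_radiation=r.solar_radiation,
            vwc=r.vwc,
            system_weight=r.system_weight,
            valid=r.valid,
        )
        for r in records
    ]
    target = int(round(gap_rate * n))
    if target == 0 or n < 3:
        return out

    rng = np.random.default_rng(seed)
    invalid = np.zeros(n, dtype=bool)
    made = 0
    attempts = 0
    while made < target and attempts < 50 * n:
        attempts += 1
        length = min(int(rng.integers(1, max_gap_len + 1)), target - made)
        start = int(rng.integers(1, n - length))  # indices 1 .. n-2 inclusive
        # one-cell buffer keeps runs from merging past max_gap_len
        if invalid[max(0, start - 1) : start + length + 1].any():
            continue
        invalid[start : start + length] = True
        made += length
    for i in np.nonzero(invalid)[0]:
        out[i].valid = False
    return out
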