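"""Shared evaluation metrics.

Every module scores estimates the same way: coefficient of determination
R^2 = 1 - SS_res / SS_tot, root mean square error, and mean absolute error.
This is the single implementation the whole package uses.
"""

from __future__ import annotations

import numpy as np

from .errors import EvaluationError


def compute_metrics(pred, ref) -> dict:
    """R^2, RMSE and MAE of ``pred`` against reference ``ref``.

    Both sequences must have equal length >= 2. A constant reference makes
    SS_tot zero; R^2 is then 1.0 for a perfect fit and -inf otherwise.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise EvaluationError(
            f"length mismatch: {pred.shape} predictions vs {ref.shape} references"
        )
    if pred.size < 2:
        raise EvaluationError("need at least 2 points to compute metrics")
    resid = pred - ref
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else float("-inf")
    else:
        r2 = 1.0 - ss_res / ss_tot
    return {
        "r2": r2,
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "mae": float(np.mean(np.abs(resid))),
    }
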