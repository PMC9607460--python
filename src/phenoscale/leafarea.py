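"""Sigmoidal leaf-area-vs-DAT regression for daily label generation.

Destructive leaf-area measurements are sparse (a handful of sampling days
per season), but the image model needs one label per day. A four-parameter
growth curve bridges the gap:

    leaf_area(DAT) = L / (1 + exp(-k (DAT - x0))) + b

with asymptote ``L`` (cm^2 per plant), rate ``k`` (day^-1), midpoint ``x0``
(DAT) and baseline ``b`` (cm^2). The fit is nonlinear least squares with
multi-start initialisation, followed by a single round of outlier
elimination (absolute standardized residual above a threshold) and a refit.
A monotone-decaying variant ``L * exp(-k (DAT + x0) - b)`` is available as
``form="decay"`` for comparison; it cannot describe sigmoidal growth and is
not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, ParameterError
from .metrics import compute_metrics
from .types import LabelTable, SigmoidCoefficients


def logistic_curve(dat, L, k, x0, b):
    return L / (1.0 + np.exp(-k * (np.asarray(dat, dtype=float) - x0))) + b


def decay_curve(dat, L, k, x0, b):
    return L / np.exp(k * (np.asarray(dat, dtype=float) + x0) + b)


_FORMS = {"logistic": logistic_curve, "decay": decay_curve}


def predict_leaf_area(coeffs: SigmoidCoefficients, dat, form: str = "logistic"):
    """Evaluate the fitted growth curve at ``dat`` (scalar or array)."""
    f = _FORMS[form]
    out = f(dat, coeffs.L, coeffs.k, coeffs.x0, coeffs.b)
    return float(out) if np.isscalar(dat) else out


def make_label_table(
    coeffs: SigmoidCoefficients, dats: Sequence[int], form: str = "logistic"
) -> LabelTable:
    """One label per DAT over the given range; images taken on the same
    date all receive the day's label."""
    dats = np.asarray(list(dats), dtype=int)
    if len(dats) == 0:
        raise ParameterError("label DAT range is empty")
    return LabelTable(dat=dats, leaf_area_label=predict_leaf_area(coeffs, dats, form))


class SigmoidGrowthModel:
    """Growth-curve model for sparse (DAT, leaf area) samples.

    Parameters
    ----------
    dat, leaf_area : array-like
        Sampling day and measured leaf area (cm^2 per plant), >= 5 samples
        spanning >= 3 distinct days.
    form : {"logistic", "decay"}
        Curve family; the logistic is the primary, sigmoidal form.

    ``fit()`` returns a :class:`SigmoidGrowthResults`.
    """

    def __init__(self, dat, leaf_area, form: str = "logistic"):
        self.dat = np.asarray(dat, dtype=float)
        self.leaf_area = np.asarray(leaf_area, dtype=float)
        if form not in _FORMS:
            raise ParameterError(f"unknown form {form!r}")
        self.form = form
        if len(self.dat) != len(self.leaf_area):
            raise ParameterError("dat and leaf_area must have equal length")
        if len(self.dat) < 5 or len(np.unique(self.dat)) < 3:
            raise ParameterError("need >= 5 samples spanning >= 3 distinct DATs")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, dat_col="dat", value_col="leaf_area_cm2", form="logistic"
    ) -> "SigmoidGrowthModel":
        return cls(df[dat_col].to_numpy(), df[value_col].to_numpy(), form=form)

    # -- fitting ---------------------------------------------------------
    def _starts(self, init: Optional[SigmoidCoefficients]):
        if init is not None:
            yield (init.L, init.k, init.x0, init.b)
        y = self.leaf_area
        x = self.dat
        L0 = max(y.max() - y.min(), 1e-6)
        b0 = max(y.min(), 0.0)
        x0_candidates = [np.median(x), x.min() + 0.5 * (x.max() - x.min())]
        span = max(x.max() - x.min(), 1.0)
        for k0 in (4.0 / span, 8.0 / span, 16.0 / span, 1.0 / span):
            for x00 in x0_candidates:
                yield (L0, k0, x00, b0)

    def _fit_once(self, x, y, start):
        popt, _ = curve_fit(
            _FORMS[self.form],
            x,
            y,
            p0=start,
            maxfev=20000,
            bounds=([1e-9, 1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf, np.inf]),
        )
        resid = y - _FORMS[self.form](x, *popt)
        return popt, float(np.sum(resid**2))

    def _best_fit(self, x, y, init):
        best = None
        tried = []
        for start in self._starts(init):
            tried.append(start)
            try:
                popt, ss = self._fit_once(x, y, start)
            except RuntimeError:
                continue
            if best is None or ss < best[1]:
                best = (popt, ss)
        if best is None:
            raise FitError(
                f"growth-curve fit failed from all {len(tried)} starts", starts=tried
            )
        return best[0]

    def fit(
        self, init: Optional[SigmoidCoefficients] = None, outlier_sd: float = 2.5
    ) -> "SigmoidGrowthResults":
        """Least-squares fit, one outlier-elimination pass, refit.

        A sample is an outlier when its absolute standardized residual
        (residual / residual SD of the first fit) exceeds ``outlier_sd``.
        """
        x, y = self.dat, self.leaf_area
        popt = self._best_fit(x, y, init)
        resid = y - _FORMS[self.form](x, *popt)
        sd = resid.std(ddof=1)
        # an essentially exact fit has no outliers, only float dust
        if sd > 1e-8 * max(np.abs(y).max(), 1.0):
            keep = np.abs(resid / sd) <= outlier_sd
        else:
            keep = np.ones_like(resid, dtype=bool)
        n_out = int((~keep).sum())
        if n_out and keep.sum() >= 5:
            start = SigmoidCoefficients(*popt) if popt[0] > 0 and popt[1] > 0 else None
            popt = self._best_fit(x[keep], y[keep], start)
        else:
            keep = np.ones_like(resid, dtype=bool)
            n_out = 0
        coeffs = SigmoidCoefficients(L=popt[0], k=popt[1], x0=popt[2], b=popt[3])
        fitted = _FORMS[self.form](x[keep], *popt)
        r2 = compute_metrics(fitted, y[keep])["r2"]
        return SigmoidGrowthResults(
            model=self, coeffs=coeffs, retained=keep, n_outliers=n_out, r2=r2
        )


@dataclass
class SigmoidGrowthResults:
    """Fitted growth curve: coefficients, retained-sample mask and R^2."""

    model: SigmoidGrowthModel
    coeffs: SigmoidCoefficients
    retained: np.ndarray
    n_outliers: int
    r2: float

    def predict(self, dat):
        return predict_leaf_area(self.coeffs, dat, form=self.model.form)

    @property
    def resid(self) -> np.ndarray:
        """Residuals on retained samples, in fit order."""
        m = self.model
        return m.leaf_area[self.retained] - self.predict(m.dat[self.retained])

    def label_table(self, dats: Sequence[int]) -> LabelTable:
        return make_label_table(self.coeffs, dats, form=self.model.form)

    def summary(self) -> str:
        c = self.coeffs
        lines = [
            "Leaf-area growth curve (nonlinear least squares)",
            f"  form:        {self.model.form}",
            f"  L (cm^2):    {c.L:12.3f}",
            f"  k (1/day):   {c.k:12.5f}",
            f"  x0 (DAT):    {c.x0:12.3f}",
            f"  b (cm^2):    {c.b:12.3f}",
            f"  n retained:  {int(self.retained.sum())} of {len(self.retained)}"
            f" ({self.n_outliers} outliers removed)",
            f"  R^2:         {self.r2:12.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        c = self.coeffs
        return {
            "L": c.L,
            "k": c.k,
            "x0": c.x0,
            "b": c.b,
            "r2": self.r2,
            "n_retained": int(self.retained.sum()),
        }
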