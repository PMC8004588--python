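"""Goodness-of-fit battery for retention-index models.

Conventions: errors are e = pred - obs.  The mean bias error (MBE) keeps
the sign, so systematic under-prediction is negative; the mean percentage
error (MPE) uses absolute relative errors and is therefore non-negative.
The reduced chi-square divides the error sum of squares by N - n_params
with n_params defaulting to the number of descriptors in the model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["FitMetrics", "goodness_of_fit", "metrics_frame"]


@dataclass(frozen=True)
class FitMetrics:
    """Fit statistics in retention-index units (except r2 and MPE)."""

    chi2: float
    rmse: float
    mbe: float
    mpe: float
    r2: float
    n: int
    n_params: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def goodness_of_fit(
    obs: Sequence[float], pred: Sequence[float], n_params: int = 7
) -> FitMetrics:
    """Compute chi2 (reduced), RMSE, MBE, MPE and r2 for predictions.

    * rmse = sqrt(sum(e^2) / N)
    * mbe  = sum(e) / N                       (signed)
    * mpe  = (100 / N) * sum(|e| / obs)       (obs must be positive)
    * chi2 = sum(e^2) / (N - n_params)
    * r2   = squared Pearson correlation of obs and pred
    """
    o = np.asarray(obs, dtype=float).ravel()
    p = np.asarray(pred, dtype=float).ravel()
    if o.shape != p.shape:
        raise ValueError("obs and pred must have equal length")
    n = o.size
    if n < 2:
        raise ValueError("need at least two observations")
    if n <= n_params:
        raise ValueError(f"N={n} must exceed n_params={n_params}")
    if np.any(o <= 0):
        raise ValueError("observations must be strictly positive (MPE divides by obs)")
    e = p - o
    rmse = float(np.sqrt((e ** 2).sum() / n))
    mbe = float(e.sum() / n)
    mpe = float(100.0 / n * (np.abs(e) / o).sum())
    chi2 = float((e ** 2).sum() / (n - n_params))
    if o.std() == 0 or p.std() == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(o, p)[0, 1] ** 2)
    return FitMetrics(chi2=chi2, rmse=rmse, mbe=mbe, mpe=mpe, r2=r2,
                      n=n, n_params=n_params)


def metrics_frame(per_model: Mapping[str, FitMetrics]) -> pd.DataFrame:
    """Arrange metrics for several models as one row per model with columns
    chi2, rmse, mbe, mpe, r2 (the usual report layout)."""
    rows = {
        name: {"chi2": m.chi2, "rmse": m.rmse, "mbe": m.mbe,
               "mpe": m.mpe, "r2": m.r2}
        for name, m in per_model.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "model"
    return df
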