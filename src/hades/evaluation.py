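"""Accuracy metrics shared by the simulator evaluation and the ML layer.

Five metrics are reported throughout: mean absolute error (MAE, response
units), relative root-mean-square error (RRMSE, % of the observed mean),
coefficient of determination (R², squared Pearson correlation),
Nash–Sutcliffe model efficiency (EF) and coefficient of residual mass
(CRM). Sign convention: CRM = (Σobs − Σpred)/Σobs, so a *negative* CRM
indicates systematic overestimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MetricSet", "metrics"]


@dataclass(frozen=True)
class MetricSet:
    """The five accuracy metrics for one (obs, pred) comparison.

    ``r2`` and ``ef`` are NaN when the observations have zero variance
    (both are undefined against a constant reference); ``degenerate``
    flags that case.
    """

    mae: float
    rrmse: float
    r2: float
    ef: float
    crm: float
    n: int
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "mae": self.mae,
            "rrmse": self.rrmse,
            "r2": self.r2,
            "ef": self.ef,
            "crm": self.crm,
            "n": self.n,
        }


def metrics(obs, pred) -> MetricSet:
    """Compute MAE, RRMSE (%), R², EF and CRM for paired series.

    Parameters
    ----------
    obs, pred : array-like
        Observed and predicted values, equal non-zero length. ``mean(obs)``
        must be positive for RRMSE and CRM to be meaningful.

    Notes
    -----
    * RRMSE = 100 · RMSE / mean(obs).
    * EF = 1 − Σ(obs−pred)² / Σ(obs−mean(obs))²; EF = 0 for the
      mean-of-observations predictor, EF = 1 for a perfect fit.
    * CRM = (Σobs − Σpred)/Σobs; CRM < 0 ⇔ Σpred > Σobs (overestimation).
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.ndim != 1 or obs.shape != pred.shape or obs.size == 0:
        raise ValueError("obs and pred must be equal-length non-empty 1-D arrays")
    n = obs.size
    resid = pred - obs
    mae = float(np.mean(np.abs(resid)))
    obs_mean = float(np.mean(obs))
    if obs_mean <= 0:
        raise ValueError("mean(obs) must be positive for RRMSE and CRM")
    rrmse = 100.0 * math.sqrt(float(np.mean(resid**2))) / obs_mean
    crm = float((obs.sum() - pred.sum()) / obs.sum())

    ss_obs = float(np.sum((obs - obs_mean) ** 2))
    degenerate = ss_obs == 0.0
    if degenerate:
        ef = math.nan
        r2 = math.nan
    else:
        ef = 1.0 - float(np.sum(resid**2)) / ss_obs
        pred_sd = float(np.std(pred))
        if pred_sd == 0.0:
            # constant predictions: correlation undefined; R² reported as 0
            # unless the fit is exact (then resid is 0 and ef == 1).
            r2 = 1.0 if np.allclose(pred, obs) else 0.0
        else:
            r = float(np.corrcoef(obs, pred)[0, 1])
            r2 = r * r
    # exact fit: avoid -0.0 / rounding artifacts in the reported values
    if np.array_equal(obs, pred):
        mae, rrmse, crm = 0.0, 0.0, 0.0
        if not degenerate:
            r2, ef = 1.0, 1.0
    return MetricSet(mae=mae, rrmse=rrmse, r2=r2, ef=ef, crm=crm, n=n,
                     degenerate=degenerate)
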