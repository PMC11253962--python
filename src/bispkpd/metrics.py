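"""Fit-quality metrics: coefficient of determination, RMSE, MAPE.

R^2 = 1 - SSE/SST may be negative for fits worse than the mean predictor;
the raw value is reported without clipping.  MAPE is reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedMetricError, ValidationError

__all__ = ["EvalReport", "r_squared", "rmse", "mape", "evaluate"]


def _as_pair(observed, predicted, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size != pred.size:
        raise ValidationError(
            f"observed and predicted differ in length ({obs.size} vs {pred.size})"
        )
    if obs.size < min_n:
        raise ValidationError(f"need at least {min_n} samples, got {obs.size}")
    return obs, pred


@dataclass(frozen=True)
class EvalReport:
    """R^2 (fraction, unclipped), RMSE (target units), MAPE (percent), n."""

    r2: float
    rmse: float
    mape: float
    n: int

    def to_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "rmse": self.rmse, "mape": self.mape, "n": self.n}


def r_squared(observed, predicted) -> float:
    """1 - SSE/SST.  Undefined (raises) when the observations are constant."""
    obs, pred = _as_pair(observed, predicted, min_n=2)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedMetricError("R^2 undefined: observed values are constant (SST = 0)")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def rmse(observed, predicted) -> float:
    """Root of the mean squared residual."""
    obs, pred = _as_pair(observed, predicted, min_n=1)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def mape(observed, predicted) -> float:
    """Mean absolute percentage error, mean(|obs - pred| / |obs|) * 100.

    Raises for any zero observation rather than silently regularizing.
    """
    obs, pred = _as_pair(observed, predicted, min_n=1)
    if np.any(obs == 0):
        raise UndefinedMetricError("MAPE undefined: observed contains zeros")
    return float(np.mean(np.abs((obs - pred) / obs)) * 100.0)


def evaluate(observed, predicted) -> EvalReport:
    """All three metrics in one report."""
    obs, pred = _as_pair(observed, predicted, min_n=2)
    return EvalReport(
        r2=r_squared(obs, pred),
        rmse=rmse(obs, pred),
        mape=mape(obs, pred),
        n=int(obs.size),
    )
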