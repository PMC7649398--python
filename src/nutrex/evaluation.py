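"""Model scoring (MAE, RMSE, R², MSE decomposition) and effective sample sizes.

Prediction error against the measurement-derived reference is summarised by

    MAE  = mean |actual − predicted|
    RMSE = sqrt(mean (actual − predicted)²)

both also expressed relative to the mean actual value, plus the regression
of predicted on actual (R², residual SE, tests of intercept = 0 and
slope = 1). The MSE is partitioned into translation (bias), rotation
(slope) and scatter (random) components:

    MSE = (p̄ − ā)² + (s_p − r·s_a)² + (1 − r²)·s_a²

an exact identity when s are population (1/n) standard deviations, so the
three shares sum to one.

Effective sample size follows the two-arm Cohen formula n = 2δ²/d² with
δ the sum of the one-sided normal quantiles z₁₋α + z₁₋β and d the
standardized difference Δ/σ. A model of reliability ρ (its R² against the
error-free measurement) attenuates the observable effect, d' = d·√ρ, so the
required n inflates by 1/ρ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats


@dataclass
class EvaluationMetrics:
    """Scores of predicted vs actual faecal N (g/animal/d unless noted)."""

    n: int
    mae: float
    rmse: float
    mae_rel: float
    rmse_rel: float
    r2: float
    residual_se: float
    intercept: float
    slope: float
    p_intercept_vs_0: float
    p_slope_vs_1: float
    mse_bias_share: float
    mse_slope_share: float
    mse_random_share: float


def mse_decomposition(pred: Sequence[float], act: Sequence[float],
                      ) -> tuple[float, float, float]:
    """Shares of MSE due to bias, slope and random scatter (sum to 1).

    Uses population (1/n) variances so the three components add up to the
    MSE exactly. Conventions for degenerate inputs: a zero MSE, or zero
    variance on both sides, reports (0, 0, 1); a zero variance on one side
    sets the correlation to 0 in the closed forms.
    """
    p = np.asarray(pred, dtype=float)
    a = np.asarray(act, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise ValueError("pred and act must be 1-d arrays of equal length")
    mse = float(np.mean((a - p) ** 2))
    if mse == 0.0:
        return 0.0, 0.0, 1.0
    sp = float(np.std(p))
    sa = float(np.std(a))
    r = float(np.corrcoef(p, a)[0, 1]) if sp > 0 and sa > 0 else 0.0
    bias = (float(np.mean(p)) - float(np.mean(a))) ** 2
    slope = (sp - r * sa) ** 2
    random = (1.0 - r ** 2) * sa ** 2
    total = bias + slope + random
    return bias / total, slope / total, random / total


def evaluate(pred: Sequence[float], act: Sequence[float]) -> EvaluationMetrics:
    """Score predictions against actual values (n ≥ 3, equal lengths)."""
    p = np.asarray(pred, dtype=float)
    a = np.asarray(act, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise ValueError("pred and act must be 1-d arrays of equal length")
    n = p.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")

    resid = a - p
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mean_act = float(np.mean(a))
    mae_rel = mae / mean_act if mean_act != 0 else math.nan
    rmse_rel = rmse / mean_act if mean_act != 0 else math.nan

    # regression of predicted on actual
    if np.var(a) == 0:
        slope, intercept = 0.0, float(np.mean(p))
        r2 = 0.0
        residual_se = float(np.std(p, ddof=1))
        p_int, p_slope = math.nan, math.nan
    else:
        res = stats.linregress(a, p)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue ** 2)
        fitted = intercept + slope * a
        dof = n - 2
        residual_se = float(np.sqrt(np.sum((p - fitted) ** 2) / dof)) if dof else 0.0
        if res.stderr and res.intercept_stderr:
            p_int = 2 * stats.t.sf(abs(intercept / res.intercept_stderr), dof)
            p_slope = 2 * stats.t.sf(abs((slope - 1.0) / res.stderr), dof)
        else:  # perfect fit: zero standard errors
            p_int = 0.0 if intercept != 0 else 1.0
            p_slope = 0.0 if slope != 1.0 else 1.0

    bias_s, slope_s, random_s = mse_decomposition(p, a)
    return EvaluationMetrics(
        n=n, mae=mae, rmse=rmse, mae_rel=mae_rel, rmse_rel=rmse_rel,
        r2=r2, residual_se=residual_se,
        intercept=intercept, slope=slope,
        p_intercept_vs_0=float(p_int), p_slope_vs_1=float(p_slope),
        mse_bias_share=bias_s, mse_slope_share=slope_s,
        mse_random_share=random_s,
    )


class SampleSizeSpec(BaseModel):
    """Design inputs for the effective-sample-size calculation.

    sigma is the population SD of faecal N (g/animal/d) — it must come from
    the user or a pilot study. reliability is the R² of the measurement
    model against the error-free endpoint (1 for a direct measurement).
    """

    model_config = ConfigDict(frozen=True)

    alpha: float = Field(default=0.05, gt=0, lt=1, description="type-I, one-tailed")
    beta: float = Field(default=0.20, gt=0, lt=1, description="type-II")
    sigma: float = Field(gt=0, description="population SD, g/animal/d")
    reliability: float = Field(default=1.0, gt=0, le=1)
    delta_grid: tuple[float, ...] = tuple(float(d) for d in range(1, 31))


def effective_sample_size_raw(spec: SampleSizeSpec, delta: float,
                              reliability: Optional[float] = None,
                              quantiles: str = "normal") -> float:
    """Pre-ceiling n = 2δ²/d'², d' = (Δ/σ)·√ρ.

    ``quantiles="normal"`` (default) uses z quantiles; ``"t"`` iterates the
    central-t quantiles at df = 2n − 2 to a fixed point.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    rho = spec.reliability if reliability is None else reliability
    d = delta / spec.sigma * math.sqrt(rho)
    crit = stats.norm.ppf(1 - spec.alpha) + stats.norm.ppf(1 - spec.beta)
    n = 2.0 * crit ** 2 / d ** 2
    if quantiles == "t":
        for _ in range(50):
            df = max(2.0 * n - 2.0, 1.0)
            crit = stats.t.ppf(1 - spec.alpha, df) + stats.t.ppf(1 - spec.beta, df)
            n_new = 2.0 * crit ** 2 / d ** 2
            if abs(n_new - n) < 1e-9:
                n = n_new
                break
            n = n_new
    elif quantiles != "normal":
        raise ValueError(f"unknown quantile family {quantiles!r}")
    return n


def effective_sample_size(spec: SampleSizeSpec, delta: float,
                          reliability: Optional[float] = None,
                          quantiles: str = "normal") -> int:
    """Animals per arm needed to detect Δ, rounded up (whole animals only)."""
    n = effective_sample_size_raw(spec, delta, reliability, quantiles)
    return math.ceil(n - 1e-9)


def sample_size_curve(spec: SampleSizeSpec, quantiles: str = "normal") -> pd.DataFrame:
    """Required n over the Δ grid, for a direct measurement (ρ = 1) and for
    the model at ``spec.reliability``. Columns: delta, n_actual, n_predicted."""
    if not spec.delta_grid:
        raise ValueError("delta_grid must be non-empty")
    rows = [
        {
            "delta": d,
            "n_actual": effective_sample_size(spec, d, reliability=1.0,
                                              quantiles=quantiles),
            "n_predicted": effective_sample_size(spec, d, quantiles=quantiles),
        }
        for d in spec.delta_grid
    ]
    return pd.DataFrame(rows)
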