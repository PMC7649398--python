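"""Faecal-N prediction via the Lucas relation, nutrient balances, herd summaries.

The Lucas equation states that the digestible N concentration of a diet is
an affine function of its total N concentration, DN = m·TN + b, with slope
m the true digestibility of dietary protein and intercept b the (negative)
metabolic faecal N per 100 g of DM intake. Multiplying through by DMI and
subtracting from intake gives the predicted faecal N quantity

    Q_FN = (1 − m)·TNI − b·DMI/100      (g/animal/d)

Urinary N closes the N balance (Q_UN = TNI − N_Ret − Q_FN) and faecal P
closes the P balance (Q_FP = PI − P_Ret; urinary P is negligible).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .intake import IntakeProfile, actual_faecal_n, derive_intake
from .model_io import AnimalClass, CowRecord, DesignConstants, DEFAULT_CONSTANTS, FeedComposition
from .retention import GrowthTrace, NRetention, PRetention, retention_for_cow

logger = logging.getLogger("nutrex")


class LucasParams(BaseModel):
    """Lucas-relation parameters: true digestibility m, metabolic faecal N b.

    b is in g N per 100 g DMI and is negative by convention (endogenous N
    adds to faecal output). A fitted b > 0 or m > 1 is physically
    implausible and triggers a warning rather than a hard error, since noisy
    survey data can legitimately produce such estimates.
    """

    model_config = ConfigDict(frozen=True)

    m: float
    b: float

    @model_validator(mode="after")
    def _plausible(self) -> "LucasParams":
        if self.m <= 0:
            raise ValueError(f"true digestibility m must be positive, got {self.m}")
        if self.m > 1:
            warnings.warn(f"true digestibility m={self.m:.3f} exceeds 1",
                          stacklevel=2)
        if self.b > 0:
            warnings.warn(
                f"metabolic faecal N intercept b={self.b:.3f} is positive; "
                "expected <= 0", stacklevel=2)
        return self


#: Parameters calibrated on the Indonesian smallholder survey.
CALIBRATED_PARAMS = LucasParams(m=0.92, b=-0.60)
#: The long-standing literature values for the Lucas N relation.
LITERATURE_PARAMS = LucasParams(m=0.92, b=-0.61)

PARAM_PRESETS = {"calibrated": CALIBRATED_PARAMS, "literature": LITERATURE_PARAMS}


@dataclass
class ExcretionResult:
    """Daily excretion budget for one animal (g/animal/d)."""

    q_fn: float
    q_un: float
    q_tn: float
    q_fp: float
    n_ret: NRetention
    p_ret: PRetention
    growth_trace: Optional[GrowthTrace] = None
    flags: list[str] = field(default_factory=list)


@dataclass
class CowPrediction:
    """Bundle of one cow with its intake profile and excretion result."""

    cow: CowRecord
    intake: IntakeProfile
    excretion: ExcretionResult


def predict_faecal_n(tni: float, dmi: float,
                     params: LucasParams = CALIBRATED_PARAMS) -> float:
    """Predicted faecal N quantity, g/d: (1−m)·TNI − b·(DMI/100)."""
    if tni < 0 or dmi < 0:
        raise ValueError("TNI and DMI must be >= 0")
    return (1.0 - params.m) * tni - params.b * (dmi / 100.0)


def nitrogen_balance(tni: float, n_ret: NRetention, q_fn: float,
                     ) -> tuple[float, float, list[str]]:
    """Close the N balance: Q_UN = TNI − N_Ret − Q_FN, Q_TN = Q_FN + Q_UN.

    A negative urinary residual (possible with measurement error) is clamped
    to zero and flagged, never silently propagated into summaries.
    """
    if tni < 0 or q_fn < 0:
        raise ValueError("TNI and Q_FN must be >= 0")
    flags: list[str] = []
    q_un = tni - n_ret.total - q_fn
    if q_un < 0:
        flags.append(f"urinary N clamped to 0 (balance residual {q_un:.2f} g/d)")
        q_un = 0.0
    return q_un, q_fn + q_un, flags


def phosphorus_balance(pi: float, p_ret: PRetention) -> tuple[float, list[str]]:
    """Close the P balance: Q_FP = PI − P_Ret, clamped at zero with a flag."""
    if pi < 0:
        raise ValueError("PI must be >= 0")
    flags: list[str] = []
    q_fp = pi - p_ret.total
    if q_fp < 0:
        flags.append(f"faecal P clamped to 0 (balance residual {q_fp:.2f} g/d)")
        q_fp = 0.0
    return q_fp, flags


def predict_cow(cow: CowRecord, feeds: dict[str, FeedComposition],
                params: LucasParams = CALIBRATED_PARAMS,
                constants: DesignConstants = DEFAULT_CONSTANTS) -> CowPrediction:
    """Full per-animal prediction: intake → retention → excretion budget."""
    profile = derive_intake(cow, feeds)
    if cow.faecal_n is not None:
        actual_faecal_n(profile, cow.faecal_n)
    n_ret, p_ret, trace, flags = retention_for_cow(cow, constants)
    q_fn = predict_faecal_n(profile.tni, profile.dmi, params)
    q_un, q_tn, n_flags = nitrogen_balance(profile.tni, n_ret, q_fn)
    q_fp, p_flags = phosphorus_balance(profile.pi, p_ret)
    result = ExcretionResult(
        q_fn=q_fn, q_un=q_un, q_tn=q_tn, q_fp=q_fp,
        n_ret=n_ret, p_ret=p_ret, growth_trace=trace,
        flags=flags + n_flags + p_flags,
    )
    return CowPrediction(cow=cow, intake=profile, excretion=result)


def predict_herd(cows: Iterable[CowRecord], feeds: dict[str, FeedComposition],
                 params: LucasParams = CALIBRATED_PARAMS,
                 constants: DesignConstants = DEFAULT_CONSTANTS,
                 ) -> list[CowPrediction]:
    return [predict_cow(cow, feeds, params, constants) for cow in cows]


# ---------------------------------------------------------------------------
# herd summary
# ---------------------------------------------------------------------------

_SUMMARY_FIELDS = [
    "dmi", "tni", "pi", "q_fn_act", "q_fn", "q_un", "q_tn", "n_ret",
    "q_fp", "p_ret",
]


def results_frame(predictions: Iterable[CowPrediction]) -> pd.DataFrame:
    """One row per cow with intake, retention and excretion quantities."""
    rows = []
    for p in predictions:
        r, i = p.excretion, p.intake
        rows.append({
            "cow_id": p.cow.cow_id,
            "farm_id": p.cow.farm_id,
            "animal_class": p.cow.animal_class.value,
            "dmi": i.dmi, "ddmi": i.ddmi, "idmi": i.idmi,
            "cpi": i.cpi, "tni": i.tni, "pi": i.pi,
            "q_fn_act": np.nan if i.q_fn_act is None else i.q_fn_act,
            "q_fn": r.q_fn, "q_un": r.q_un, "q_tn": r.q_tn, "q_fp": r.q_fp,
            "n_ret": r.n_ret.total,
            "n_milk": r.n_ret.n_milk, "n_preg": r.n_ret.n_preg,
            "n_growth": r.n_ret.n_growth, "n_scurf": r.n_ret.n_scurf,
            "p_ret": r.p_ret.total,
            "p_milk": r.p_ret.p_milk, "p_preg": r.p_ret.p_preg,
            "p_growth": r.p_ret.p_growth,
            "flags": "; ".join(r.flags),
        })
    return pd.DataFrame(rows)


@dataclass
class HerdSummary:
    """Class-level and herd-level means ± SE plus intake-fraction shares.

    Intake fractions are ratios of herd means (herd totals), not means of
    per-cow ratios, so that N_Ret + Q_FN + Q_UN shares of TNI sum to one
    before rounding whenever no cow was clamped.
    """

    class_means: pd.DataFrame
    class_se: pd.DataFrame
    overall_mean: pd.Series
    overall_se: pd.Series
    counts: dict[str, int]
    fraction_n_retained: float
    fraction_n_faeces: float
    fraction_n_urine: float
    fraction_p_retained: float
    fraction_p_faeces: float

    @property
    def herd_size(self) -> int:
        return sum(self.counts.values())


def summarize_herd(predictions: list[CowPrediction]) -> HerdSummary:
    """Aggregate per-cow predictions to class and herd level.

    SE is SD/√n with the sample (n−1) SD; single-animal classes report SE 0.
    Overall means weight each animal equally (i.e. class means weighted by
    class counts).
    """
    if not predictions:
        raise ValueError("cannot summarise an empty herd")
    df = results_frame(predictions)
    num = df[_SUMMARY_FIELDS]

    def se(group: pd.DataFrame) -> pd.Series:
        n = len(group)
        if n < 2:
            return pd.Series(0.0, index=group.columns)
        return group.std(ddof=1) / np.sqrt(n)

    grouped = num.groupby(df["animal_class"])
    class_means = grouped.mean()
    class_se = grouped.apply(se)
    counts = df["animal_class"].value_counts().to_dict()

    overall_mean = num.mean()
    overall_se = se(num)

    mean_tni = overall_mean["tni"]
    mean_pi = overall_mean["pi"]
    if mean_tni <= 0 or mean_pi <= 0:
        raise ValueError("herd mean TNI and PI must be positive to form fractions")
    return HerdSummary(
        class_means=class_means,
        class_se=class_se,
        overall_mean=overall_mean,
        overall_se=overall_se,
        counts=counts,
        fraction_n_retained=overall_mean["n_ret"] / mean_tni,
        fraction_n_faeces=overall_mean["q_fn"] / mean_tni,
        fraction_n_urine=overall_mean["q_un"] / mean_tni,
        fraction_p_retained=overall_mean["p_ret"] / mean_pi,
        fraction_p_faeces=overall_mean["q_fp"] / mean_pi,
    )


def write_report(predictions: list[CowPrediction], out_dir: str | Path) -> HerdSummary:
    """Write the per-cow table and the herd summary under ``out_dir``.

    ``report.csv`` keeps full precision; ``summary.csv`` rounds the
    g/animal/d means to integers (reporting convention) while
    ``summary.json`` keeps everything unrounded for machine consumption.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_frame(predictions).to_csv(out / "report.csv", index=False)
    summary = summarize_herd(predictions)

    rounded = summary.class_means.round(0)
    rounded.loc["overall"] = summary.overall_mean.round(0)
    rounded = rounded.astype("Int64")  # NA-safe: q_fn_act absent without faecal data
    rounded.insert(0, "n", [summary.counts.get(c, 0) for c in summary.class_means.index]
                   + [summary.herd_size])
    rounded.to_csv(out / "summary.csv")

    payload = {
        "counts": summary.counts,
        "class_means": summary.class_means.to_dict(orient="index"),
        "class_se": summary.class_se.to_dict(orient="index"),
        "overall_mean": summary.overall_mean.to_dict(),
        "overall_se": summary.overall_se.to_dict(),
        "fraction_n_retained": summary.fraction_n_retained,
        "fraction_n_faeces": summary.fraction_n_faeces,
        "fraction_n_urine": summary.fraction_n_urine,
        "fraction_p_retained": summary.fraction_p_retained,
        "fraction_p_faeces": summary.fraction_p_faeces,
    }
    import json

    (out / "summary.json").write_text(json.dumps(payload, indent=2))
    return summary
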