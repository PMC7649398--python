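"""Estimating the Lucas parameters from cow-level survey data.

Calibration regresses the digestible-N concentration of each cow's diet on
its total-N concentration (both in g per 100 g of DM intake):

    DN_i = m·TN_i + b + e_i

by ordinary least squares on a random training subset (3/5 of the herd by
default); the held-out 2/5 serves model evaluation. DN is not observed
directly but follows from the measured faecal N: DN = (TNI − Q_FNACT)/DMI·100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .excretion import LucasParams
from .intake import actual_faecal_n, derive_intake
from .model_io import CowRecord, FeedComposition

logger = logging.getLogger("nutrex")


@dataclass
class CalibrationResult:
    params: LucasParams
    n_train: int
    residual_se: float  # g/100 g DMI
    se_m: float
    se_b: float
    r2: float


def build_calibration_dataset(
    cows: Iterable[CowRecord], feeds: dict[str, FeedComposition]
) -> pd.DataFrame:
    """Per-cow concentrations and quantities needed for the Lucas fit.

    Columns: cow_id, animal_class, tn and dn (g/100 g DMI), dmi, tni,
    q_fn_act (g/animal/d). Cows with zero DMI or no faecal analysis cannot
    contribute and are excluded with a logged warning.
    """
    rows = []
    for cow in cows:
        if cow.faecal_n is None:
            logger.warning("cow %s: no faecal N analysis; excluded from calibration",
                           cow.cow_id)
            continue
        profile = derive_intake(cow, feeds)
        if profile.dmi <= 0:
            logger.warning("cow %s: zero DMI; excluded from calibration", cow.cow_id)
            continue
        q_act = actual_faecal_n(profile, cow.faecal_n)
        rows.append({
            "cow_id": cow.cow_id,
            "animal_class": cow.animal_class.value,
            "tn": profile.tni / profile.dmi * 100.0,
            "dn": (profile.tni - q_act) / profile.dmi * 100.0,
            "dmi": profile.dmi,
            "tni": profile.tni,
            "q_fn_act": q_act,
        })
    return pd.DataFrame(rows)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def split(dataset: pd.DataFrame, fraction: float = 0.6, seed: int = 0) -> pd.DataFrame:
    """Label each cow ``train`` or ``test`` by a seeded uniform shuffle.

    The training size is round(n×fraction), half away from zero (so a herd
    of 144 at 3/5 trains on 86 and tests on 58).
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    n = len(dataset)
    if n < 5:
        raise ValueError(f"need at least 5 cows to calibrate, got {n}")
    n_train = _round_half_away(n * fraction)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[order[:n_train]] = "train"
    labels[order[n_train:]] = "test"
    out = dataset.copy()
    out["split_label"] = labels
    return out


def fit_lucas(train: pd.DataFrame) -> CalibrationResult:
    """OLS of DN on TN on the concentration basis (g/100 g DMI).

    The slope is the true digestibility m, the intercept the metabolic
    faecal N b. Standard errors are the usual OLS ones.
    """
    if len(train) < 3:
        raise ValueError(f"need at least 3 training cows, got {len(train)}")
    tn = np.asarray(train["tn"], dtype=float)
    dn = np.asarray(train["dn"], dtype=float)
    if np.var(tn) == 0:
        raise ValueError("total-N concentration has zero variance; cannot fit slope")
    model = sm.OLS(dn, sm.add_constant(tn)).fit()
    b, m = model.params
    se_b, se_m = model.bse
    return CalibrationResult(
        params=LucasParams(m=float(m), b=float(b)),
        n_train=len(train),
        residual_se=float(np.sqrt(model.mse_resid)) if len(train) > 2 else 0.0,
        se_m=float(se_m),
        se_b=float(se_b),
        r2=float(model.rsquared),
    )


def calibrate(cows: Iterable[CowRecord], feeds: dict[str, FeedComposition],
              fraction: float = 0.6, seed: int = 0,
              ) -> tuple[CalibrationResult, pd.DataFrame]:
    """Dataset build + split + fit in one step; returns (result, labelled data)."""
    dataset = split(build_calibration_dataset(cows, feeds), fraction, seed)
    result = fit_lucas(dataset[dataset["split_label"] == "train"])
    return result, dataset
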