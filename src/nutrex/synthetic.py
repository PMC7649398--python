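"""Synthetic smallholder herds with the statistical structure of the survey.

The generator emulates a 144-cow herd (106 lactating, 12 dry, 26 young) fed
six feeds — elephant grass, road-side grass, rice straw, cassava waste, tofu
waste and concentrate. Per-class per-feed DM intakes and per-feed nutrient
compositions are drawn from the survey's summary statistics (means with
standard errors; SDs reconstructed as SE·√n). Each cow's digestible-N
concentration is then set by a configurable *true* Lucas relation plus
noise, and the faecal N concentration is back-derived so that the actual
faecal N quantity (IDMI × faecal N) is internally consistent with that
truth — calibration, evaluation and herd application are therefore testable
end-to-end against a known ground truth without any survey download.

Sampling uses a symmetric truncated normal on [0, 2·mean]: no negative
mass, no point mass at zero, and the mean is preserved exactly even where
the reconstructed SD is comparable to the mean. Draws are keyed by
(seed, stream, class, cow index), so regeneration is bit-identical and
adding cows never perturbs earlier ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.special import ndtr, ndtri

from .excretion import LucasParams
from .model_io import AnimalClass, CowRecord, DietEntry, FeedComposition, write_herd

# ---------------------------------------------------------------------------
# survey summary statistics used as generator defaults
# ---------------------------------------------------------------------------

CLASS_COUNTS_DEFAULT = {"lactating": 106, "dry": 12, "young": 26}

#: per-class per-feed DM intake, g/animal/d: (mean, SE of the class mean)
FEED_INTAKE_DEFAULT = {
    "lactating": {
        "elephant_grass": (3620.0, 284.0),
        "road_side_grass": (1342.0, 293.0),
        "rice_straw": (949.0, 137.0),
        "cassava_waste": (1230.0, 151.0),
        "tofu_waste": (1944.0, 211.0),
        "concentrate": (4796.0, 351.0),
    },
    "dry": {
        "elephant_grass": (4319.0, 1130.0),
        "road_side_grass": (752.0, 656.0),
        "rice_straw": (515.0, 276.0),
        "cassava_waste": (713.0, 253.0),
        "tofu_waste": (1881.0, 496.0),
        "concentrate": (2590.0, 940.0),
    },
    "young": {
        "elephant_grass": (3310.0, 744.0),
        "road_side_grass": (571.0, 396.0),
        "rice_straw": (485.0, 251.0),
        "cassava_waste": (295.0, 159.0),
        "tofu_waste": (1049.0, 258.0),
        "concentrate": (1763.0, 453.0),
    },
}

#: per-feed composition: field → (mean, SE, n samples); ddm has no survey
#: SE (digestibility taken from feed tables) and is held fixed.
FEED_COMPOSITION_DEFAULT = {
    "elephant_grass": {"dm": (178.0, 11.0, 27), "cp": (101.0, 6.0, 27),
                       "p": (4.0, 0.1, 27), "ash": (112.0, 6.0, 27),
                       "ddm": (529.0, 0.0, 27)},
    "road_side_grass": {"dm": (188.0, 15.0, 9), "cp": (103.0, 7.0, 9),
                        "p": (5.0, 0.4, 9), "ash": (101.0, 9.0, 9),
                        "ddm": (489.0, 0.0, 9)},
    "rice_straw": {"dm": (319.0, 32.0, 11), "cp": (90.0, 3.0, 11),
                   "p": (3.0, 0.3, 11), "ash": (198.0, 13.0, 11),
                   "ddm": (408.0, 0.0, 11)},
    "tofu_waste": {"dm": (155.0, 7.0, 15), "cp": (201.0, 2.0, 15),
                   "p": (3.0, 0.2, 15), "ash": (33.0, 2.0, 15),
                   "ddm": (865.0, 0.0, 15)},
    "cassava_waste": {"dm": (181.0, 13.0, 17), "cp": (61.0, 5.0, 17),
                      "p": (4.0, 0.5, 17), "ash": (28.0, 10.0, 17),
                      "ddm": (768.0, 0.0, 17)},
    "concentrate": {"dm": (876.0, 3.0, 30), "cp": (140.0, 1.0, 30),
                    "p": (7.0, 0.4, 30), "ash": (73.0, 3.0, 30),
                    "ddm": (861.0, 0.0, 30)},
}

#: live weight per class, kg: (mean, SD). Means are the survey class means;
#: SDs are not reported and are set to plausible herd spreads (young stock
#: spans 4-month calves to 2-year heifers, hence the wider SD).
BW_DEFAULT = {"lactating": (433.0, 45.0), "dry": (419.0, 45.0),
              "young": (278.0, 60.0)}

MILK_YIELD_DEFAULT = (13000.0, 3000.0)  # g/d; SD chosen, survey gives the mean
MILK_PROTEIN_DEFAULT = (34.0, 4.12)     # g/kg; SD = SE 0.4 × √106
MILK_P_DEFAULT = (0.6, 0.0515)          # g/kg; SD = SE 0.005 × √106
FAECAL_DM_DEFAULT = (138.0, 54.8)       # g/kg fresh; SD = SE 10 × √30
FAECAL_P_DEFAULT = (7.0, 1.1)           # g/kg DM; SD = SE 0.2 × √30
PREGNANCY_DAYS_DEFAULT = (210, 240)     # dry cows, inclusive


class SyntheticConfig(BaseModel):
    """Everything the generator draws from, with survey-derived defaults."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    class_counts: dict[str, int] = Field(
        default_factory=lambda: dict(CLASS_COUNTS_DEFAULT))
    feed_intake: dict[str, dict[str, tuple[float, float]]] = Field(
        default_factory=lambda: {c: dict(v) for c, v in FEED_INTAKE_DEFAULT.items()})
    feed_composition: dict[str, dict[str, tuple[float, float, int]]] = Field(
        default_factory=lambda: {f: dict(v) for f, v in FEED_COMPOSITION_DEFAULT.items()})
    bw: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(BW_DEFAULT))
    milk_yield: tuple[float, float] = MILK_YIELD_DEFAULT
    milk_protein: tuple[float, float] = MILK_PROTEIN_DEFAULT
    milk_p: tuple[float, float] = MILK_P_DEFAULT
    faecal_dm: tuple[float, float] = FAECAL_DM_DEFAULT
    faecal_p: tuple[float, float] = FAECAL_P_DEFAULT
    pregnancy_days: tuple[int, int] = PREGNANCY_DAYS_DEFAULT
    #: ground-truth Lucas relation the herd obeys
    true_m: float = 0.92
    true_b: float = -0.60
    #: SD of the noise added to each cow's digestible-N concentration,
    #: g/100 g DMI — the scatter the calibration regression sees
    dn_noise_sd: float = 0.16

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SyntheticHerd:
    cows: list[CowRecord]
    feeds: dict[str, FeedComposition]
    truth: LucasParams
    seed: int
    config_digest: str

    def write_tables(self, out_dir: str | Path) -> None:
        """Write herd/diet/feed CSVs plus a truth sidecar under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_herd(self.cows, self.feeds, out / "herd.csv", out / "diet.csv",
                   out / "feeds.csv")
        (out / "truth.json").write_text(json.dumps({
            "true_m": self.truth.m, "true_b": self.truth.b,
            "seed": self.seed, "config_digest": self.config_digest,
        }, indent=2))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float) -> float:
    """One draw from N(mean, sd) truncated to [low, high] (inverse CDF)."""
    if sd <= 0 or low == high:
        return mean
    a = ndtr((low - mean) / sd)
    b = ndtr((high - mean) / sd)
    u = rng.uniform(a, b)
    return mean + sd * float(ndtri(u))


def _positive_draw(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Mean-preserving non-negative draw: N(mean, sd) truncated to [0, 2·mean]."""
    if mean < 0:
        raise ValueError(f"mean must be >= 0, got {mean}")
    if mean == 0:
        return 0.0
    return _truncated_normal(rng, mean, sd, 0.0, 2.0 * mean)


def _cow_rng(seed: int, class_idx: int, cow_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, 1, class_idx, cow_idx]))


def _draw_feeds(config: SyntheticConfig) -> dict[str, FeedComposition]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    feeds = {}
    for feed_name in sorted(config.feed_composition):
        spec = config.feed_composition[feed_name]
        vals = {}
        for field_name in ("dm", "cp", "p", "ash", "ddm"):
            mean, se, _n = spec[field_name]
            # one laboratory-mean composition per herd: its uncertainty is
            # the standard error of the survey mean, not the
            # sample-to-sample scatter
            vals[field_name] = min(_positive_draw(rng, mean, se), 1000.0)
        feeds[feed_name] = FeedComposition(feed_name=feed_name, **vals)
    return feeds


def generate(config: SyntheticConfig) -> SyntheticHerd:
    """Generate a herd whose measurements obey the configured Lucas truth.

    Per cow: feed DM intakes are drawn, converted to fresh offers via the
    feed DM concentrations (leftovers zero); the diet's total-N
    concentration TN follows from the drawn compositions; the digestible-N
    concentration is set to DN = m·TN + b + ε with ε ~ N(0, dn_noise_sd),
    resampled in the rare case it leaves (0, TN); finally the faecal N
    concentration is back-derived as (TNI − DNI)/IDMI·1000 so the measured
    quantities are exactly consistent with the truth-plus-noise.
    """
    for cls, feeds_for_class in config.feed_intake.items():
        for feed_name, (mean, _) in feeds_for_class.items():
            if mean < 0:
                raise ValueError(f"negative mean intake for {cls}/{feed_name}")
    feeds = _draw_feeds(config)
    truth = LucasParams(m=config.true_m, b=config.true_b)

    cows: list[CowRecord] = []
    class_order = ["lactating", "dry", "young"]
    for class_idx, cls in enumerate(class_order):
        count = config.class_counts.get(cls, 0)
        intake_spec = config.feed_intake[cls]
        n_class = max(CLASS_COUNTS_DEFAULT.get(cls, count), 1)
        for cow_idx in range(count):
            rng = _cow_rng(config.seed, class_idx, cow_idx)
            diet = []
            dmi = ddmi = cpi = 0.0
            for feed_name in sorted(intake_spec):
                mean, se = intake_spec[feed_name]
                sd = se * np.sqrt(n_class)
                feed_dmi = _positive_draw(rng, mean, sd)
                comp = feeds[feed_name]
                if comp.dm <= 0:
                    continue
                offered = feed_dmi / comp.dm * 1000.0
                diet.append(DietEntry(feed_name=feed_name, offered_fresh=offered,
                                      leftover_fresh=0.0))
                dmi += feed_dmi
                ddmi += feed_dmi * comp.ddm / 1000.0
                cpi += feed_dmi * comp.cp / 1000.0
            tni = cpi / 6.25
            idmi = dmi - ddmi

            bw_mean, bw_sd = config.bw[cls]
            bw = _positive_draw(rng, bw_mean, bw_sd)

            milk_yield = milk_protein = milk_p = None
            days_pregnant = None
            if cls == "lactating":
                milk_yield = _positive_draw(rng, *config.milk_yield)
                milk_protein = _positive_draw(rng, *config.milk_protein)
                milk_p = _positive_draw(rng, *config.milk_p)
            elif cls == "dry":
                lo, hi = config.pregnancy_days
                days_pregnant = float(rng.integers(lo, hi + 1))

            # digestible-N concentration from the truth + noise (g/100 g DMI)
            tn = tni / dmi * 100.0 if dmi > 0 else 0.0
            dn = truth.m * tn + truth.b
            if config.dn_noise_sd > 0 and dmi > 0:
                for _ in range(100):
                    candidate = dn + rng.normal(0.0, config.dn_noise_sd)
                    if 0.0 < candidate <= tn:
                        dn = candidate
                        break
                else:
                    dn = min(max(dn, 1e-6), tn)
            dni = dn * dmi / 100.0
            q_fn_act = tni - dni
            faecal_n = q_fn_act / idmi * 1000.0 if idmi > 0 else 0.0

            cows.append(CowRecord(
                cow_id=f"{cls[:1].upper()}{cow_idx + 1:03d}",
                farm_id=f"farm{(cow_idx % 30) + 1:02d}",
                animal_class=AnimalClass(cls),
                bw=bw,
                milk_yield=milk_yield if milk_yield is not None else 0.0,
                milk_protein=milk_protein,
                milk_p=milk_p,
                days_pregnant=days_pregnant,
                diet=diet,
                faecal_dm=_positive_draw(rng, *config.faecal_dm),
                faecal_n=faecal_n,
                faecal_p=_positive_draw(rng, *config.faecal_p),
            ))
    return SyntheticHerd(cows=cows, feeds=feeds, truth=truth,
                         seed=config.seed, config_digest=config.digest())


FIXTURE_PRESETS = ("paper-default", "noiseless", "tiny")


def make_fixture(name: str, seed: int = 0) -> SyntheticHerd:
    """Named generator presets.

    * ``paper-default`` — the full survey emulation: 144 cows (106/12/26),
      truth (0.92, −0.60), DN noise 0.16 g/100 g chosen so the evaluation
      pipeline lands near survey-scale relative errors;
    * ``noiseless``     — same herd with zero DN noise, for exact-recovery
      tests;
    * ``tiny``          — 10 cows (7/1/2) for fast tests.
    """
    if name == "paper-default":
        config = SyntheticConfig(seed=seed)
    elif name == "noiseless":
        config = SyntheticConfig(seed=seed, dn_noise_sd=0.0)
    elif name == "tiny":
        config = SyntheticConfig(
            seed=seed, class_counts={"lactating": 7, "dry": 1, "young": 2})
    else:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(FIXTURE_PRESETS)}")
    return generate(config)
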