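"""Domain data model, validation and delimited-table I/O.

The package works on three comma-separated tables (UTF-8, one header row,
decimal point):

* herd table   — one row per animal: identity, class, body and milk data,
  pregnancy stage, faecal composition;
* diet table   — long form, one row per (cow, feed): fresh mass offered and
  left over, g/animal/d;
* feed table   — one row per feed: DM (g/kg fresh) and CP/P/ash/digestible-DM
  concentrations (g/kg DM).

All masses are handled internally in g/animal/d and all concentrations in
g/kg; unit conversions happen only at type boundaries.
"""

from __future__ import annotations

import logging
import math
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

logger = logging.getLogger("nutrex")

#: g crude protein per g N in feed and faeces (Kjeldahl convention).
N_TO_PROTEIN_FEED = 6.25
#: g milk protein per g N.
N_TO_PROTEIN_MILK = 6.38

#: Herd-mean fallbacks for lactating cows without a milk analysis (g/kg).
DEFAULT_MILK_PROTEIN = 34.0
DEFAULT_MILK_P = 0.6

HERD_COLUMNS = [
    "cow_id", "farm_id", "animal_class", "bw", "heart_girth", "milk_yield",
    "milk_protein", "milk_p", "days_pregnant", "cbw", "mw", "wg",
    "faecal_dm", "faecal_n", "faecal_p",
]
DIET_COLUMNS = ["cow_id", "feed_name", "offered_fresh", "leftover_fresh"]
FEED_COLUMNS = ["feed_name", "dm", "cp", "p", "ash", "ddm"]


class AnimalClass(str, Enum):
    LACTATING = "lactating"
    DRY = "dry"
    YOUNG = "young"


class HerdValidationError(ValueError):
    """Raised when input tables contain malformed rows.

    Carries one located message per offence so survey files can be fixed
    without guesswork; nothing is ever silently coerced.
    """

    def __init__(self, messages: list[str]):
        self.messages = list(messages)
        super().__init__("herd input rejected:\n" + "\n".join(self.messages))


def bw_from_heart_girth(heart_girth: float) -> float:
    """Estimate live weight (kg) from heart girth (cm).

    Uses the Schoorl relation BW = (girth + 22)^2 / 100, the convention for
    estimating dairy-cattle live weight from a girth tape when no scale is
    available. Used only when an explicit ``bw`` is absent.
    """
    if not heart_girth > 0:
        raise ValueError(f"heart girth must be positive, got {heart_girth}")
    return (heart_girth + 22.0) ** 2 / 100.0


class FeedComposition(BaseModel):
    """Composition of one feed: DM of the fresh product, nutrients per kg DM."""

    model_config = ConfigDict(frozen=True)

    feed_name: str
    dm: float = Field(ge=0, le=1000, description="g DM per kg fresh matter")
    cp: float = Field(ge=0, le=1000, description="g crude protein per kg DM")
    p: float = Field(ge=0, le=1000, description="g P per kg DM")
    ash: float = Field(ge=0, le=1000, description="g ash per kg DM")
    ddm: float = Field(ge=0, le=1000, description="g digestible DM per kg DM")

    @property
    def n(self) -> float:
        """N concentration, g/kg DM (CP / 6.25)."""
        return self.cp / N_TO_PROTEIN_FEED


class DietEntry(BaseModel):
    """Fresh mass of one feed offered to one cow, with the leftover weighed back."""

    model_config = ConfigDict(frozen=True)

    feed_name: str
    offered_fresh: float = Field(ge=0, description="g fresh/animal/d")
    leftover_fresh: float = Field(default=0.0, ge=0, description="g fresh/animal/d")

    @model_validator(mode="after")
    def _leftover_not_above_offer(self) -> "DietEntry":
        if self.leftover_fresh > self.offered_fresh:
            raise ValueError(
                f"feed {self.feed_name!r}: leftover ({self.leftover_fresh}) "
                f"exceeds offered ({self.offered_fresh})"
            )
        return self

    @property
    def net_fresh(self) -> float:
        """Net fresh intake, g/animal/d."""
        return self.offered_fresh - self.leftover_fresh


class CowRecord(BaseModel):
    """One animal's survey record.

    ``bw`` takes precedence over ``heart_girth``; when only the girth is
    given the live weight is derived with :func:`bw_from_heart_girth`.
    Milk fields are meaningful for lactating cows only, and the model
    enforces zero milk yield for dry and young animals.
    """

    cow_id: str
    farm_id: str = ""
    animal_class: AnimalClass
    bw: Optional[float] = Field(default=None, description="live weight, kg")
    heart_girth: Optional[float] = Field(default=None, description="cm")
    milk_yield: float = Field(default=0.0, ge=0, description="g/animal/d")
    milk_protein: Optional[float] = Field(default=None, ge=0, description="g/kg")
    milk_p: Optional[float] = Field(default=None, ge=0, description="g/kg")
    days_pregnant: Optional[float] = Field(default=None, description="d")
    cbw: float = Field(default=40.0, gt=0, description="calf birth weight, kg")
    mw: float = Field(default=500.0, gt=0, description="expected mature live weight, kg")
    wg: float = Field(default=450.0, ge=0, description="weight gain, g/d")
    diet: list[DietEntry] = Field(default_factory=list)
    faecal_dm: Optional[float] = Field(default=None, ge=0, description="g/kg fresh")
    faecal_n: Optional[float] = Field(default=None, ge=0, description="g/kg DM")
    faecal_p: Optional[float] = Field(default=None, ge=0, description="g/kg DM")

    @field_validator("days_pregnant")
    @classmethod
    def _pregnancy_in_range(cls, v):
        if v is not None and not (0 <= v <= 283):
            raise ValueError(f"days_pregnant must lie in [0, 283], got {v}")
        return v

    @model_validator(mode="after")
    def _resolve_bw_and_milk(self) -> "CowRecord":
        if self.bw is None:
            if self.heart_girth is None:
                raise ValueError(
                    f"cow {self.cow_id!r}: either bw or heart_girth is required"
                )
            object.__setattr__(self, "bw", bw_from_heart_girth(self.heart_girth))
        if not self.bw > 0:
            raise ValueError(f"cow {self.cow_id!r}: bw must be positive, got {self.bw}")
        if self.animal_class is not AnimalClass.LACTATING and self.milk_yield != 0:
            raise ValueError(
                f"cow {self.cow_id!r}: milk_yield must be 0 for "
                f"{self.animal_class.value} animals, got {self.milk_yield}"
            )
        return self


class DesignConstants(BaseModel):
    """Fixed modelling constants, immutable at run time.

    Overridable only through explicit configuration (e.g. a run-config file),
    never mutated in place.
    """

    model_config = ConfigDict(frozen=True)

    n_to_protein_feed: float = N_TO_PROTEIN_FEED
    n_to_protein_milk: float = N_TO_PROTEIN_MILK
    #: efficiency of metabolizable protein use for pregnancy
    eff_mp_preg: float = 0.33
    #: shrunk body weight as a fraction of live weight (overnight fast)
    shrink_factor: float = 0.96
    #: reference shrunk body weight (kg) used to standardise growth equations
    reference_sbw: float = 478.0
    #: gestation-day window over which pregnancy retention applies
    pregnancy_window: tuple[int, int] = (190, 279)
    #: if True, the CBW/45 scaling applies to the whole pregnancy-protein
    #: requirement; if False, only to the intercept term (alternative
    #: reading of an ambiguous printed bracket — see docs/methods.md)
    cbw_scales_whole_mp_preg: bool = True


DEFAULT_CONSTANTS = DesignConstants()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: list[str], what: str,
                     errors: list[str]) -> bool:
    missing = [c for c in required if c not in df.columns]
    if missing:
        errors.append(f"{what}: missing column(s) {', '.join(missing)}")
        return False
    return True


def _opt(value):
    """NaN/empty → None for optional numeric cells."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return value


def read_feed_table(path: str | Path) -> dict[str, FeedComposition]:
    """Read the feed table into a mapping feed_name → :class:`FeedComposition`."""
    df = pd.read_csv(path, float_precision="round_trip")
    errors: list[str] = []
    if not _require_columns(df, FEED_COLUMNS, f"feed table {path}", errors):
        raise HerdValidationError(errors)
    feeds: dict[str, FeedComposition] = {}
    for i, row in df.iterrows():
        try:
            comp = FeedComposition(**{c: row[c] for c in FEED_COLUMNS})
        except ValidationError as exc:
            errors.append(f"feed table row {i + 2}: {exc.errors()[0]['msg']}")
            continue
        if comp.feed_name in feeds:
            errors.append(f"feed table row {i + 2}: duplicate feed {comp.feed_name!r}")
        feeds[comp.feed_name] = comp
    if errors:
        raise HerdValidationError(errors)
    return feeds


def read_herd(
    herd_path: str | Path,
    diet_path: str | Path,
    feed_path: str | Path,
) -> tuple[list[CowRecord], dict[str, FeedComposition]]:
    """Read and validate herd, diet and feed tables.

    Every malformed row is reported with its file and 1-based row number
    (header excluded); all offences are collected before rejection. Lactating
    cows lacking a milk analysis fall back to the herd-mean defaults
    (protein 34 g/kg, P 0.6 g/kg) with a logged warning.
    """
    feeds = read_feed_table(feed_path)
    herd_df = pd.read_csv(herd_path, float_precision="round_trip")
    diet_df = pd.read_csv(diet_path, float_precision="round_trip")

    errors: list[str] = []
    ok = _require_columns(herd_df, ["cow_id", "animal_class"], f"herd table {herd_path}", errors)
    ok &= _require_columns(diet_df, DIET_COLUMNS, f"diet table {diet_path}", errors)
    if not ok:
        raise HerdValidationError(errors)

    diet_by_cow: dict[str, list[DietEntry]] = {}
    for i, row in diet_df.iterrows():
        loc = f"diet table row {i + 2}"
        if row["feed_name"] not in feeds:
            errors.append(f"{loc}: unresolved feed name {row['feed_name']!r}")
            continue
        try:
            entry = DietEntry(
                feed_name=row["feed_name"],
                offered_fresh=row["offered_fresh"],
                leftover_fresh=0.0 if _opt(row["leftover_fresh"]) is None
                else row["leftover_fresh"],
            )
        except ValidationError as exc:
            errors.append(f"{loc}: {exc.errors()[0]['msg']}")
            continue
        diet_by_cow.setdefault(str(row["cow_id"]), []).append(entry)

    cows: list[CowRecord] = []
    for i, row in herd_df.iterrows():
        loc = f"herd table row {i + 2}"
        data = {c: _opt(row[c]) for c in herd_df.columns if c in HERD_COLUMNS}
        data["cow_id"] = str(row["cow_id"])
        if _opt(row.get("farm_id")) is not None:
            data["farm_id"] = str(row["farm_id"])
        data = {k: v for k, v in data.items() if v is not None}
        data["diet"] = diet_by_cow.get(data["cow_id"], [])
        try:
            cow = CowRecord(**data)
        except (ValidationError, ValueError) as exc:
            msg = exc.errors()[0]["msg"] if isinstance(exc, ValidationError) else str(exc)
            errors.append(f"{loc}: {msg}")
            continue
        if cow.animal_class is AnimalClass.LACTATING:
            if cow.milk_protein is None:
                logger.warning(
                    "cow %s: missing milk protein, falling back to herd mean %.1f g/kg",
                    cow.cow_id, DEFAULT_MILK_PROTEIN)
                cow = cow.model_copy(update={"milk_protein": DEFAULT_MILK_PROTEIN})
            if cow.milk_p is None:
                logger.warning(
                    "cow %s: missing milk P, falling back to herd mean %.1f g/kg",
                    cow.cow_id, DEFAULT_MILK_P)
                cow = cow.model_copy(update={"milk_p": DEFAULT_MILK_P})
        cows.append(cow)

    if errors:
        raise HerdValidationError(errors)
    return cows, feeds


def write_herd(
    cows: list[CowRecord],
    feeds: dict[str, FeedComposition],
    herd_path: str | Path,
    diet_path: str | Path,
    feed_path: str | Path,
) -> None:
    """Write herd, diet and feed tables; numeric fields round-trip exactly."""
    herd_rows = []
    diet_rows = []
    for cow in cows:
        herd_rows.append({
            "cow_id": cow.cow_id, "farm_id": cow.farm_id,
            "animal_class": cow.animal_class.value, "bw": cow.bw,
            "heart_girth": cow.heart_girth, "milk_yield": cow.milk_yield,
            "milk_protein": cow.milk_protein, "milk_p": cow.milk_p,
            "days_pregnant": cow.days_pregnant, "cbw": cow.cbw,
            "mw": cow.mw, "wg": cow.wg, "faecal_dm": cow.faecal_dm,
            "faecal_n": cow.faecal_n, "faecal_p": cow.faecal_p,
        })
        for entry in cow.diet:
            diet_rows.append({
                "cow_id": cow.cow_id, "feed_name": entry.feed_name,
                "offered_fresh": entry.offered_fresh,
                "leftover_fresh": entry.leftover_fresh,
            })
    pd.DataFrame(herd_rows, columns=HERD_COLUMNS).to_csv(herd_path, index=False)
    pd.DataFrame(diet_rows, columns=DIET_COLUMNS).to_csv(diet_path, index=False)
    feed_rows = [
        {c: getattr(comp, c) for c in FEED_COLUMNS} for comp in feeds.values()
    ]
    pd.DataFrame(feed_rows, columns=FEED_COLUMNS).to_csv(feed_path, index=False)
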