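"""Derived daily intake quantities.

All quantities are per animal and per day, in grams:

* DMI   — dry matter intake, Σ net fresh mass × DM/1000 over the diet;
* DDMI  — digestible DM intake, Σ feed DMI × DDM/1000;
* IDMI  — indigestible DM intake, DMI − DDMI (≈ faecal DM output);
* CPI   — crude protein intake, Σ feed DMI × CP/1000;
* TNI   — total N intake, CPI / 6.25;
* PI    — P intake, Σ feed DMI × P/1000.

The actual faecal N quantity (Q_FNACT) is IDMI × faecal N concentration,
from which the indigestible (IDNI) and digestible (DNI) N intakes follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model_io import CowRecord, FeedComposition, N_TO_PROTEIN_FEED


@dataclass
class IntakeProfile:
    """Daily intake quantities for one animal (g/animal/d)."""

    dmi: float = 0.0
    ddmi: float = 0.0
    idmi: float = 0.0
    cpi: float = 0.0
    tni: float = 0.0
    pi: float = 0.0
    #: set by :func:`actual_faecal_n` (requires a faecal N analysis)
    q_fn_act: Optional[float] = None
    idni: Optional[float] = None
    dni: Optional[float] = None
    flags: list[str] = field(default_factory=list)


def derive_intake(cow: CowRecord, feeds: dict[str, FeedComposition]) -> IntakeProfile:
    """Aggregate a cow's diet entries into an :class:`IntakeProfile`.

    An empty diet yields an all-zero profile. An unresolved feed name is an
    error (the I/O layer normally catches this earlier, with row locations).
    """
    profile = IntakeProfile()
    for entry in cow.diet:
        try:
            comp = feeds[entry.feed_name]
        except KeyError:
            raise KeyError(
                f"cow {cow.cow_id!r}: feed {entry.feed_name!r} not in feed table"
            ) from None
        feed_dmi = entry.net_fresh * comp.dm / 1000.0
        profile.dmi += feed_dmi
        profile.ddmi += feed_dmi * comp.ddm / 1000.0
        profile.cpi += feed_dmi * comp.cp / 1000.0
        profile.pi += feed_dmi * comp.p / 1000.0
    profile.idmi = profile.dmi - profile.ddmi
    profile.tni = profile.cpi / N_TO_PROTEIN_FEED
    return profile


def actual_faecal_n(profile: IntakeProfile, faecal_n: float) -> float:
    """Actual faecal N quantity Q_FNACT = IDMI × faecal N concentration / 1000.

    ``faecal_n`` is the laboratory N concentration of faeces (g/kg DM).
    Also stores the derived indigestible and digestible N intakes on the
    profile (IDNI = Q_FNACT, DNI = TNI − IDNI) and returns Q_FNACT (g/d).
    """
    if faecal_n < 0:
        raise ValueError(f"faecal N concentration must be >= 0, got {faecal_n}")
    q = profile.idmi * faecal_n / 1000.0
    profile.q_fn_act = q
    profile.idni = q
    profile.dni = profile.tni - q
    return q
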