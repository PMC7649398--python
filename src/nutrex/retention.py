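"""N and P retention (milk, pregnancy, growth, scurf) per NRC-style equations.

Retained N has four sinks:

* milk      — milk protein / 6.38;
* pregnancy — metabolizable protein for gestation (days 190–279) / 6.25;
* growth    — metabolizable protein for gain in young stock / 6.25, via the
  NRC shrunk/equivalent body-weight chain (lactating and dry cows are
  assumed not to accrete body protein);
* scurf     — skin, skin secretions and hair, 0.3·BW^0.60 g protein/d.

Retained P has milk, pregnancy and growth components; urinary P is
negligible in cattle and is not modelled.

Weight gain (WG) enters the survey data in g/d but the exponentiated NRC
forms (WG^1.2, WG/0.96) are dimensioned for kg/d; conversion happens inside
these functions, at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .model_io import AnimalClass, CowRecord, DesignConstants, DEFAULT_CONSTANTS


@dataclass
class GrowthTrace:
    """Intermediate quantities of the growth-protein chain, for auditing.

    sbw/msbw/eqsbw/eqebw in kg; swg/eqebg in kg/d; ne_growth_diet and re in
    Mcal/d; np_g, mp_growth, mp_preg in g/d.
    """

    sbw: float = 0.0
    msbw: float = 0.0
    eqsbw: float = 0.0
    ne_growth_diet: float = 0.0
    swg: float = 0.0
    eqebw: float = 0.0
    eqebg: float = 0.0
    re: float = 0.0
    np_g: float = 0.0
    mp_growth: float = 0.0
    mp_preg: float = 0.0


@dataclass
class NRetention:
    """Retained N per sink and in total (g/animal/d)."""

    n_milk: float
    n_preg: float
    n_growth: float
    n_scurf: float

    @property
    def total(self) -> float:
        return self.n_milk + self.n_preg + self.n_growth + self.n_scurf


@dataclass
class PRetention:
    """Retained P per sink and in total (g/animal/d)."""

    p_milk: float
    p_preg: float
    p_growth: float

    @property
    def total(self) -> float:
        return self.p_milk + self.p_preg + self.p_growth


def _in_window(days_pregnant: Optional[float], constants: DesignConstants) -> bool:
    if days_pregnant is None:
        return False
    if days_pregnant < 0:
        raise ValueError(f"days_pregnant must be >= 0, got {days_pregnant}")
    lo, hi = constants.pregnancy_window
    return lo <= days_pregnant <= hi


def n_milk(milk_yield: float, milk_protein: float,
           constants: DesignConstants = DEFAULT_CONSTANTS) -> float:
    """N secreted in milk, g/d: yield (g/d) × protein (g/kg) / 1000 / 6.38."""
    if milk_yield < 0 or milk_protein < 0:
        raise ValueError("milk yield and protein concentration must be >= 0")
    return milk_yield * milk_protein / 1000.0 / constants.n_to_protein_milk


def mp_pregnancy(days_pregnant: float, cbw: float,
                 constants: DesignConstants = DEFAULT_CONSTANTS) -> float:
    """Metabolizable protein requirement for gestation, g/d.

    MP_Preg = ((0.69·t − 69.2) × CBW/45) / 0.33 for t in the 190–279 d
    window, zero outside. CBW is the expected calf birth weight (kg). The
    CBW/45 scaling applies to the whole requirement by default; set
    ``cbw_scales_whole_mp_preg=False`` in the constants for the alternative
    reading in which it scales only the intercept term.
    """
    if cbw <= 0:
        raise ValueError(f"calf birth weight must be positive, got {cbw}")
    if not _in_window(days_pregnant, constants):
        return 0.0
    if constants.cbw_scales_whole_mp_preg:
        mp = (0.69 * days_pregnant - 69.2) * (cbw / 45.0)
    else:
        mp = 0.69 * days_pregnant - 69.2 * (cbw / 45.0)
    return mp / constants.eff_mp_preg


def n_preg(days_pregnant: Optional[float], cbw: float = 40.0,
           constants: DesignConstants = DEFAULT_CONSTANTS) -> float:
    """N retained for gestation, g/d (MP_Preg / 6.25); zero outside the window."""
    if days_pregnant is None:
        return 0.0
    return mp_pregnancy(days_pregnant, cbw, constants) / constants.n_to_protein_feed


def growth_trace(bw: float, mw: float, wg: float,
                 constants: DesignConstants = DEFAULT_CONSTANTS) -> GrowthTrace:
    """Run the NRC growth chain for a growing animal.

    bw, mw in kg; wg in g/d. Returns the full intermediate trace; the
    metabolizable protein for gain is ``trace.mp_growth`` (g/d).
    """
    if not 0 < bw <= mw:
        raise ValueError(f"need 0 < bw <= mw, got bw={bw}, mw={mw}")
    if wg < 0:
        raise ValueError(f"weight gain must be >= 0, got {wg}")
    t = GrowthTrace()
    t.sbw = constants.shrink_factor * bw
    t.msbw = constants.shrink_factor * mw
    t.eqsbw = t.sbw * constants.reference_sbw / t.msbw
    denom = 0.834 - t.eqsbw * 0.00114
    if denom <= 0:
        raise ValueError(
            f"growth-protein denominator 0.834 - 0.00114*EQSBW <= 0 at "
            f"EQSBW={t.eqsbw:.1f} kg (bw={bw}, mw={mw}); animal too heavy "
            f"relative to its mature weight for the growth equations"
        )
    if wg == 0:
        return t
    wg_kg = wg / 1000.0
    t.ne_growth_diet = (0.84 * bw ** 0.355 * wg_kg ** 1.2) * 0.69
    t.swg = 13.9 * t.ne_growth_diet ** 0.9116 * t.eqsbw ** -0.6837
    t.eqebw = 0.891 * t.eqsbw
    t.eqebg = 0.956 * t.swg
    t.re = 0.0635 * t.eqebw ** 0.75 * t.eqebg ** 1.097
    # SWG enters in kg/d both as the leading factor and inside the RE/SWG
    # ratio; the bracket has units g protein per kg gain, so NP_g is g/d.
    t.np_g = t.swg * (268.0 - 29.4 * (t.re / t.swg))
    t.mp_growth = t.np_g / denom
    return t


def n_growth(bw: float, mw: float, wg: float,
             animal_class: AnimalClass = AnimalClass.YOUNG,
             constants: DesignConstants = DEFAULT_CONSTANTS,
             ) -> tuple[float, Optional[GrowthTrace]]:
    """N retained for growth, g/d, with the audit trace.

    Only young stock accrete body protein; lactating and dry cows return
    (0, None).
    """
    if animal_class is not AnimalClass.YOUNG:
        return 0.0, None
    trace = growth_trace(bw, mw, wg, constants)
    return trace.mp_growth / constants.n_to_protein_feed, trace


def n_scurf(bw: float, constants: DesignConstants = DEFAULT_CONSTANTS) -> float:
    """N lost as scurf protein (skin, secretions, hair), g/d: 0.3·BW^0.6 / 6.25."""
    if bw <= 0:
        raise ValueError(f"bw must be positive, got {bw}")
    return 0.3 * bw ** 0.60 / constants.n_to_protein_feed


def p_milk(milk_yield: float, milk_p: float) -> float:
    """P secreted in milk, g/d: yield (kg/d) × milk P concentration (g/kg)."""
    if milk_yield < 0 or milk_p < 0:
        raise ValueError("milk yield and P concentration must be >= 0")
    return milk_yield / 1000.0 * milk_p


def p_preg(days_pregnant: Optional[float],
           constants: DesignConstants = DEFAULT_CONSTANTS) -> float:
    """P retained for gestation, g/d; zero outside the 190–279 d window.

    Daily accretion is the first difference of a Gompertz-like cumulative
    conceptus-P curve:
    0.02743·exp((0.05527 − 0.000075·t)·t) − same at t−1.
    """
    if days_pregnant is None or not _in_window(days_pregnant, constants):
        return 0.0
    t = days_pregnant

    def cum(day: float) -> float:
        return 0.02743 * math.exp((0.05527 - 0.000075 * day) * day)

    return cum(t) - cum(t - 1)


def p_growth(bw: float, mw: float, wg: float,
             animal_class: AnimalClass = AnimalClass.YOUNG) -> float:
    """P retained for growth in young stock, g/d; 0 for lactating/dry cows.

    (1.2 + 4.635·MW^0.22·BW^−0.22) × (WG_kg / 0.96), with wg given in g/d.
    """
    if animal_class is not AnimalClass.YOUNG:
        return 0.0
    if bw <= 0 or mw <= 0 or wg < 0:
        raise ValueError("need bw > 0, mw > 0, wg >= 0")
    wg_kg = wg / 1000.0
    return (1.2 + 4.635 * mw ** 0.22 * bw ** -0.22) * (wg_kg / 0.96)


def retention_for_cow(
    cow: CowRecord,
    constants: DesignConstants = DEFAULT_CONSTANTS,
) -> tuple[NRetention, PRetention, Optional[GrowthTrace], list[str]]:
    """Compute both retention budgets for one animal.

    Returns (N retention, P retention, growth trace or None, warning flags).
    A dry cow without a recorded gestation day gets zero pregnancy retention
    plus a flag, since dry cows in late pregnancy are the norm.
    """
    flags: list[str] = []
    if cow.animal_class is AnimalClass.LACTATING:
        nm = n_milk(cow.milk_yield, cow.milk_protein or 0.0, constants)
        pm = p_milk(cow.milk_yield, cow.milk_p or 0.0)
    else:
        nm, pm = 0.0, 0.0

    if cow.animal_class is AnimalClass.DRY and cow.days_pregnant is None:
        flags.append(
            f"cow {cow.cow_id!r}: dry cow without days_pregnant; "
            "pregnancy retention set to 0"
        )
    np_ = n_preg(cow.days_pregnant, cow.cbw, constants)
    pp = p_preg(cow.days_pregnant, constants)

    ng, trace = n_growth(cow.bw, cow.mw, cow.wg, cow.animal_class, constants)
    pg = p_growth(cow.bw, cow.mw, cow.wg, cow.animal_class)
    if trace is not None:
        trace.mp_preg = mp_pregnancy(cow.days_pregnant, cow.cbw, constants) \
            if cow.days_pregnant is not None else 0.0

    n_ret = NRetention(n_milk=nm, n_preg=np_, n_growth=ng,
                       n_scurf=n_scurf(cow.bw, constants))
    p_ret = PRetention(p_milk=pm, p_preg=pp, p_growth=pg)
    return n_ret, p_ret, trace, flags
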