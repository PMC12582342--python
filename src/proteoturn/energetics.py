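"""Whole-body energy arithmetic and indirect-calorimetry substrate oxidation.

Energy availability (EA) is dietary energy intake minus exercise energy
expenditure, normalized to fat-free mass (kcal per kg FFM per day); fat and
carbohydrate oxidation rates are linear stoichiometric combinations of
VO2 and VCO2 with context-specific coefficient sets (rest vs exercise).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

#: prescribed exercise energy expenditure target (kcal per kg FFM per day)
EEE_TARGET_KCAL_PER_KG_FFM = 15.0


def _load_oxidation_coefficients() -> dict[str, tuple[float, float, float, float]]:
    text = (
        importlib.resources.files("proteoturn.data")
        .joinpath("oxidation_coefficients.tsv")
        .read_text()
    )
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ctx, a1, a2, b1, b2 = line.split("\t")
        out[ctx] = (float(a1), float(a2), float(b1), float(b2))
    return out


OXIDATION_COEFFICIENTS = _load_oxidation_coefficients()


def energy_availability(ei_kcal: float, eee_kcal: float, ffm_kg: float) -> float:
    """EA = (energy intake - exercise energy expenditure) / FFM."""
    if ffm_kg <= 0:
        raise ValueError("fat-free mass must be positive")
    return (ei_kcal - eee_kcal) / ffm_kg


def percent_reduction(a: float, b: float, round_to_int: bool = False) -> float:
    """100 x (a - b)/a: how much smaller b is than a, in percent of a.

    Negative values mean b exceeds a (an increase). ``round_to_int`` uses
    round-half-even, the usual reporting convention.
    """
    if a == 0:
        raise ValueError("reference value must be nonzero")
    pct = 100.0 * (a - b) / a
    return float(round(pct)) if round_to_int else pct


def percent_excess(a: float, b: float, round_to_int: bool = False) -> float:
    """100 x (b - a)/a: how much larger b is than a, in percent of a."""
    return percent_reduction(a, 2 * a - b, round_to_int=round_to_int)


@dataclass
class OxidationResult:
    fat_g_min: float
    cho_g_min: float
    rer: float
    flags: set


def substrate_oxidation(
    vo2_l_min: float,
    vco2_l_min: float,
    context: str = "exercise",
    coefficients: dict | None = None,
) -> OxidationResult:
    """Fat and carbohydrate oxidation (g/min) from respiratory gases.

    fat = a1*VO2 - a2*VCO2 and cho = b1*VCO2 - b2*VO2 with per-context
    coefficient sets (rest: Frayn; exercise: moderate-to-high-intensity
    set). Negative rates clamp to zero with a flag; an RER outside
    [0.6, 1.3] is flagged, not rejected, since protein oxidation and
    non-steady-state gas exchange can push it out.
    """
    if vo2_l_min <= 0 or vco2_l_min <= 0:
        raise ValueError("gas exchange values must be positive")
    coeffs = coefficients if coefficients is not None else OXIDATION_COEFFICIENTS
    if context not in coeffs:
        raise ValueError(f"unknown context {context!r}")
    a1, a2, b1, b2 = coeffs[context]
    rer = vco2_l_min / vo2_l_min
    flags = set()
    if not 0.6 <= rer <= 1.3:
        flags.add("rer_out_of_range")
    fat = a1 * vo2_l_min - a2 * vco2_l_min
    cho = b1 * vco2_l_min - b2 * vo2_l_min
    if fat < 0:
        flags.add("fat_clamped")
        fat = 0.0
    if cho < 0:
        flags.add("cho_clamped")
        cho = 0.0
    return OxidationResult(fat, cho, rer, flags)


def eee_prescription(ffm_kg: float, target: float = EEE_TARGET_KCAL_PER_KG_FFM) -> float:
    """Daily exercise energy expenditure prescription (kcal/day)."""
    if ffm_kg <= 0:
        raise ValueError("fat-free mass must be positive")
    return target * ffm_kg
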