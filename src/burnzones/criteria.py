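"""Harm criteria with era-dependent fallbacks.

A fire meets the fatality criterion with at least one civilian fatality,
or — for ignition years 2000-2013, when the incident-summary source did not
break out civilian fatalities — with at least one fatality of any type. It
meets the structure criterion with at least one destroyed structure, or —
for 2007-2009, when the California annual reports combined damaged and
destroyed structures — with a combined count of at least one. It meets the
FMAG criterion by appearing in the federal fire-assistance declarations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .records import CanonicalFire, CriteriaFlags


@dataclass
class CriteriaConfig:
    fatality_fallback_years: tuple[int, int] = (2000, 2013)
    structure_fallback_years: tuple[int, int] = (2007, 2009)


def _in_range(year: Optional[int], lo_hi: tuple[int, int]) -> bool:
    return year is not None and lo_hi[0] <= year <= lo_hi[1]


def evaluate_criteria(
    fire: CanonicalFire, cfg: Optional[CriteriaConfig] = None
) -> CriteriaFlags:
    """Evaluate the three harm criteria for one canonical fire.

    The era is keyed on the ignition year. A fire with no ignition year is
    evaluated under the strict (non-fallback) rules and annotated as such.
    """
    cfg = cfg or CriteriaConfig()
    year = fire.ignition_year
    strict_only = year is None

    flags = CriteriaFlags()

    if (fire.civilian_fatalities or 0) >= 1:
        flags.fatality_met = True
        flags.fatality_rule = "civilian"
    elif (
        not strict_only
        and _in_range(year, cfg.fatality_fallback_years)
        and (fire.total_fatalities or 0) >= 1
    ):
        flags.fatality_met = True
        flags.fatality_rule = "any_fatality_fallback_2000_2013"
    elif strict_only:
        flags.fatality_rule = "none_strict_no_year"

    if (fire.destroyed_structures or 0) >= 1:
        flags.structure_met = True
        flags.structure_rule = "destroyed"
    elif (
        not strict_only
        and _in_range(year, cfg.structure_fallback_years)
        and (fire.combined_damaged_destroyed or 0) >= 1
    ):
        flags.structure_met = True
        flags.structure_rule = "damaged_fallback_2007_2009"
    elif strict_only:
        flags.structure_rule = "none_strict_no_year"

    if fire.fmag:
        flags.fmag_met = True
        flags.fmag_rule = "fmag"

    return flags


def filter_preliminary(
    fires: Sequence[CanonicalFire], cfg: Optional[CriteriaConfig] = None
) -> tuple[list[tuple[CanonicalFire, CriteriaFlags]], dict[str, int]]:
    """Retain fires meeting at least one harm criterion.

    Returns the preliminary set (fire, flags) plus counts by criterion.
    """
    kept = []
    counts = {"fatality": 0, "structure": 0, "fmag": 0, "dropped": 0}
    for fire in fires:
        flags = evaluate_criteria(fire, cfg)
        if flags.any_met:
            kept.append((fire, flags))
            counts["fatality"] += flags.fatality_met
            counts["structure"] += flags.structure_met
            counts["fmag"] += flags.fmag_met
        else:
            counts["dropped"] += 1
    return kept, counts
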