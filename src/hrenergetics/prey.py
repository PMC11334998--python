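"""Prey-equivalent energetics: insects needed and minutes fuelled.

Translates daily energy expenditures into intake requirements for an
insectivore: how many items of a prey type cover a day's energy budget
given an assimilation efficiency, what fresh mass that represents
relative to body mass, and how long one prey item sustains a given
activity's energy-expenditure rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "InsectSpec",
    "PreyParams",
    "JUNE_BEETLE",
    "insects_needed",
    "fresh_mass_fraction",
    "minutes_fueled",
    "prey_report",
]


@dataclass(frozen=True)
class InsectSpec:
    """One prey type: gross energy and fresh mass per item."""

    name: str
    energy_kj: float
    fresh_mass_g: float

    def __post_init__(self) -> None:
        if self.energy_kj <= 0 or self.fresh_mass_g <= 0:
            raise ValueError("energy and fresh mass per item must be positive")


@dataclass(frozen=True)
class PreyParams:
    """Digestive parameters; assimilation efficiency defaults to 75%."""

    assimilation_efficiency: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.assimilation_efficiency <= 1.0:
            raise ValueError("assimilation efficiency must lie in (0, 1]")


#: a large swarming beetle frequently taken by aerial-hawking bats
JUNE_BEETLE = InsectSpec(name="june_beetle", energy_kj=1.86, fresh_mass_g=0.303)


def insects_needed(
    dee_kj: float,
    insect: InsectSpec,
    params: PreyParams = PreyParams(),
) -> tuple[int, float]:
    """Prey items needed to cover a daily energy expenditure.

    The exact requirement is ``dee / (efficiency * energy_per_item)``;
    the reported count rounds to the nearest integer.

    Returns ``(count, exact)``.
    """
    if dee_kj <= 0:
        raise ValueError("daily energy expenditure must be positive")
    exact = dee_kj / (params.assimilation_efficiency * insect.energy_kj)
    return int(round(exact)), exact


def fresh_mass_fraction(total_fresh_mass_g: float, body_mass_g: float) -> tuple[int, float]:
    """Fresh prey mass as a percentage of body mass.

    Returns ``(integer percent, exact percent)``.
    """
    if total_fresh_mass_g <= 0 or body_mass_g <= 0:
        raise ValueError("masses must be positive")
    exact = 100.0 * total_fresh_mass_g / body_mass_g
    return int(round(exact)), exact


def minutes_fueled(
    insect: InsectSpec,
    ee_rate_kj_h: float,
    params: PreyParams = PreyParams(),
) -> float:
    """Minutes of an activity fuelled by one prey item.

    ``minutes = 60 * efficiency * energy_per_item / rate``.  The
    assimilation efficiency is applied here exactly as in
    :func:`insects_needed`, so one consistent convention covers both
    directions of the arithmetic.
    """
    if ee_rate_kj_h <= 0:
        raise ValueError("energy-expenditure rate must be positive")
    return 60.0 * params.assimilation_efficiency * insect.energy_kj / ee_rate_kj_h


def prey_report(
    dee_by_group: dict[str, float],
    insect: InsectSpec,
    body_mass_g: float,
    params: PreyParams = PreyParams(),
    rates_kj_h: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Tabulate prey equivalents per group (and per activity rate).

    One row per group: items needed, fresh mass, percent of body mass;
    plus, when activity rates are supplied, minutes fuelled per item.
    """
    rows = []
    for group, dee in dee_by_group.items():
        count, exact = insects_needed(dee, insect, params)
        mass = count * insect.fresh_mass_g
        pct, pct_exact = fresh_mass_fraction(mass, body_mass_g)
        rows.append(
            {
                "group": group,
                "insect": insect.name,
                "dee_kj": dee,
                "items_needed": count,
                "items_exact": exact,
                "fresh_mass_g": mass,
                "pct_body_mass": pct,
            }
        )
    df = pd.DataFrame(rows)
    if rates_kj_h:
        for activity, rate in rates_kj_h.items():
            df[f"min_per_item_{activity}"] = minutes_fueled(insect, rate, params)
    return df
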