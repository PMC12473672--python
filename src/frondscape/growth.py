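"""Growth and frond-shape indices for duckweed culture trials.

Implements the standard desk indices of a 7-day static duckweed growth
trial: relative growth rate of frond number, doubling time, colony size,
senescence percentage, the ellipse approximation of frond area, roundness,
daily light integral and frond mass-to-area ratio, plus the vessel-level
averaging used for morphometric data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedDoublingError


@dataclass(frozen=True)
class CultureObservation:
    """Frond/colony/senescent counts of one vessel on one day."""

    vessel_id: str
    day: int
    frond_count: int
    colony_count: int
    senescent_count: int = 0

    def __post_init__(self):
        fn, cn, sn = self.frond_count, self.colony_count, self.senescent_count
        if min(fn, cn, sn) < 0:
            raise InvalidArgumentError("counts must be non-negative")
        if sn > fn:
            raise InvalidArgumentError("senescent_count cannot exceed frond_count")
        if cn > fn:
            raise InvalidArgumentError("colony_count cannot exceed frond_count")


@dataclass(frozen=True)
class FrondMorphometry:
    """Length/width of one frond with the derived ellipse area and roundness."""

    vessel_id: str
    frond_id: str
    length: float  # mm
    width: float  # mm
    area: float = field(init=False)  # mm^2
    roundness: float = field(init=False)

    def __post_init__(self):
        if not (self.length >= self.width > 0):
            raise InvalidArgumentError("require length >= width > 0")
        object.__setattr__(self, "area", ellipse_area(self.length, self.width))
        object.__setattr__(self, "roundness", self.length / self.width)


@dataclass(frozen=True)
class BiomassSample:
    """Projected area / fresh mass / dry mass of one vessel's biomass."""

    vessel_id: str
    plant_area: float  # cm^2
    fresh_mass: float  # mg
    dry_mass: float  # mg
    fma: float = field(init=False)  # mg cm^-2

    def __post_init__(self):
        if not (0 < self.dry_mass <= self.fresh_mass):
            raise InvalidArgumentError("require 0 < dry_mass <= fresh_mass")
        object.__setattr__(self, "fma", frond_mass_area(self.dry_mass, self.plant_area))


@dataclass(frozen=True)
class LightRegime:
    """A PPFD × photoperiod regime with its daily light integral."""

    ppfd: float  # umol m^-2 s^-1
    photoperiod: float  # h day^-1
    dli: float = field(init=False)  # mol m^-2 day^-1

    def __post_init__(self):
        object.__setattr__(self, "dli", daily_light_integral(self.ppfd, self.photoperiod))


def relative_growth_rate(obs0: CultureObservation, obs7: CultureObservation) -> float:
    """RGR of frond number, (ln FN_t1 − ln FN_t0) / (t1 − t0), day⁻¹."""
    if obs0.frond_count < 1 or obs7.frond_count < 1:
        raise InvalidArgumentError("frond counts must be >= 1 (log undefined at 0)")
    if obs7.day <= obs0.day:
        raise InvalidArgumentError("second observation must be later than the first")
    dt = obs7.day - obs0.day
    return (math.log(obs7.frond_count) - math.log(obs0.frond_count)) / dt


def doubling_time(rgr: float) -> float:
    """Days needed to double frond number at growth rate ``rgr``, ln(2)/RGR."""
    if rgr <= 0:
        raise UndefinedDoublingError("doubling time undefined for rgr <= 0")
    return math.log(2.0) / rgr


def colony_size(obs: CultureObservation) -> float:
    """Mean fronds per colony, FN/CN."""
    if obs.colony_count < 1:
        raise InvalidArgumentError("colony_count must be >= 1")
    return obs.frond_count / obs.colony_count


def senescence_percent(obs: CultureObservation) -> float:
    """Percentage of fronds showing senescence, 100·senescent/FN."""
    if obs.frond_count < 1:
        raise InvalidArgumentError("frond_count must be >= 1")
    return 100.0 * obs.senescent_count / obs.frond_count


def ellipse_area(length: float, width: float) -> float:
    """Ellipse area from full length and width: π·(L/2)·(W/2), mm²."""
    if length <= 0 or width <= 0:
        raise InvalidArgumentError("length and width must be > 0")
    return math.pi * (length / 2.0) * (width / 2.0)


def daily_light_integral(ppfd: float, photoperiod_h: float) -> float:
    """DLI in mol m⁻² day⁻¹ from PPFD (µmol m⁻² s⁻¹) and photoperiod (h)."""
    if ppfd < 0:
        raise InvalidArgumentError("ppfd must be >= 0")
    if not (0.0 <= photoperiod_h <= 24.0):
        raise InvalidArgumentError("photoperiod must be within 0-24 h")
    return ppfd * photoperiod_h * 3600.0 * 1e-6


def frond_mass_area(dm: float, area: float) -> float:
    """Frond mass-to-area ratio FMA = DM/area, mg cm⁻²."""
    if area <= 0:
        raise InvalidArgumentError("area must be > 0")
    if dm < 0:
        raise InvalidArgumentError("dry mass must be >= 0")
    return dm / area


def vessel_average(frond_values: Sequence[float]) -> float:
    """Arithmetic mean of per-frond values within one vessel."""
    if len(frond_values) == 0:
        raise InvalidArgumentError("cannot average an empty list")
    return float(np.mean(np.asarray(frond_values, dtype=float)))


def growth_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-vessel growth indices from a tidy counts table.

    ``counts`` must have columns ``vessel_id, day, frond_count, colony_count,
    senescent_count`` with a first- and last-day row per vessel. Returns one
    row per vessel with RGR, doubling time, day-7 colony size and senescence
    percentage.
    """
    required = {"vessel_id", "day", "frond_count", "colony_count", "senescent_count"}
    missing = required - set(counts.columns)
    if missing:
        raise InvalidArgumentError(f"counts table missing columns: {sorted(missing)}")
    rows = []
    for vessel, grp in counts.groupby("vessel_id", sort=True):
        grp = grp.sort_values("day")
        first, last = grp.iloc[0], grp.iloc[-1]
        obs0 = CultureObservation(str(vessel), int(first.day), int(first.frond_count),
                                  int(first.colony_count), int(first.senescent_count))
        obs7 = CultureObservation(str(vessel), int(last.day), int(last.frond_count),
                                  int(last.colony_count), int(last.senescent_count))
        rgr = relative_growth_rate(obs0, obs7)
        rows.append({
            "vessel_id": str(vessel),
            "rgr": rgr,
            "doubling_time_d": doubling_time(rgr),
            "colony_size": colony_size(obs7),
            "senescence_pct": senescence_percent(obs7),
        })
    return pd.DataFrame(rows)


def morphometry_summary(morpho: pd.DataFrame) -> pd.DataFrame:
    """Vessel-averaged frond length, width, ellipse area and roundness.

    ``morpho`` needs columns ``vessel_id, frond_id, length, width`` (mm).
    """
    records = [
        FrondMorphometry(str(r.vessel_id), str(r.frond_id), float(r.length), float(r.width))
        for r in morpho.itertuples()
    ]
    df = pd.DataFrame(
        {
            "vessel_id": [m.vessel_id for m in records],
            "length": [m.length for m in records],
            "width": [m.width for m in records],
            "area": [m.area for m in records],
            "roundness": [m.roundness for m in records],
        }
    )
    return df.groupby("vessel_id", sort=True).mean(numeric_only=True).reset_index()
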