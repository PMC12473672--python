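"""Photosynthetic pigment quantification and carotenoid-pool ratios.

Chlorophyll a, chlorophyll b and total carotenoids are computed from
80%-acetone extract absorbances (A470.0, A646.8, A663.2, with A750.0 as the
turbidity baseline) using the classic spectrophotometric equations for
0.1–0.5 nm band-pass instruments, then scaled to a fresh-mass basis.
Xanthophyll-cycle ratios (VAZ/Car, Z/VAZ) and Chl a/b are computed from
HPLC composition tables expressed in mmol pigment per mol Chl a+b.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InvalidArgumentError

# 80% acetone, 0.1-0.5 nm spectral resolution (ug mL^-1):
#   Chl a = 12.25 A663.2 - 2.79 A646.8
#   Chl b = 21.50 A646.8 - 5.10 A663.2
#   Car   = (1000 A470 - 1.82 Chl a - 85.02 Chl b) / 198
WELLBURN_80ACETONE_NARROW = {
    "chl_a": (12.25, -2.79),
    "chl_b": (-5.10, 21.50),
    "car": (1.82, 85.02, 198.0),
}

# approximate molar masses (g mol^-1) for optional molar-basis ratios
MOLAR_MASS = {"chl_a": 893.51, "chl_b": 907.49, "car": 570.9}


def _coefficient_matrix(coefficients: Mapping) -> np.ndarray:
    """3×3 matrix mapping [A663.2, A646.8, A470] to [chl_a, chl_b, car] (µg/mL)."""
    ca1, ca2 = coefficients["chl_a"]
    cb1, cb2 = coefficients["chl_b"]
    k_a, k_b, k_car = coefficients["car"]
    row_a = np.array([ca1, ca2, 0.0])
    row_b = np.array([cb1, cb2, 0.0])
    row_car = (-k_a * row_a - k_b * row_b + np.array([0.0, 0.0, 1000.0])) / k_car
    mat = np.vstack([row_a, row_b, row_car])
    if abs(np.linalg.det(mat)) < 1e-9:
        raise InvalidArgumentError("pigment coefficient matrix is singular")
    return mat


#: default matrix, validated (invertible) at import time
_DEFAULT_MATRIX = _coefficient_matrix(WELLBURN_80ACETONE_NARROW)


@dataclass
class PigmentExtract:
    """Absorbances of one acetone extract plus sample mass and volume."""

    a470: float
    a646_8: float
    a663_2: float
    a750: float
    fresh_mass: float  # mg
    extract_volume: float  # mL
    sample_id: str = ""

    def __post_init__(self):
        if min(self.a470, self.a646_8, self.a663_2, self.a750) < 0:
            raise InvalidArgumentError("absorbances must be >= 0")
        if self.fresh_mass <= 0 or self.extract_volume <= 0:
            raise InvalidArgumentError("fresh_mass and extract_volume must be > 0")


def pigment_concentrations(
    extract: PigmentExtract,
    coefficients: Mapping = WELLBURN_80ACETONE_NARROW,
) -> tuple[float, float, float]:
    """(Chl a, Chl b, Car) in µg per g fresh mass.

    Each analytical absorbance is first baseline-corrected by subtracting
    A750, the equation system is applied to get µg mL⁻¹, and the result is
    scaled by extract volume over fresh mass.
    """
    corrected = np.array(
        [extract.a663_2 - extract.a750,
         extract.a646_8 - extract.a750,
         extract.a470 - extract.a750]
    )
    if extract.a663_2 <= extract.a750 or extract.a646_8 <= extract.a750:
        if not np.allclose(corrected, 0.0):
            raise InvalidArgumentError(
                "analytical absorbances must exceed the A750 turbidity baseline"
            )
    if np.any(corrected < -1e-12):
        raise InvalidArgumentError("negative baseline-corrected absorbance")
    mat = _coefficient_matrix(coefficients) if coefficients is not WELLBURN_80ACETONE_NARROW \
        else _DEFAULT_MATRIX
    ug_per_ml = mat @ np.clip(corrected, 0.0, None)
    if np.any(ug_per_ml < -1e-9):
        raise InvalidArgumentError("pigment equations returned a negative concentration")
    fresh_mass_g = extract.fresh_mass / 1000.0
    chl_a, chl_b, car = np.clip(ug_per_ml, 0.0, None) * extract.extract_volume / fresh_mass_g
    return float(chl_a), float(chl_b), float(car)


def absorbances_from_concentrations(
    chl_a: float, chl_b: float, car: float,
    coefficients: Mapping = WELLBURN_80ACETONE_NARROW,
) -> tuple[float, float, float]:
    """Invert the equation system: (A663.2, A646.8, A470) for µg mL⁻¹ inputs.

    Used by the synthetic generator to produce Beer–Lambert-consistent
    absorbance tables from ground-truth concentrations.
    """
    mat = _coefficient_matrix(coefficients)
    a = np.linalg.solve(mat, np.array([chl_a, chl_b, car], dtype=float))
    return float(a[0]), float(a[1]), float(a[2])


@dataclass
class CarotenoidComposition:
    """HPLC carotenoid pools, mmol pigment (mol Chl a+b)⁻¹."""

    violaxanthin: float
    antheraxanthin: float
    zeaxanthin: float
    other_car: float
    sample_id: str = ""

    def __post_init__(self):
        if min(self.violaxanthin, self.antheraxanthin, self.zeaxanthin, self.other_car) < 0:
            raise InvalidArgumentError("pigment pools must be >= 0")

    @property
    def vaz(self) -> float:
        return self.violaxanthin + self.antheraxanthin + self.zeaxanthin

    @property
    def total_car(self) -> float:
        return self.vaz + self.other_car


@dataclass(frozen=True)
class PigmentRatios:
    """Chl a/b, Car/(Chl a+b) on mass and molar bases, VAZ/Car and Z/VAZ.

    ``z_vaz`` is None (undefined, never silently zero) when the VAZ pool is
    empty; ``vaz_car`` likewise when there are no carotenoids.
    """

    chl_a_b: float
    car_chl_mass: float
    car_chl_molar: float
    vaz_car: float | None
    z_vaz: float | None


def pigment_ratios(
    comp: CarotenoidComposition, chl_a: float, chl_b: float, car: float
) -> PigmentRatios:
    """Pigment-pool ratios from mass concentrations + an HPLC composition."""
    if chl_b <= 0:
        raise InvalidArgumentError("chl_b must be > 0 for the Chl a/b ratio")
    if chl_a < 0 or car < 0:
        raise InvalidArgumentError("concentrations must be >= 0")
    chl_ab = chl_a + chl_b
    car_chl_mass = car / chl_ab
    chl_mol = chl_a / MOLAR_MASS["chl_a"] + chl_b / MOLAR_MASS["chl_b"]
    car_chl_molar = (car / MOLAR_MASS["car"]) / chl_mol
    vaz_car = comp.vaz / comp.total_car if comp.total_car > 0 else None
    z_vaz = comp.zeaxanthin / comp.vaz if comp.vaz > 0 else None
    return PigmentRatios(
        chl_a_b=chl_a / chl_b,
        car_chl_mass=car_chl_mass,
        car_chl_molar=car_chl_molar,
        vaz_car=vaz_car,
        z_vaz=z_vaz,
    )
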