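"""Ground-truth parameter sets for one duckweed clone under one light regime.

A :class:`CloneLightParams` instance holds everything the synthetic-data
generators need to emulate a clone × light combination of the study design:
the exponential frond-number growth rate, frond geometry, the within-frond
Y(II) maturation model, rapid-light-curve truth, pigment concentrations and
per-channel noise. Parameter sets round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

from .errors import InvalidArgumentError

LIGHT_LEVELS = ("low", "high")


@dataclass
class CloneLightParams:
    """Generator truth for one clone under one light level.

    Parameters
    ----------
    clone_id:
        Accession label (4-level factor in the study design).
    light_level:
        ``"low"`` or ``"high"`` (100 vs 243 µmol m⁻² s⁻¹ PPFD regimes).
    rgr_true:
        Relative growth rate of frond number, day⁻¹.
    frond_length_mean:
        Mean mature frond length, mm.
    length_width_ratio:
        Frond length/width (roundness), ≥ 1; 1 is a circular frond.
    fma_true:
        Frond dry-mass-to-area ratio, mg cm⁻².
    yii_young, yii_mature:
        Effective PSII yield Y(II) of a 1 mm frond and of a fully mature
        frond, respectively; 0 < yii_young ≤ yii_mature < 1.
    ynpq_share:
        Fraction of the non-photochemical loss (1 − Y(II)) that is regulated
        (goes to Y(NPQ) rather than Y(NO)).
    alpha_true:
        Initial slope of the rapid light curve, e⁻ photon⁻¹.
    retrmax_true:
        Plateau of the rapid light curve, µmol e⁻ m⁻² s⁻¹.
    chl_a_true, chl_b_true, car_true:
        Pigment concentrations, µg per g fresh mass.
    noise_sd:
        Per-channel Gaussian noise level used by the generators
        (dimensionless fraction; see each generator's docstring).
    fv_fm_true:
        Dark-adapted maximal PSII yield used when synthesising quenching
        records and OJIP landmark sets.
    maturation_l50_mm, maturation_scale_mm:
        Midpoint and scale (mm) of the logistic Y(II)-vs-length maturation
        term.
    gradient_amp:
        Peak base→tip Y(II) difference of the basipetal axial term.
    gradient_onset_mm:
        Frond length (mm) at which the axial gradient starts to appear.
    colony_size_mean:
        Mean fronds per colony used when drawing colony counts.
    senescence_rate:
        Per-frond probability of showing senescence (yellowing).
    length_cv:
        Coefficient of variation of drawn frond lengths around
        ``frond_length_mean``.
    """

    clone_id: str
    light_level: str
    rgr_true: float
    frond_length_mean: float
    length_width_ratio: float
    fma_true: float
    yii_young: float
    yii_mature: float
    ynpq_share: float
    alpha_true: float
    retrmax_true: float
    chl_a_true: float
    chl_b_true: float
    car_true: float
    noise_sd: float = 0.02
    fv_fm_true: float = 0.80
    maturation_l50_mm: float = 2.5
    maturation_scale_mm: float = 0.6
    gradient_amp: float = 0.08
    gradient_onset_mm: float = 2.5
    colony_size_mean: float = 3.0
    senescence_rate: float = 0.05
    length_cv: float = 0.35

    def __post_init__(self) -> None:
        if self.light_level not in LIGHT_LEVELS:
            raise InvalidArgumentError(
                f"light_level must be one of {LIGHT_LEVELS}, got {self.light_level!r}"
            )
        if not (0.0 < self.yii_young <= self.yii_mature < 1.0):
            raise InvalidArgumentError(
                "require 0 < yii_young <= yii_mature < 1, got "
                f"({self.yii_young}, {self.yii_mature})"
            )
        if self.rgr_true < 0:
            raise InvalidArgumentError("rgr_true must be >= 0")
        if self.alpha_true <= 0 or self.retrmax_true <= 0:
            raise InvalidArgumentError("alpha_true and retrmax_true must be > 0")
        if not (0.0 <= self.ynpq_share <= 1.0):
            raise InvalidArgumentError("ynpq_share must be in [0, 1]")
        if self.length_width_ratio < 1.0:
            raise InvalidArgumentError("length_width_ratio must be >= 1")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if not (0.0 < self.fv_fm_true < 1.0):
            raise InvalidArgumentError("fv_fm_true must be in (0, 1)")

    @property
    def key(self) -> str:
        return f"{self.clone_id}_{self.light_level}"

    def replace(self, **changes) -> "CloneLightParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CloneLightParams":
        return cls(**d)


def dump_params(params: Iterable[CloneLightParams], path: str | Path) -> None:
    """Write a list of parameter sets to YAML (lossless round-trip)."""
    payload = {"clones": [p.to_dict() for p in params]}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_params(path: str | Path) -> list[CloneLightParams]:
    """Read parameter sets from a YAML file written by :func:`dump_params`."""
    payload = yaml.safe_load(Path(path).read_text())
    return [CloneLightParams.from_dict(d) for d in payload["clones"]]


def default_clone_set() -> list[CloneLightParams]:
    """The demo study design: four L. gibba clones under two light regimes.

    Growth rates span 0.36–0.55 day⁻¹ with the slowest combination being the
    tetraploid clone under low light and the fastest a diploid under high
    light; one clone (UD0102) shows no light response in growth. Y(II)
    ontogeny truth follows the observed bands: under high light, 1 mm fronds
    near 0.43–0.48 rising to 0.54–0.56 at maturity; under low light 0.51–0.61
    rising to 0.66–0.68. The tetraploid has the highest mass-to-area ratio
    and a larger regulated-quenching share.
    """
    rows: list[CloneLightParams] = []

    def add(clone, light, rgr, L, lw, fma, yy, ym, share, alpha, retr, ca, cb, car):
        rows.append(
            CloneLightParams(
                clone_id=clone, light_level=light, rgr_true=rgr,
                frond_length_mean=L, length_width_ratio=lw, fma_true=fma,
                yii_young=yy, yii_mature=ym, ynpq_share=share,
                alpha_true=alpha, retrmax_true=retr,
                chl_a_true=ca, chl_b_true=cb, car_true=car,
            )
        )

    # clone        light   rgr    L    l/w  fma   y_yng y_mat shr  alpha retr  chla chlb car
    add("UD0102", "low", 0.470, 4.2, 1.60, 2.4, 0.55, 0.67, 0.45, 0.30, 42.0, 950, 340, 210)
    add("UD0102", "high", 0.472, 3.8, 1.65, 2.9, 0.45, 0.55, 0.55, 0.27, 68.0, 780, 260, 205)
    add("UD0106", "low", 0.480, 4.0, 1.60, 2.3, 0.57, 0.66, 0.45, 0.30, 45.0, 980, 350, 215)
    add("UD0106", "high", 0.550, 3.6, 1.65, 2.7, 0.46, 0.56, 0.55, 0.27, 75.0, 800, 270, 210)
    add("MJ201", "low", 0.440, 4.8, 1.40, 2.1, 0.51, 0.66, 0.45, 0.29, 40.0, 820, 300, 185)
    add("MJ201", "high", 0.500, 4.3, 1.45, 2.5, 0.43, 0.54, 0.55, 0.26, 70.0, 690, 235, 180)
    add("9602", "low", 0.360, 5.0, 1.35, 3.4, 0.61, 0.68, 0.60, 0.31, 38.0, 720, 265, 170)
    add("9602", "high", 0.420, 4.5, 1.40, 4.0, 0.48, 0.56, 0.65, 0.26, 65.0, 700, 240, 175)
    return rows
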