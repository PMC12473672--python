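"""Slow-kinetics quenching analysis and rapid-light-curve (RLC) fitting.

The light-adapted PSII excitation budget is partitioned into three yields
that sum to one: photochemistry Y(II) = (Fm′−F)/Fm′, regulated
non-photochemical quenching Y(NPQ) = F/Fm′ − F/Fm, and non-regulated losses
Y(NO) = F/Fm. The electron transport rate follows
ETR = Y(II)·PPFD·0.5·0.84, and its irradiance dependence is summarised by
fitting the exponential rise-to-maximum ETR(I) = a·(1 − exp(−b·I)), from
which α = a·b (initial slope), rETRmax = a and Ek = 1/b = rETRmax/α.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    DegenerateTransientError,
    FitFailureError,
    InconsistentRecordError,
    InvalidArgumentError,
)

PSII_FRACTION = 0.5  # assumed excitation split between the two photosystems
ABSORPTANCE = 0.84  # empirical leaf light-absorption efficiency


@dataclass(frozen=True)
class QuenchingRecord:
    """One slow-kinetics record: F0, Fm (dark) and F, Fm′ (light-adapted)."""

    fo: float
    fm: float
    f: float
    fm_prime: float
    actinic_ppfd: float = 0.0
    sample_id: str = ""

    def __post_init__(self):
        if min(self.fo, self.fm, self.f, self.fm_prime) <= 0:
            raise InvalidArgumentError("fluorescence levels must be > 0")
        if self.fo >= self.fm:
            raise InconsistentRecordError("require fo < fm")
        if self.f > self.fm_prime * (1 + 1e-12):
            raise InconsistentRecordError("require f <= fm_prime")
        if self.fm_prime > self.fm * (1 + 1e-12):
            raise InconsistentRecordError("require fm_prime <= fm")


def quenching_partition(record: QuenchingRecord) -> tuple[float, float, float]:
    """(Y(II), Y(NPQ), Y(NO)) for one record; the three yields sum to 1."""
    y_ii = (record.fm_prime - record.f) / record.fm_prime
    y_no = record.f / record.fm
    y_npq = record.f / record.fm_prime - record.f / record.fm
    return y_ii, y_npq, y_no


def fv_fm(fo: float, fm: float) -> float:
    """Dark-adapted maximal PSII yield, (Fm − F0)/Fm."""
    if not (fm > fo > 0):
        raise DegenerateTransientError("require fm > fo > 0")
    return (fm - fo) / fm


def electron_transport_rate(
    y_ii: float | np.ndarray,
    ppfd: float | np.ndarray,
    psii_fraction: float = PSII_FRACTION,
    absorptance: float = ABSORPTANCE,
) -> float | np.ndarray:
    """ETR = Y(II)·PPFD·psii_fraction·absorptance, µmol e⁻ m⁻² s⁻¹."""
    y = np.asarray(y_ii, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise InvalidArgumentError("y_ii must lie in [0, 1]")
    if np.any(np.asarray(ppfd) < 0):
        raise InvalidArgumentError("ppfd must be >= 0")
    out = y * np.asarray(ppfd, dtype=float) * psii_fraction * absorptance
    return float(out) if out.ndim == 0 else out


@dataclass
class RapidLightCurve:
    """Stepped-irradiance Y(II)/ETR series, optionally carrying its fit."""

    ppfd_steps: np.ndarray
    y_ii_steps: np.ndarray
    etr_steps: np.ndarray | None = None
    sample_id: str = ""

    def __post_init__(self):
        self.ppfd_steps = np.asarray(self.ppfd_steps, dtype=float)
        self.y_ii_steps = np.asarray(self.y_ii_steps, dtype=float)
        if self.ppfd_steps.shape != self.y_ii_steps.shape:
            raise InvalidArgumentError("ppfd and y_ii must have equal length")
        if self.etr_steps is None:
            self.etr_steps = electron_transport_rate(
                np.clip(self.y_ii_steps, 0.0, 1.0), self.ppfd_steps
            )
        else:
            self.etr_steps = np.asarray(self.etr_steps, dtype=float)


@dataclass(frozen=True)
class RLCFit:
    """Fitted RLC parameters with least-squares diagnostics."""

    alpha: float  # e- photon^-1, initial slope
    retrmax: float  # umol e- m^-2 s^-1, plateau
    ek: float  # umol m^-2 s^-1, = retrmax/alpha
    rss: float
    converged: bool
    saturation_reached: bool


def _rise_to_max(i, log_a, log_b):
    # optimizer excursions can overflow exp(); clamped values keep the
    # objective finite so the search recovers
    a = np.exp(np.clip(log_a, -50.0, 50.0))
    b = np.exp(np.clip(log_b, -50.0, 50.0))
    return a * (1.0 - np.exp(-b * i))


def fit_rlc(curve: RapidLightCurve, max_restarts: int = 5) -> RLCFit:
    """Least-squares fit of ETR(I) = a·(1 − e^{−b·I}).

    Positivity of both parameters is enforced by fitting in log space.
    Initialisation: a at the largest observed ETR, b from the initial slope
    over the first non-zero steps. When the fitted curve stays essentially
    linear over the measured range (b·Imax small), ``saturation_reached`` is
    False and the plateau estimate should not be trusted.
    """
    order = np.argsort(curve.ppfd_steps, kind="stable")
    i_steps = curve.ppfd_steps[order]
    etr = curve.etr_steps[order]
    if np.unique(i_steps).size < 5 or i_steps[0] != 0.0:
        raise InvalidArgumentError("need >= 5 distinct irradiance steps including 0")
    if np.allclose(etr, 0.0):
        raise DegenerateTransientError("all-zero ETR curve cannot be fitted")

    a0 = max(float(np.max(etr)), 1e-9)
    nz = i_steps > 0
    slope0 = float(etr[nz][0] / i_steps[nz][0])
    b0 = max(slope0 / a0, 1e-6)

    last_err: Exception | None = None
    rng = np.random.default_rng(0)  # deterministic restart jitter
    for attempt in range(max_restarts):
        jitter = 1.0 if attempt == 0 else float(np.exp(rng.normal(0, 0.5)))
        p0 = (np.log(a0 * (1.05 * jitter)), np.log(b0 * jitter))
        try:
            popt, _ = curve_fit(_rise_to_max, i_steps, etr, p0=p0, maxfev=20000)
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            last_err = exc
            continue
        a, b = float(np.exp(popt[0])), float(np.exp(popt[1]))
        resid = etr - _rise_to_max(i_steps, *popt)
        return RLCFit(
            alpha=a * b,
            retrmax=a,
            ek=1.0 / b,
            rss=float(np.sum(resid**2)),
            converged=True,
            saturation_reached=bool(b * i_steps[-1] > 1.0),
        )
    raise FitFailureError(
        "RLC fit failed to converge", diagnostics={"restarts": max_restarts, "error": str(last_err)}
    )


def analyze_quenching_table(records: pd.DataFrame) -> pd.DataFrame:
    """Yield partition + Fv/Fm + ETR for a CSV-shaped quenching table.

    Expects columns ``fo, fm, f, fm_prime, actinic_ppfd`` (and optionally
    ``sample_id``).
    """
    rows = []
    for r in records.itertuples():
        rec = QuenchingRecord(
            fo=float(r.fo), fm=float(r.fm), f=float(r.f), fm_prime=float(r.fm_prime),
            actinic_ppfd=float(getattr(r, "actinic_ppfd", 0.0)),
            sample_id=str(getattr(r, "sample_id", "")),
        )
        y_ii, y_npq, y_no = quenching_partition(rec)
        rows.append({
            "sample_id": rec.sample_id,
            "fv_fm": fv_fm(rec.fo, rec.fm),
            "y_ii": y_ii, "y_npq": y_npq, "y_no": y_no,
            "etr": electron_transport_rate(y_ii, rec.actinic_ppfd),
        })
    return pd.DataFrame(rows)


def fit_rlc_table(rlc: pd.DataFrame) -> pd.DataFrame:
    """Fit every sample of a long-format RLC table (sample_id, ppfd, y_ii)."""
    rows = []
    for sid, grp in rlc.groupby("sample_id", sort=True):
        curve = RapidLightCurve(grp["ppfd"].to_numpy(), grp["y_ii"].to_numpy(), sample_id=str(sid))
        fit = fit_rlc(curve)
        rows.append({
            "sample_id": str(sid), "alpha": fit.alpha, "retrmax": fit.retrmax,
            "ek": fit.ek, "rss": fit.rss, "converged": fit.converged,
            "saturation_reached": fit.saturation_reached,
        })
    return pd.DataFrame(rows)
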