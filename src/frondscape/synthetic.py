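"""Synthetic-data generators with known ground truth.

Every input the analysis stages consume can be generated here with known
parameters, so each stage is testable by parameter recovery:

* exponential frond-number growth series with Poisson/binomial count noise,
* monotone OJIP transients passing exactly through configurable landmarks,
* saturating rapid light curves with Gaussian noise,
* internally consistent quenching records from target yield triplets,
* Beer–Lambert-consistent pigment-extract absorbance tables,
* 640×480 chlorophyll-fluorescence parameter scenes (Y(II)/Y(NPQ)/Y(NO)
  rasters + label mask + base/tip anchors) with a size-dependent, basipetal
  Y(II) maturation gradient.

Randomness: a single integer master seed; each generator draws from an
independent stream derived from the master seed and a fixed per-generator
offset, so adding draws to one generator never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.interpolate import PchipInterpolator
from skimage.draw import ellipse as draw_ellipse

from .errors import InvalidArgumentError, PlacementError
from .ojip import OJIPTransient
from .params import CloneLightParams
from .pigments import PigmentExtract, absorbances_from_concentrations
from .quenching import (
    ABSORPTANCE,
    PSII_FRACTION,
    QuenchingRecord,
    RapidLightCurve,
)

#: fixed per-generator stream offsets (master seed, offset) -> stream
_STREAMS = {
    "growth": 11,
    "ojip": 23,
    "rlc": 37,
    "quenching": 41,
    "pigments": 53,
    "scene": 67,
}

#: Imaging-PAM-like 13-step actinic ladder, 0-700 umol m^-2 s^-1
DEFAULT_RLC_STEPS = np.array(
    [0.0, 11.0, 21.0, 36.0, 56.0, 81.0, 111.0, 146.0, 186.0, 231.0, 336.0, 531.0, 700.0]
)

DEFAULT_SCENE_SHAPE = (480, 640)  # rows, cols
DEFAULT_SCALE = 4.6  # pixels per mm
BACKGROUND = -1.0  # sentinel value in parameter rasters


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent per-generator RNG stream for one master seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, _STREAMS[stream]])


# ---------------------------------------------------------------------------
# growth series
# ---------------------------------------------------------------------------

def simulate_growth_series(
    params: CloneLightParams,
    fn0: int,
    days: int,
    seed: int,
    noise: bool = True,
) -> pd.DataFrame:
    """Daily frond/colony/senescent counts of one vessel.

    The expected frond count follows fn0·exp(rgr_true·day). With ``noise``
    the daily count is Poisson around that mean (kept non-decreasing is not
    enforced in noise mode), colony counts follow the configured mean colony
    size with binomial jitter, and senescent counts are binomial with the
    clone's senescence rate. Noise-free output is the rounded expectation.
    """
    if fn0 < 1 or days < 1:
        raise InvalidArgumentError("fn0 and days must be >= 1")
    rng = stream_rng(seed, "growth")
    day = np.arange(days + 1)
    mean = fn0 * np.exp(params.rgr_true * day)
    if noise:
        fn = np.maximum(1, rng.poisson(mean))
    else:
        fn = np.round(mean).astype(int)
    # colonies: mean colony size fronds per colony
    cn_mean = np.maximum(1.0, fn / params.colony_size_mean)
    if noise:
        cn = np.clip(rng.poisson(cn_mean), 1, fn)
    else:
        cn = np.clip(np.round(cn_mean).astype(int), 1, fn)
    if noise:
        sen = rng.binomial(fn, params.senescence_rate)
    else:
        sen = np.round(fn * params.senescence_rate).astype(int)
    return pd.DataFrame(
        {"day": day, "frond_count": fn, "colony_count": cn, "senescent_count": sen}
    )


# ---------------------------------------------------------------------------
# OJIP transient
# ---------------------------------------------------------------------------

def simulate_ojip(
    f0: float,
    fj: float,
    fi: float,
    fm: float,
    seed: int = 0,
    noise_sd: float = 0.0,
    t_fm: float = 0.3,
    n_points: int = 140,
    sample_id: str = "",
) -> OJIPTransient:
    """Monotone OJIP transient through the requested landmarks.

    The rise is a monotone piecewise-cubic (PCHIP) interpolation in
    log-time over knots at (50 µs, F0), (2 ms, FJ), (30 ms, FI) and
    (``t_fm``, Fm), flat before 50 µs and after the peak, sampled on a
    logarithmic grid from 10 µs to 2 s that contains the canonical landmark
    times exactly. ``noise_sd`` is a relative (multiplicative) Gaussian sd.
    """
    if not (f0 < fj <= fi <= fm):
        raise InvalidArgumentError(
            f"landmarks must satisfy f0 < fj <= fi <= fm, got ({f0}, {fj}, {fi}, {fm})"
        )
    if f0 <= 0:
        raise InvalidArgumentError("f0 must be > 0")
    if not (30e-3 < t_fm <= 2.0):
        raise InvalidArgumentError("t_fm must lie in (30 ms, 2 s]")
    if t_fm < 2.0:
        knots_t = np.array([1e-5, 50e-6, 2e-3, 30e-3, t_fm, 2.0])
        knots_f = np.array([f0, f0, fj, fi, fm, fm], dtype=float)
    else:  # peak at the very end of the pulse
        knots_t = np.array([1e-5, 50e-6, 2e-3, 30e-3, 2.0])
        knots_f = np.array([f0, f0, fj, fi, fm], dtype=float)
    interp = PchipInterpolator(np.log10(knots_t), knots_f)
    grid = np.unique(
        np.concatenate(
            [np.geomspace(1e-5, 2.0, n_points), [50e-6, 300e-6, 2e-3, 30e-3, t_fm]]
        )
    )
    f = interp(np.log10(grid))
    if noise_sd > 0:
        rng = stream_rng(seed, "ojip")
        f = f * (1.0 + rng.normal(0.0, noise_sd, size=f.shape))
        f = np.clip(f, 0.0, None)
    return OJIPTransient(grid, f, sample_id=sample_id)


def ojip_landmarks_for(params: CloneLightParams) -> tuple[float, float, float, float]:
    """Plausible (F0, FJ, FI, Fm) for a clone×light truth set.

    Fm is fixed at 3000 AU; F0 follows the clone's dark-adapted Fv/Fm;
    J and I steps are placed at relative variable fluorescence 0.45 / 0.75.
    """
    fm = 3000.0
    f0 = fm * (1.0 - params.fv_fm_true)
    fj = f0 + 0.45 * (fm - f0)
    fi = f0 + 0.75 * (fm - f0)
    return f0, fj, fi, fm


# ---------------------------------------------------------------------------
# rapid light curve
# ---------------------------------------------------------------------------

def simulate_rlc(
    alpha_true: float,
    retrmax_true: float,
    ppfd_steps: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "",
) -> RapidLightCurve:
    """Saturating ETR-vs-PPFD curve with Gaussian noise.

    ETR(I) = rETRmax·(1 − exp(−α·I/rETRmax)); the additive Gaussian noise sd
    is ``noise_sd × rETRmax`` (i.e. noise_sd is a fraction of the plateau).
    Y(II) is back-computed per step from the noisy ETR via
    Y(II) = ETR/(I·0.5·0.84), using the α-limit at I = 0.
    """
    if ppfd_steps is None:
        ppfd_steps = DEFAULT_RLC_STEPS.copy()
    ppfd_steps = np.asarray(ppfd_steps, dtype=float)
    if ppfd_steps[0] != 0.0 or np.any(np.diff(ppfd_steps) <= 0):
        raise InvalidArgumentError("ppfd steps must be strictly increasing from 0")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    if alpha_true <= 0 or retrmax_true <= 0:
        raise InvalidArgumentError("alpha_true and retrmax_true must be > 0")
    etr = retrmax_true * (1.0 - np.exp(-alpha_true * ppfd_steps / retrmax_true))
    if noise_sd > 0:
        rng = stream_rng(seed, "rlc")
        etr = etr + rng.normal(0.0, noise_sd * retrmax_true, size=etr.shape)
    scale = PSII_FRACTION * ABSORPTANCE
    with np.errstate(divide="ignore", invalid="ignore"):
        y_ii = np.where(ppfd_steps > 0, etr / (ppfd_steps * scale), alpha_true / scale)
    return RapidLightCurve(ppfd_steps, np.clip(y_ii, 0.0, 1.0), etr_steps=etr,
                           sample_id=sample_id)


# ---------------------------------------------------------------------------
# quenching records
# ---------------------------------------------------------------------------

def simulate_quenching(
    y_ii: float,
    y_npq: float,
    fv_fm_true: float = 0.8,
    fm: float = 1000.0,
    actinic_ppfd: float = 0.0,
    sample_id: str = "",
) -> QuenchingRecord:
    """A raw-fluorescence record whose partition equals the target yields.

    Given Y(II), Y(NPQ) (with Y(NO) the remainder): F = Y(NO)·Fm and
    Fm′ = F/(Y(NO)+Y(NPQ)), so the yield identities invert exactly.
    """
    y_no = 1.0 - y_ii - y_npq
    if min(y_ii, y_npq) < 0 or y_no <= 0 or y_ii >= 1:
        raise InvalidArgumentError("need yields in [0,1) with positive Y(NO) remainder")
    f = y_no * fm
    fm_prime = f / (y_no + y_npq)
    fo = fm * (1.0 - fv_fm_true)
    return QuenchingRecord(fo=fo, fm=fm, f=f, fm_prime=fm_prime,
                           actinic_ppfd=actinic_ppfd, sample_id=sample_id)


def random_quenching_records(n: int, seed: int) -> list[QuenchingRecord]:
    """``n`` valid records with Dirichlet-distributed yield triplets."""
    rng = stream_rng(seed, "quenching")
    yields = rng.dirichlet([4.0, 2.0, 2.0], size=n)  # (y_ii, y_npq, y_no)
    out = []
    for k, (y_ii, y_npq, y_no) in enumerate(yields):
        fvfm = rng.uniform(0.6, 0.85)
        out.append(simulate_quenching(y_ii, y_npq, fv_fm_true=fvfm, sample_id=f"q{k}"))
    return out


# ---------------------------------------------------------------------------
# pigment extracts
# ---------------------------------------------------------------------------

def simulate_pigment_extract(
    params: CloneLightParams,
    fresh_mass_mg: float = 30.0,
    extract_volume_ml: float = 2.0,
    a750: float = 0.01,
    seed: int = 0,
    noise: bool = True,
    sample_id: str = "",
) -> PigmentExtract:
    """Absorbance record consistent with the clone's true pigment contents.

    True µg g⁻¹ fresh-mass concentrations are converted to µg mL⁻¹ for the
    given sample mass and extract volume, the pigment equation system is
    inverted to absorbances, the A750 turbidity baseline is added, and
    (optionally) relative Gaussian noise of sd ``params.noise_sd`` applied
    to the true concentrations before inversion.
    """
    rng = stream_rng(seed, "pigments")
    conc_fm = np.array([params.chl_a_true, params.chl_b_true, params.car_true], float)
    if noise and params.noise_sd > 0:
        conc_fm = conc_fm * np.exp(rng.normal(0.0, params.noise_sd, size=3))
    ug_per_ml = conc_fm * (fresh_mass_mg / 1000.0) / extract_volume_ml
    a663, a646, a470 = absorbances_from_concentrations(*ug_per_ml)
    return PigmentExtract(
        a470=a470 + a750, a646_8=a646 + a750, a663_2=a663 + a750, a750=a750,
        fresh_mass=fresh_mass_mg, extract_volume=extract_volume_ml, sample_id=sample_id,
    )


def simulate_carotenoid_composition(
    params: CloneLightParams, seed: int = 0, noise: bool = True
) -> dict[str, float]:
    """HPLC pool sizes (mmol / mol Chl a+b) consistent with the light regime.

    High-light truth carries a larger VAZ pool and de-epoxidation state
    (more zeaxanthin), the standard xanthophyll-cycle response.
    """
    rng = stream_rng(seed, "pigments")
    high = params.light_level == "high"
    vaz = 60.0 if high else 38.0
    z_share = 0.35 if high else 0.12
    other = 210.0
    pools = {
        "violaxanthin": vaz * (1.0 - z_share) * 0.85,
        "antheraxanthin": vaz * (1.0 - z_share) * 0.15,
        "zeaxanthin": vaz * z_share,
        "other_car": other,
    }
    if noise and params.noise_sd > 0:
        pools = {k: v * float(np.exp(rng.normal(0, params.noise_sd)))
                 for k, v in pools.items()}
    return pools


# ---------------------------------------------------------------------------
# imaged scenes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScene:
    """Rendered parameter rasters + label mask + anchors for one vessel.

    ``parameter_images`` maps {"YII", "YNPQ", "YNO"} to float rasters in
    [0, 1] on foreground and ``BACKGROUND`` (−1) elsewhere; ``label_mask``
    is 0 on background and k on frond k; ``anchors`` maps frond id to
    base/tip pixel coordinates (row, col); ``scale`` is pixels per mm.
    """

    parameter_images: dict[str, np.ndarray]
    label_mask: np.ndarray
    anchors: dict[int, dict[str, tuple[int, int]]]
    scale: float = DEFAULT_SCALE
    lengths_mm: dict[int, float] = field(default_factory=dict)

    @property
    def frond_ids(self) -> list[int]:
        return sorted(self.anchors)


def yii_maturation(u, length_mm, params: CloneLightParams):
    """Ground-truth Y(II) at axial position ``u`` ∈ [0,1] (0 = base).

    Two terms: a logistic increase with frond length, renormalised so the
    value at 1 mm equals ``yii_young`` and the asymptote is ``yii_mature``,
    plus a basipetal axial gradient g·(u − 0.5) that ramps in linearly over
    1 mm beyond ``gradient_onset_mm`` (tips of longer fronds mature first).
    """
    u = np.asarray(u, dtype=float)
    L = np.asarray(length_mm, dtype=float)

    def sigm(x):
        return 1.0 / (1.0 + np.exp(-x))

    s0 = sigm((1.0 - params.maturation_l50_mm) / params.maturation_scale_mm)
    frac = (sigm((L - params.maturation_l50_mm) / params.maturation_scale_mm) - s0) / (1.0 - s0)
    frac = np.clip(frac, 0.0, 1.0)
    base = params.yii_young + (params.yii_mature - params.yii_young) * frac
    ramp = np.clip(L - params.gradient_onset_mm, 0.0, 1.0)
    yii = base + params.gradient_amp * (u - 0.5) * ramp
    return np.clip(yii, 0.01, 0.98)


def render_scene(
    params: CloneLightParams,
    n_fronds: int,
    seed: int,
    shape: tuple[int, int] = DEFAULT_SCENE_SHAPE,
    scale: float = DEFAULT_SCALE,
    min_length_mm: float = 1.0,
    max_retries_per_frond: int = 200,
) -> SyntheticScene:
    """Render non-overlapping elliptical fronds with yield rasters.

    Frond lengths are drawn from a normal distribution around
    ``frond_length_mean`` (CV ``length_cv``), truncated below at
    ``min_length_mm``; widths follow the clone's length-to-width ratio.
    Each frond is a randomly rotated ellipse; base/tip anchors sit at the
    major-axis endpoints just inside the mask. Foreground Y(II) follows
    :func:`yii_maturation` (+ per-pixel Gaussian noise of sd
    ``params.noise_sd``), Y(NPQ) = ynpq_share·(1−Y(II)) and Y(NO) the
    remainder, so the three rasters sum to exactly 1 on every foreground
    pixel.
    """
    if n_fronds < 1:
        raise InvalidArgumentError("n_fronds must be >= 1")
    rng = stream_rng(seed, "scene")
    rows, cols = shape
    label = np.zeros(shape, dtype=np.uint16)
    occupied = np.zeros(shape, dtype=bool)
    yii_img = np.full(shape, BACKGROUND, dtype=np.float64)
    anchors: dict[int, dict[str, tuple[int, int]]] = {}
    lengths: dict[int, float] = {}

    for k in range(1, n_fronds + 1):
        length_mm = float(
            np.clip(
                rng.normal(params.frond_length_mean,
                           params.length_cv * params.frond_length_mean),
                min_length_mm, 1.8 * params.frond_length_mean,
            )
        )
        a_px = max(length_mm * scale / 2.0, 1.5)  # semi-major, px
        b_px = max(a_px / params.length_width_ratio, 1.0)
        placed = False
        for _ in range(max_retries_per_frond):
            theta = rng.uniform(0.0, np.pi)
            margin = a_px + 2.0
            cr = rng.uniform(margin, rows - margin)
            cc = rng.uniform(margin, cols - margin)
            # skimage rotation is counter-clockwise about the column axis
            rr, cc_idx = draw_ellipse(cr, cc, a_px, b_px, shape=shape, rotation=theta)
            rr_pad, cc_pad = draw_ellipse(cr, cc, a_px + 1.5, b_px + 1.5,
                                          shape=shape, rotation=theta)
            if rr.size < 4 or occupied[rr_pad, cc_pad].any():
                continue
            # major axis direction for this rotation convention
            v = np.array([np.cos(theta), np.sin(theta)])
            center = np.array([cr, cc])
            base = center - (a_px - 1.2) * v
            tip = center + (a_px - 1.2) * v
            base_px = tuple(int(round(x)) for x in base)
            tip_px = tuple(int(round(x)) for x in tip)

            label[rr, cc_idx] = k
            occupied[rr_pad, cc_pad] = True

            def _inside(p):
                q = np.array(p, dtype=float)
                for _step in range(10):
                    pi = (int(round(q[0])), int(round(q[1])))
                    if 0 <= pi[0] < rows and 0 <= pi[1] < cols and label[pi] == k:
                        return pi
                    q = q + (center - q) * 0.25
                return (int(round(cr)), int(round(cc)))

            base_px, tip_px = _inside(base_px), _inside(tip_px)
            axis = np.array(tip_px, float) - np.array(base_px, float)
            axis_len = float(np.hypot(*axis))
            if axis_len < 1.0:
                label[rr, cc_idx] = 0
                occupied[rr_pad, cc_pad] = False
                continue
            pix = np.stack([rr, cc_idx], axis=1).astype(float)
            u = np.clip((pix - np.array(base_px, float)) @ (axis / axis_len) / axis_len, 0, 1)
            vals = yii_maturation(u, length_mm, params)
            if params.noise_sd > 0:
                vals = np.clip(vals + rng.normal(0, params.noise_sd, size=vals.shape),
                               0.01, 0.98)
            yii_img[rr, cc_idx] = vals
            anchors[k] = {"base": base_px, "tip": tip_px}
            lengths[k] = length_mm
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place frond {k}/{n_fronds} after {max_retries_per_frond} tries"
            )

    fg = label > 0
    ynpq_img = np.full(shape, BACKGROUND, dtype=np.float64)
    yno_img = np.full(shape, BACKGROUND, dtype=np.float64)
    ynpq_img[fg] = params.ynpq_share * (1.0 - yii_img[fg])
    yno_img[fg] = 1.0 - yii_img[fg] - ynpq_img[fg]
    return SyntheticScene(
        parameter_images={"YII": yii_img, "YNPQ": ynpq_img, "YNO": yno_img},
        label_mask=label, anchors=anchors, scale=scale, lengths_mm=lengths,
    )


def write_scene(scene: SyntheticScene, out_dir: str | Path, prefix: str = "scene") -> list[Path]:
    """Write rasters (32-bit float TIFF), mask (16-bit TIFF) and JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, img in scene.parameter_images.items():
        p = out / f"{prefix}_{name.lower()}.tif"
        tifffile.imwrite(p, img.astype(np.float32))
        written.append(p)
    pm = out / f"{prefix}_labels.tif"
    tifffile.imwrite(pm, scene.label_mask.astype(np.uint16))
    written.append(pm)
    sidecar = {
        "scale_px_per_mm": scene.scale,
        "anchors": {str(k): {"base": list(v["base"]), "tip": list(v["tip"])}
                    for k, v in scene.anchors.items()},
        "lengths_mm": {str(k): v for k, v in scene.lengths_mm.items()},
    }
    pj = out / f"{prefix}_anchors.json"
    pj.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    written.append(pj)
    return written


def read_scene(in_dir: str | Path, prefix: str = "scene") -> SyntheticScene:
    """Read a scene written by :func:`write_scene`."""
    d = Path(in_dir)
    images = {
        name: tifffile.imread(d / f"{prefix}_{name.lower()}.tif").astype(np.float64)
        for name in ("YII", "YNPQ", "YNO")
    }
    label = tifffile.imread(d / f"{prefix}_labels.tif").astype(np.uint16)
    sidecar = json.loads((d / f"{prefix}_anchors.json").read_text())
    anchors = {
        int(k): {"base": tuple(v["base"]), "tip": tuple(v["tip"])}
        for k, v in sidecar["anchors"].items()
    }
    lengths = {int(k): float(v) for k, v in sidecar.get("lengths_mm", {}).items()}
    return SyntheticScene(parameter_images=images, label_mask=label, anchors=anchors,
                          scale=float(sidecar["scale_px_per_mm"]), lengths_mm=lengths)
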