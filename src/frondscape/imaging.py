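"""Within-frond spatial analysis of chlorophyll-fluorescence parameter images.

Yield rasters (Y(II)/Y(NPQ)/Y(NO)) are sampled along straight base→tip
transects of each labelled frond, compiled into pixel-level and
frond-averaged databases, regressed against frond length (the ontogeny
trend), and pooled into size-ordered within-frond interpolation maps in
which overlapping pixels are reduced by their median and the largest,
under-populated size classes are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import griddata
from scipy.spatial import QhullError

from .errors import InsufficientDataError, InvalidArgumentError
from .synthetic import BACKGROUND, DEFAULT_SCALE, SyntheticScene

PARAMS = ("YII", "YNPQ", "YNO")

#: minimum transect length in pixels (>1.0 mm at 4.6 px/mm)
MIN_LENGTH_PX = 6.0


def px_to_mm(px: float | np.ndarray, scale: float = DEFAULT_SCALE):
    """Convert a pixel distance to mm at ``scale`` pixels per mm."""
    if scale <= 0:
        raise InvalidArgumentError("scale must be > 0")
    return np.asarray(px, dtype=float) / scale if np.ndim(px) else float(px) / scale


@dataclass
class FrondTransect:
    """Base→tip pixel profile of one frond.

    ``positions_px`` increases strictly from 0 (the base anchor); values are
    NaN where the sampling line crossed a background gap.
    """

    frond_id: int
    positions_px: np.ndarray
    values: dict[str, np.ndarray]
    scale: float = DEFAULT_SCALE
    positions_mm: np.ndarray = field(init=False)
    frond_length_px: float = field(init=False)
    frond_length_mm: float = field(init=False)

    def __post_init__(self):
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        if self.positions_px[0] != 0.0 or np.any(np.diff(self.positions_px) <= 0):
            raise InvalidArgumentError("positions must increase strictly from 0")
        self.positions_mm = self.positions_px / self.scale
        self.frond_length_px = float(self.positions_px[-1])
        self.frond_length_mm = self.frond_length_px / self.scale

    def frond_mean(self, param: str) -> float:
        """Mean over the transect's non-gap pixels for one parameter."""
        return float(np.nanmean(self.values[param]))

    @property
    def has_gap(self) -> bool:
        return bool(np.isnan(self.values["YII"]).any())


def extract_transect(scene: SyntheticScene, frond_id: int) -> FrondTransect:
    """Sample the parameter rasters along the frond's base→tip line.

    The straight segment between the anchors is walked at 1-px steps (the
    endpoint is always included) with nearest-pixel lookup, restricted to
    the frond's own label region; positions outside it are flagged as gaps
    (NaN values).
    """
    if frond_id not in scene.anchors:
        raise InvalidArgumentError(f"unknown frond id {frond_id}")
    base = np.array(scene.anchors[frond_id]["base"], dtype=float)
    tip = np.array(scene.anchors[frond_id]["tip"], dtype=float)
    label = scene.label_mask
    for name, p in (("base", base), ("tip", tip)):
        pi = (int(round(p[0])), int(round(p[1])))
        if not (0 <= pi[0] < label.shape[0] and 0 <= pi[1] < label.shape[1]) \
                or label[pi] != frond_id:
            raise InvalidArgumentError(
                f"{name} anchor {pi} of frond {frond_id} lies outside its mask"
            )
    dist = float(np.hypot(*(tip - base)))
    n_steps = int(np.floor(dist))
    positions = np.arange(n_steps + 1, dtype=float)
    if positions[-1] < dist:
        positions = np.append(positions, dist)
    direction = (tip - base) / dist
    pts = base[None, :] + positions[:, None] * direction[None, :]
    rr = np.clip(np.round(pts[:, 0]).astype(int), 0, label.shape[0] - 1)
    cc = np.clip(np.round(pts[:, 1]).astype(int), 0, label.shape[1] - 1)
    inside = label[rr, cc] == frond_id
    values = {}
    for name in PARAMS:
        img = scene.parameter_images[name]
        v = img[rr, cc].astype(float)
        v[~inside] = np.nan
        v[v == BACKGROUND] = np.nan
        values[name] = v
    return FrondTransect(frond_id=frond_id, positions_px=positions, values=values,
                         scale=scene.scale)


def extract_all_transects(
    scene: SyntheticScene, min_length_px: float = MIN_LENGTH_PX
) -> list[FrondTransect]:
    """All frond transects of a scene passing the minimum-length filter."""
    out = []
    for fid in scene.frond_ids:
        tr = extract_transect(scene, fid)
        if tr.frond_length_px >= min_length_px:
            out.append(tr)
    return out


def pixel_database(transects: list[FrondTransect]) -> pd.DataFrame:
    """Long-format pixel table (frond_id, pos_px, pos_mm, yii, ynpq, yno)."""
    frames = []
    for tr in transects:
        frames.append(pd.DataFrame({
            "frond_id": tr.frond_id,
            "pos_px": tr.positions_px,
            "pos_mm": tr.positions_mm,
            "yii": tr.values["YII"],
            "ynpq": tr.values["YNPQ"],
            "yno": tr.values["YNO"],
        }))
    if not frames:
        raise InsufficientDataError("no transects to compile")
    return pd.concat(frames, ignore_index=True)


def frond_average_table(transects: list[FrondTransect]) -> pd.DataFrame:
    """One row per frond: length + per-parameter transect means.

    Rows are ordered deterministically by frond length, then frond id.
    """
    if not transects:
        raise InsufficientDataError("no transects to average")
    rows = [
        {
            "frond_id": tr.frond_id,
            "frond_length_px": tr.frond_length_px,
            "frond_length_mm": tr.frond_length_mm,
            "n_px": int(np.sum(~np.isnan(tr.values["YII"]))),
            "mean_yii": tr.frond_mean("YII"),
            "mean_ynpq": tr.frond_mean("YNPQ"),
            "mean_yno": tr.frond_mean("YNO"),
        }
        for tr in transects
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["frond_length_mm", "frond_id"], kind="stable")
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class OntogenyFit:
    """OLS fit of a frond-mean parameter on frond length (mm)."""

    parameter: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float

    def predict(self, length_mm: float) -> float:
        return self.intercept + self.slope * length_mm


def ontogeny_regression(table: pd.DataFrame, parameter: str = "mean_yii") -> OntogenyFit:
    """Linear ontogeny trend of a frond-averaged parameter vs frond length."""
    x = table["frond_length_mm"].to_numpy(dtype=float)
    y = table[parameter].to_numpy(dtype=float)
    if np.unique(x).size < 3:
        raise InsufficientDataError("need >= 3 fronds with distinct lengths")
    if np.allclose(y, y[0]):
        return OntogenyFit(parameter=parameter, slope=0.0, intercept=float(y[0]),
                           r_squared=0.0, p_value=1.0)
    res = stats.linregress(x, y)
    return OntogenyFit(parameter=parameter, slope=float(res.slope),
                       intercept=float(res.intercept),
                       r_squared=float(res.rvalue**2), p_value=float(res.pvalue))


@dataclass
class OntogenyMap:
    """Size-ordered within-frond parameter map.

    ``medians`` holds per-cell medians of overlapping pixels on a (position
    × size-class) grid — NaN where no pixel contributed; ``interpolated``
    smooths the occupied region only (no extrapolation beyond the convex
    hull of contributing cells); ``counts`` records per-cell provenance.
    """

    parameter: str
    medians: np.ndarray  # (n_pos_bins, n_size_bins)
    interpolated: np.ndarray
    counts: np.ndarray
    position_bin_px: float
    bin_lengths_mm: list[float]  # mean frond length per retained size class
    bin_counts: list[int]  # fronds per retained size class
    excluded_bins: int


def build_ontogeny_map(
    transects: list[FrondTransect],
    parameter: str = "YII",
    size_bins: int = 8,
    min_per_bin: int = 3,
    position_bin_px: float = 1.0,
    max_excluded: int = 2,
) -> OntogenyMap:
    """Pool transect pixels into a size-rank × within-frond-position grid.

    Fronds are ranked by transect length (ties broken by frond id) and split
    into ``size_bins`` near-equal-count classes; pixels falling in the same
    (class, position) cell are reduced by their median; up to
    ``max_excluded`` of the largest classes are dropped while they hold
    fewer than ``min_per_bin`` fronds; the retained medians are smoothed by
    scattered cubic interpolation, which leaves cells outside the data hull
    missing.
    """
    if len(transects) < 5:
        raise InsufficientDataError("need >= 5 fronds surviving the length filter")
    ordered = sorted(transects, key=lambda t: (t.frond_length_px, t.frond_id))
    size_bins = min(size_bins, len(ordered))
    groups = [list(g) for g in np.array_split(np.array(ordered, dtype=object), size_bins)]
    excluded = 0
    while excluded < max_excluded and len(groups) > 1 and len(groups[-1]) < min_per_bin:
        groups.pop()
        excluded += 1
    if not groups:
        raise InsufficientDataError("no size classes remain after exclusion")

    max_pos = max(t.frond_length_px for g in groups for t in g)
    n_pos = int(np.floor(max_pos / position_bin_px)) + 1
    medians = np.full((n_pos, len(groups)), np.nan)
    counts = np.zeros((n_pos, len(groups)), dtype=int)
    for j, group in enumerate(groups):
        cell_pixels: dict[int, list[float]] = {}
        for tr in group:
            vals = tr.values[parameter]
            for pos, v in zip(tr.positions_px, vals):
                if np.isnan(v):
                    continue
                cell_pixels.setdefault(int(pos // position_bin_px), []).append(float(v))
        for i, pix in cell_pixels.items():
            medians[i, j] = float(np.median(pix))
            counts[i, j] = len(pix)

    occupied = ~np.isnan(medians)
    pts = np.argwhere(occupied).astype(float)
    vals = medians[occupied]
    grid_i, grid_j = np.mgrid[0:n_pos, 0:len(groups)]
    if pts.shape[0] >= 4 and np.unique(pts[:, 0]).size > 1 and np.unique(pts[:, 1]).size > 1:
        try:
            interp = griddata(pts, vals, (grid_i, grid_j), method="cubic")
        except QhullError:
            interp = medians.copy()
    else:
        interp = medians.copy()
    return OntogenyMap(
        parameter=parameter, medians=medians, interpolated=interp, counts=counts,
        position_bin_px=position_bin_px,
        bin_lengths_mm=[float(np.mean([t.frond_length_mm for t in g])) for g in groups],
        bin_counts=[len(g) for g in groups],
        excluded_bins=excluded,
    )
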