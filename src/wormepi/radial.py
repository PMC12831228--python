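"""Radial fluorescence profiling of single cells.

Given a multi-channel image of a cell (e.g. a C. elegans -2 oocyte with
a DAPI nuclear stain and an antibody signal channel) and a polygonal
cell outline, the profile is built from the nuclear center outward: the
center is the intensity-weighted centroid of the Otsu-thresholded
nuclear signal inside the ROI, and every ROI pixel gets a normalized
radius r = d(pixel, center) / d(center, boundary along the ray through
that pixel), so that any convex (more generally star-shaped) cell maps
onto r in [0, 1] regardless of its shape. Pixels are averaged in
equal-width r bins; curves are aggregated cell -> replicate -> group,
expressed relative to a negative control, and compared per bin with a
two-way ANOVA plus Bonferroni correction.

Ray-boundary intersections are computed exactly on the polygon (segment
intersection), not on a rasterized mask, to avoid staircase bias. An
absolute-distance mode (radii in microns via the calibration) is also
provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu

from .stats import two_way_anova_bonferroni

__all__ = [
    "Calibration",
    "CellRoi",
    "MicroscopyImage",
    "RadialProfile",
    "calibrate",
    "detect_nucleus_center",
    "radial_profile",
    "aggregate_profiles",
    "normalize_to_control",
    "compare_profile_groups",
]


@dataclass(frozen=True)
class Calibration:
    """Spatial calibration of the image."""

    microns_per_pixel: float

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")


def calibrate(scale_bar_um: float, scale_bar_px: float) -> Calibration:
    """Calibration from a scale bar, e.g. a 10 um bar spanning 97.5 px."""
    if scale_bar_um <= 0 or scale_bar_px <= 0:
        raise ValueError("scale bar length and pixel span must be positive")
    return Calibration(scale_bar_um / scale_bar_px)


@dataclass
class CellRoi:
    """Closed polygon cell outline in (x=column, y=row) pixel coordinates."""

    vertices: np.ndarray
    cell_id: str = "cell"
    position: str = ""
    replicate: str = "1"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("ROI polygon must be simple with positive area")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        # polygon2mask wants (row, col) vertex order
        return polygon2mask(shape, self.vertices[:, ::-1])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "cell_id": self.cell_id,
                    "position": self.position,
                    "replicate": self.replicate,
                    "vertices": self.vertices.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "CellRoi":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.asarray(d["vertices"], float),
            cell_id=d.get("cell_id", "cell"),
            position=d.get("position", ""),
            replicate=d.get("replicate", "1"),
        )


@dataclass
class MicroscopyImage:
    """Named 2-D channels sharing one shape (e.g. 'dapi' and 'signal')."""

    channels: dict[str, np.ndarray]
    calibration: Calibration | None = None

    def __post_init__(self) -> None:
        shapes = {c: np.asarray(a).shape for c, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        for c, a in self.channels.items():
            a = np.asarray(a, dtype=float)
            if a.ndim != 2:
                raise ValueError(f"channel {c!r} is not 2-D")
            if np.any(a < 0):
                raise ValueError(f"channel {c!r} has negative intensities")
            self.channels[c] = a

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def detect_nucleus_center(
    img: MicroscopyImage, roi: CellRoi, channel: str = "dapi"
) -> tuple[float, float]:
    """Intensity-weighted centroid of the Otsu-thresholded nuclear mask.

    Thresholding is computed within the ROI only. Returns (x, y) pixel
    coordinates; errors if nothing exceeds the threshold or the centroid
    falls outside the ROI (a pathological, e.g. bimodal, mask).
    """
    arr = img.channels[channel]
    mask = roi.mask(arr.shape)
    vals = arr[mask]
    if vals.size == 0:
        raise ValueError("ROI contains no pixels")
    thr = threshold_otsu(vals)
    nuc = mask & (arr > thr)
    if not nuc.any():
        raise ValueError("no nuclear pixel above the Otsu threshold in the ROI")
    rows, cols = np.nonzero(nuc)
    w = arr[rows, cols]
    cx = float((cols * w).sum() / w.sum())
    cy = float((rows * w).sum() / w.sum())
    if not roi.polygon().contains(Point(cx, cy)):
        raise ValueError(
            f"nuclear centroid ({cx:.1f}, {cy:.1f}) lies outside the ROI; "
            "check the nuclear channel or the outline"
        )
    return cx, cy


def _ray_boundary_distances(
    center: np.ndarray, points: np.ndarray, vertices: np.ndarray
) -> np.ndarray:
    """Distance from center to the polygon boundary along each point's ray.

    Exact segment intersection, vectorized over points x edges. For a
    center interior to a star-shaped polygon the relevant crossing is
    the smallest positive t along the unit ray direction.
    """
    d = points - center  # (P, 2)
    norms = np.linalg.norm(d, axis=1)
    safe = norms > 0
    dirs = np.zeros_like(d)
    dirs[safe] = d[safe] / norms[safe, None]
    v1 = vertices
    v2 = np.roll(vertices, -1, axis=0)
    e = v2 - v1  # (S, 2)
    # solve center + t*dir = v1 + s*e  for each (point, segment)
    dx, dy = dirs[:, 0][:, None], dirs[:, 1][:, None]  # (P, 1)
    ex, ey = e[None, :, 0], e[None, :, 1]  # (1, S)
    denom = dx * ey - dy * ex  # (P, S)
    wx = v1[None, :, 0] - center[0]
    wy = v1[None, :, 1] - center[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (wx * ey - wy * ex) / denom
        s = (wx * dy - wy * dx) / denom
    valid = (np.abs(denom) > 1e-12) & (s >= -1e-9) & (s <= 1 + 1e-9) & (t > 1e-9)
    t = np.where(valid, t, np.inf)
    dist = t.min(axis=1)
    dist[~safe] = np.inf  # the center pixel itself: r = 0
    return dist


@dataclass
class RadialProfile:
    """Binned radial intensity profile of one cell."""

    bin_edges: np.ndarray  # length n_bins + 1, over r in [0, 1] (or um)
    bin_mean: np.ndarray  # NaN where a bin holds no pixel
    bin_count: np.ndarray
    cell_id: str = "cell"
    condition: str = ""
    replicate: str = "1"
    mode: str = "normalized"
    n_clipped: int = 0  # boundary pixels with discretized r marginally > 1

    @property
    def n_bins(self) -> int:
        return self.bin_mean.size

    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def total_intensity(self) -> float:
        ok = self.bin_count > 0
        return float((self.bin_mean[ok] * self.bin_count[ok]).sum())


def radial_profile(
    img: MicroscopyImage,
    roi: CellRoi,
    center: tuple[float, float],
    n_bins: int = 20,
    channel: str = "signal",
    mode: str = "normalized",
    calibration: Calibration | None = None,
    background_percentile: float | None = None,
) -> RadialProfile:
    """Mean intensity in equal-width radius bins from the nuclear center.

    ``mode='normalized'`` bins by r = pixel distance / boundary distance
    along the same ray (r in (0, 1]); ``mode='absolute'`` bins by
    physical distance in microns (requires a calibration) out to the
    farthest ROI pixel. Empty bins are reported as NaN means with zero
    counts, never as zeros. No background is subtracted unless
    ``background_percentile`` is given (that percentile of in-ROI
    intensity is subtracted, floored at 0).
    """
    if mode not in {"normalized", "absolute"}:
        raise ValueError("mode must be 'normalized' or 'absolute'")
    arr = img.channels[channel]
    poly = roi.polygon()
    c = np.asarray(center, dtype=float)
    if not poly.contains(Point(*c)):
        raise ValueError("center must lie strictly inside the ROI polygon")
    mask = roi.mask(arr.shape)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("ROI rasterizes to zero pixels")
    pts = np.column_stack([cols, rows]).astype(float)  # (x, y)
    vals = arr[rows, cols].astype(float)
    if background_percentile is not None:
        vals = np.maximum(vals - np.percentile(vals, background_percentile), 0.0)
    dist = np.linalg.norm(pts - c, axis=1)
    n_clipped = 0
    if mode == "normalized":
        bound = _ray_boundary_distances(c, pts, roi.vertices)
        with np.errstate(invalid="ignore"):
            r = np.where(dist > 0, dist / bound, 0.0)
        n_clipped = int(np.sum(r > 1.0))
        r = np.minimum(r, 1.0)
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    else:
        if calibration is None:
            raise ValueError("absolute mode requires a calibration")
        r = dist * calibration.microns_per_pixel
        edges = np.linspace(0.0, float(r.max()) or 1.0, n_bins + 1)
    # bin i covers (edges[i], edges[i+1]]; r == 0 goes to bin 0
    idx = np.clip(np.ceil(r / edges[-1] * n_bins).astype(int) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RadialProfile(
        bin_edges=edges,
        bin_mean=means,
        bin_count=counts,
        cell_id=roi.cell_id,
        condition=roi.position,
        replicate=roi.replicate,
        mode=mode,
        n_clipped=n_clipped,
    )


def profiles_to_frame(profiles: list[RadialProfile]) -> pd.DataFrame:
    """Long table: one row per (cell, bin) with group/replicate labels."""
    rows = []
    for p in profiles:
        centers = p.bin_centers()
        for b in range(p.n_bins):
            if p.bin_count[b] == 0:
                continue
            rows.append(
                {
                    "cell_id": p.cell_id,
                    "condition": p.condition,
                    "replicate": p.replicate,
                    "bin": b,
                    "r": centers[b],
                    "mean_intensity": p.bin_mean[b],
                }
            )
    return pd.DataFrame(rows)


def aggregate_profiles(
    profiles: list[RadialProfile],
) -> pd.DataFrame:
    """Group curves as mean +/- s.e.m. over replicate means (nested design).

    Cells are first averaged within each biological replicate; the group
    mean and s.e.m. are then computed across replicate means, so cells
    are never treated as independent across replicates.

    Returns columns (condition, bin, r, mean, sem, n_replicates, n_cells).
    """
    n_bins = {p.n_bins for p in profiles}
    if len(n_bins) != 1:
        raise ValueError("profiles have mismatched bin counts")
    df = profiles_to_frame(profiles)
    rep_means = (
        df.groupby(["condition", "replicate", "bin"], sort=True)["mean_intensity"]
        .mean()
        .reset_index()
    )
    out = []
    for (cond, b), sub in rep_means.groupby(["condition", "bin"], sort=True):
        vals = sub["mean_intensity"].to_numpy()
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
        n_cells = int(
            df[(df["condition"] == cond) & (df["bin"] == b)]["cell_id"].nunique()
        )
        r = float(df[(df["condition"] == cond) & (df["bin"] == b)]["r"].iloc[0])
        out.append(
            {
                "condition": cond,
                "bin": b,
                "r": r,
                "mean": float(vals.mean()),
                "sem": float(sem),
                "n_replicates": int(vals.size),
                "n_cells": n_cells,
            }
        )
    return pd.DataFrame(out)


def normalize_to_control(
    group_curve: pd.DataFrame, control_curve: pd.DataFrame
) -> pd.DataFrame:
    """Per-bin division of a group curve by the negative-control curve.

    The control normalized by itself is identically 1 in every bin. A
    zero control bin is an error naming the bin.
    """
    g = group_curve.set_index("bin")
    c = control_curve.set_index("bin")
    if not g.index.equals(c.index):
        raise ValueError("group and control curves have mismatched bins")
    zero = c.index[c["mean"] == 0]
    if len(zero):
        raise ValueError(f"control mean is zero in bin(s) {list(zero)}")
    out = g.copy()
    out["relative"] = g["mean"] / c["mean"]
    out["relative_sem"] = g["sem"] / c["mean"]
    return out.reset_index()


def compare_profile_groups(
    profiles: list[RadialProfile], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way (group x bin) ANOVA with per-bin Bonferroni comparison.

    The observational unit is the cell (nested in replicate); delegates
    to :func:`wormepi.stats.two_way_anova_bonferroni` and returns its
    (omnibus, per-bin) tables, the per-bin ``significant`` flag matching
    the usual gray-dot display convention.
    """
    df = profiles_to_frame(profiles)
    if df["condition"].nunique() < 2:
        raise ValueError("need >= 2 groups to compare")
    return two_way_anova_bonferroni(
        df.rename(columns={"mean_intensity": "value", "condition": "group"}),
        value="value",
        group="group",
        bin_col="bin",
        alpha=alpha,
    )
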