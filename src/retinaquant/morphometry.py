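"""Curve-based retinal morphometry.

The core quantification: fit a smooth curve through the retinal band,
sample band-averaged luminance along it, count discontinuities (the frailty
index — histological "solutions of continuity"), and measure per-layer
thickness along the curve normals at landmark-referenced sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from retinaquant._exceptions import (
    GeometryError,
    MeasurementError,
    ValidationError,
)
from retinaquant.imageprep import GrayImage, RetinaMask

__all__ = [
    "RetinalCurve",
    "IntensityProfile",
    "FrailtyResult",
    "ThicknessResult",
    "fit_retinal_curve",
    "sample_profile",
    "count_discontinuities",
    "measure_thickness",
]

log = logging.getLogger(__name__)


@dataclass
class RetinalCurve:
    """Smooth midline of the retinal band, sampled once per column.

    ``x_px``/``y_px`` are pixel coordinates (column, row); ``arclength_um``
    is the cumulative arc length from the first sample; ``normals`` are unit
    vectors ``(dx, dy)`` perpendicular to the local tangent, oriented toward
    increasing row (the inner side for an upright section).
    """

    x_px: np.ndarray
    y_px: np.ndarray
    arclength_um: np.ndarray
    tangents: np.ndarray
    normals: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.arclength_um) <= 0):
            raise ValidationError("arclength must be strictly increasing")

    def point_at(self, arclength_um: float) -> tuple[float, float, np.ndarray]:
        """Interpolate (x, y, unit normal) at an arclength position."""
        s = self.arclength_um
        if not (s[0] <= arclength_um <= s[-1]):
            raise ValidationError(f"arclength {arclength_um} outside curve [{s[0]}, {s[-1]}]")
        x = float(np.interp(arclength_um, s, self.x_px))
        y = float(np.interp(arclength_um, s, self.y_px))
        nx = np.interp(arclength_um, s, self.normals[:, 0])
        ny = np.interp(arclength_um, s, self.normals[:, 1])
        n = np.array([nx, ny])
        return x, y, n / np.linalg.norm(n)


@dataclass
class IntensityProfile:
    """Band-averaged luminance sampled along a retinal curve."""

    positions_um: np.ndarray
    values: np.ndarray
    band_halfwidth_um: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValidationError("profile positions must be strictly increasing")
        if len(self.positions_um) != len(self.values):
            raise ValidationError("positions and values must have equal length")


@dataclass
class FrailtyResult:
    """Discontinuity (rupture) count along the retinal curve."""

    n_discontinuities: int
    spans_um: list[tuple[float, float]]
    threshold_used: float

    def __post_init__(self) -> None:
        if self.n_discontinuities != len(self.spans_um):
            raise ValidationError("count must equal number of spans")


@dataclass
class ThicknessResult:
    """Per-layer thickness averaged over landmark-referenced sites."""

    thickness_um: dict[str, float]
    total_um: float
    sites_um: list[float]
    n_sites_used: int
    skipped_sites_um: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------


def fit_retinal_curve(
    mask: RetinaMask,
    polynomial_degree: int = 5,
    min_aspect: float = 2.0,
) -> RetinalCurve:
    """Fit the band midline: smoothed locus of per-column band mid-points.

    The mask must be band-like (extent along its principal axis at least
    ``min_aspect`` times the perpendicular extent).  Bands running closer to
    vertical than horizontal are handled by transposing.  Columns without
    tissue, or clipped by a slanted rupture, are excluded from the fit; the
    global polynomial bridges those gaps smoothly.
    """
    m = mask.mask
    if not m.any():
        raise GeometryError("empty mask")
    pts = np.argwhere(m).astype(float)  # (row, col)
    centered = pts - pts.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    principal = evecs[:, np.argmax(evals)]
    proj_major = centered @ principal
    minor = evecs[:, np.argmin(evals)]
    proj_minor = centered @ minor
    extent_major = np.ptp(proj_major)
    extent_minor = np.ptp(proj_minor)
    if extent_minor == 0 or extent_major / extent_minor < min_aspect:
        raise GeometryError(
            f"mask is not band-like (aspect {extent_major / max(extent_minor, 1e-9):.2f} "
            f"< {min_aspect})"
        )
    transposed = abs(principal[0]) > abs(principal[1])  # major axis more vertical
    work = m.T if transposed else m

    rows, cols = work.shape
    row_grid = np.arange(rows)[:, None]
    top = np.where(work, row_grid, rows).min(axis=0).astype(float)
    bot = np.where(work, row_grid, -1).max(axis=0).astype(float)
    height = bot - top + 1
    # columns clipped by a (possibly slanted) rupture have much less than the
    # typical band height; their mid-points are meaningless, so bridge them
    typical = np.median(height[height > 0])
    col_idx = np.flatnonzero(height >= 0.9 * typical)
    if col_idx.size < 5:
        raise GeometryError("too few full-height columns to fit a curve")
    mid = (top + bot) / 2.0
    x = np.arange(cols, dtype=float)
    deg = min(polynomial_degree, col_idx.size - 1)

    def _smooth(idx: np.ndarray) -> np.ndarray:
        # a global low-order polynomial: locally smooth, and it bridges
        # rupture gaps without the wobble a windowed smoother picks up there
        return np.polynomial.Polynomial.fit(x[idx], mid[idx], deg)(x)

    y = _smooth(col_idx)
    # second pass: partially clipped columns near slanted ruptures bias the
    # mid-points; reject columns far from the first-pass curve and refit
    resid = mid[col_idx] - y[col_idx]
    sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    keep = col_idx[np.abs(resid) <= max(3.0 * sigma, 2.0)]
    if keep.size > deg:
        y = _smooth(keep)

    if transposed:
        x, y = y, x
    dx = np.gradient(x)
    dy = np.gradient(y)
    step = np.hypot(dx, dy)
    arclength = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
    arclength_um = arclength * mask.pixel_size_um
    tangents = np.stack([dx / step, dy / step], axis=1)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    flip = normals[:, 1] < 0  # orient toward increasing row
    normals[flip] *= -1
    return RetinalCurve(
        x_px=x,
        y_px=y,
        arclength_um=arclength_um,
        tangents=tangents,
        normals=normals,
        pixel_size_um=mask.pixel_size_um,
    )


# ---------------------------------------------------------------------------
# Intensity profile
# ---------------------------------------------------------------------------


def sample_profile(
    gray: GrayImage,
    curve: RetinalCurve,
    band_halfwidth_um: float = 0.0,
) -> IntensityProfile:
    """Mean luminance over the normal segment +/- ``band_halfwidth_um``.

    One sample per curve point; the normal segment is stepped at one-pixel
    resolution with bilinear interpolation.  Samples falling outside the
    image are clipped to the border (a warning is logged).
    """
    px = curve.pixel_size_um
    hw_px = band_halfwidth_um / px
    n_off = int(np.floor(hw_px + 1e-9))
    offsets = np.arange(-n_off, n_off + 1, dtype=float)
    xs = curve.x_px[None, :] + offsets[:, None] * curve.normals[:, 0][None, :]
    ys = curve.y_px[None, :] + offsets[:, None] * curve.normals[:, 1][None, :]
    rows, cols = gray.shape
    if xs.min() < 0 or xs.max() > cols - 1 or ys.min() < 0 or ys.max() > rows - 1:
        log.warning("profile band exits image bounds; samples clipped to border")
    vals = map_coordinates(gray.values, [ys.ravel(), xs.ravel()], order=1, mode="nearest")
    vals = vals.reshape(xs.shape).mean(axis=0)
    return IntensityProfile(
        positions_um=curve.arclength_um.copy(),
        values=vals,
        band_halfwidth_um=band_halfwidth_um,
    )


# ---------------------------------------------------------------------------
# Frailty index
# ---------------------------------------------------------------------------


def count_discontinuities(
    profile: IntensityProfile,
    threshold: float | None = None,
    min_width_um: float = 5.0,
    background_level: float | None = None,
) -> FrailtyResult:
    """Count background-level gaps in the luminance profile.

    Positions whose luminance exceeds the tissue level (profile median) by
    more than ``threshold`` — i.e. deviates toward the brighter background —
    are flagged; flagged runs closer together than ``min_width_um`` are
    merged (ties merge), runs narrower than ``min_width_um`` are dropped,
    and the survivors are counted.

    With ``threshold=None`` the threshold defaults to half the gap between
    the background level (given, or the profile maximum) and the tissue
    median, floored at 5 luminance units.
    """
    pos = np.asarray(profile.positions_um, dtype=float)
    vals = np.asarray(profile.values, dtype=float)
    if pos.size < 3:
        raise ValidationError("profile must have at least 3 samples")
    if np.any(np.diff(pos) <= 0):
        raise ValidationError("profile positions must be strictly increasing")
    tissue_level = float(np.median(vals))
    if threshold is None:
        bg = background_level if background_level is not None else float(vals.max())
        threshold = max(5.0, (bg - tissue_level) / 2.0)
    flagged = (vals - tissue_level) > threshold

    spans: list[tuple[float, float]] = []
    idx = np.flatnonzero(flagged)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks], [idx[-1]]])
        raw = [(pos[s], pos[e]) for s, e in zip(starts, ends)]
        merged = [list(raw[0])]
        for a, b in raw[1:]:
            if a - merged[-1][1] <= min_width_um:  # ties merge
                merged[-1][1] = b
            else:
                merged.append([a, b])
        spans = [(a, b) for a, b in merged if b - a >= min_width_um]
    return FrailtyResult(
        n_discontinuities=len(spans), spans_um=spans, threshold_used=float(threshold)
    )


# ---------------------------------------------------------------------------
# Thickness
# ---------------------------------------------------------------------------


def _normal_crossings(
    boundaries: np.ndarray,
    x0: float,
    y0: float,
    normal: np.ndarray,
    t_max_px: float,
    step_px: float = 0.25,
) -> np.ndarray | None:
    """Signed distances along the normal where each boundary is crossed.

    Returns one crossing per interface (linear interpolation of the sign
    change), or ``None`` if any interface is not crossed exactly once-plus.
    """
    t = np.arange(-t_max_px, t_max_px + step_px, step_px)
    xs = x0 + t * normal[0]
    ys = y0 + t * normal[1]
    cols = np.arange(boundaries.shape[1], dtype=float)
    crossings = np.empty(boundaries.shape[0])
    for j in range(boundaries.shape[0]):
        b = np.interp(xs, cols, boundaries[j])
        f = ys - b  # + below the boundary
        sign_change = np.flatnonzero(np.diff(np.sign(f)) != 0)
        if sign_change.size == 0:
            return None
        k = sign_change[0]
        # linear interpolation of the zero of f between t[k] and t[k+1]
        frac = f[k] / (f[k] - f[k + 1])
        crossings[j] = t[k] + frac * (t[k + 1] - t[k])
    return crossings


def measure_thickness(
    boundaries: np.ndarray,
    layer_names: tuple[str, ...],
    curve: RetinalCurve,
    landmark_arclength_um: float,
    offsets_um: tuple[float, ...] = (-500.0, 500.0),
    n_sites_per_offset: int = 3,
    site_spacing_um: float = 25.0,
    gray: GrayImage | None = None,
    background_level: float | None = None,
    exclude_spans_um: list[tuple[float, float]] | None = None,
) -> ThicknessResult:
    """Per-layer thickness at landmark-referenced sites along curve normals.

    ``boundaries`` has shape ``(n_layers + 1, image_cols)`` — the vertical
    coordinate of each interface per column, outer to inner.  At each site
    (``landmark +/- offsets``, ``n_sites_per_offset`` measurements spaced
    ``site_spacing_um`` around each offset) the thickness of layer *i* is
    the distance between the crossings of interfaces *i* and *i+1* along the
    local normal.  Sites falling in a rupture (listed in
    ``exclude_spans_um``, or detected as background luminance when ``gray``
    is provided) are skipped and logged; if every site is skipped a
    :class:`MeasurementError` is raised.
    """
    boundaries = np.asarray(boundaries, dtype=float)
    if boundaries.ndim != 2 or boundaries.shape[0] != len(layer_names) + 1:
        raise ValidationError("boundaries must be (n_layers + 1, cols)")
    px = curve.pixel_size_um
    centers = np.arange(n_sites_per_offset) - (n_sites_per_offset - 1) / 2.0
    sites = [
        landmark_arclength_um + off + c * site_spacing_um
        for off in offsets_um
        for c in centers
    ]
    t_max_px = (np.nanmax(boundaries) - np.nanmin(boundaries)) + 10.0

    per_layer: list[np.ndarray] = []
    used: list[float] = []
    skipped: list[float] = []
    for s in sites:
        try:
            x0, y0, n = curve.point_at(s)
        except ValidationError:
            skipped.append(s)
            continue
        if exclude_spans_um and any(a <= s <= b for a, b in exclude_spans_um):
            skipped.append(s)
            log.info("site %.1f um inside an excluded span; skipped", s)
            continue
        if gray is not None and background_level is not None:
            lum = float(map_coordinates(gray.values, [[y0], [x0]], order=1, mode="nearest")[0])
            if lum >= background_level - 10.0:
                skipped.append(s)
                log.info("site %.1f um has background luminance; skipped", s)
                continue
        crossings = _normal_crossings(boundaries, x0, y0, n, t_max_px)
        if crossings is None:
            skipped.append(s)
            log.info("normal at %.1f um does not cross all interfaces; skipped", s)
            continue
        per_layer.append(np.abs(np.diff(np.sort(crossings))) * px)
        used.append(s)
    if not per_layer:
        raise MeasurementError("all measurement sites were skipped")
    mean_per_layer = np.mean(per_layer, axis=0)
    thickness = {name: float(v) for name, v in zip(layer_names, mean_per_layer)}
    return ThicknessResult(
        thickness_um=thickness,
        total_um=float(mean_per_layer.sum()),
        sites_um=used,
        n_sites_used=len(used),
        skipped_sites_um=skipped,
    )
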