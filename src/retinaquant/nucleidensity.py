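"""Nuclei binarization, OPL segmentation and density per 100 um^2.

Pipeline: binarize the nuclear region (nuclei -> 0, cytoplasm/matrix ->
255), locate the outer plexiform layer as the nuclei-sparse valley between
the two nuclei-dense bands on either side, and report a density for each
nuclear layer as calibrated pixel counts over the band area.  Counting by
total nuclei pixels divided by a single-nucleus calibration area is the
default because it is robust to clumped nuclei; per-connected-component
counting is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from skimage import measure as sk_measure
from skimage.filters import threshold_otsu

from retinaquant._exceptions import SegmentationError, ValidationError
from retinaquant.imageprep import GrayImage, RetinaMask
from retinaquant.morphometry import RetinalCurve

__all__ = [
    "BinaryNucleiImage",
    "NucleiDensityResult",
    "binarize_nuclei",
    "segment_opl",
    "nuclei_density",
]


@dataclass
class BinaryNucleiImage:
    """Binary image with nuclei = 0 and everything else = 255."""

    values: np.ndarray
    pixel_size_um: float
    region: np.ndarray  # bool mask of the analysed region

    def __post_init__(self) -> None:
        bad = set(np.unique(self.values)) - {0, 255}
        if bad:
            raise ValidationError(f"binary image contains values other than 0/255: {bad}")

    @property
    def nuclei_mask(self) -> np.ndarray:
        return (self.values == 0) & self.region


@dataclass
class NucleiDensityResult:
    layer: str
    nuclei_count: float
    region_area_um2: float
    density_per_100um2: float
    calibration_nucleus_area_um2: float

    def __post_init__(self) -> None:
        if self.region_area_um2 <= 0:
            raise ValidationError("region area must be > 0")
        if self.density_per_100um2 < 0:
            raise ValidationError("density must be >= 0")


def binarize_nuclei(gray: GrayImage, region: RetinaMask | np.ndarray) -> BinaryNucleiImage:
    """Otsu-threshold luminance inside ``region``: darker class -> 0.

    If the within-region histogram is effectively unimodal (class means
    closer than 10 luminance units) no nuclei are present and an all-255
    image is returned.  Inverted-polarity inputs (dark background, bright
    minority) are rejected.
    """
    mask = region.mask if isinstance(region, RetinaMask) else np.asarray(region, dtype=bool)
    if not mask.any():
        raise ValidationError("region is empty")
    vals = gray.values[mask]
    out = np.full(gray.shape, 255, dtype=np.uint8)
    try:
        thr = threshold_otsu(vals)
    except ValueError:  # constant region
        return BinaryNucleiImage(out, gray.pixel_size_um, mask)
    dark, light = vals[vals <= thr], vals[vals > thr]
    if dark.size == 0 or light.size == 0 or light.mean() - dark.mean() < 10.0:
        return BinaryNucleiImage(out, gray.pixel_size_um, mask)  # unimodal
    dark_frac = float(np.mean(vals <= thr))
    if dark_frac > 0.6:
        raise ValidationError(
            f"histogram polarity check failed: {dark_frac:.0%} of region pixels are in "
            "the dark class; input looks inverted"
        )
    nuclei = mask & (gray.values <= thr)
    out[nuclei] = 0
    return BinaryNucleiImage(out, gray.pixel_size_um, mask)


def _normal_offsets(binary: BinaryNucleiImage, curve: RetinalCurve) -> tuple[np.ndarray, np.ndarray]:
    """Signed normal offset (px) of every region pixel relative to the curve."""
    pts = np.argwhere(binary.region)  # (row, col)
    curve_pts = np.stack([curve.y_px, curve.x_px], axis=1)
    tree = cKDTree(curve_pts)
    _, nearest = tree.query(pts.astype(float))
    normals_rc = curve.normals[nearest][:, ::-1]  # (dy, dx) -> match (row, col)
    offsets = np.einsum("ij,ij->i", pts - curve_pts[nearest], normals_rc)
    return pts, offsets


def segment_opl(
    binary: BinaryNucleiImage,
    curve: RetinalCurve,
    bin_width_px: float = 2.0,
    min_peak_frac: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Split the nuclear region into ONL and INL across the OPL valley.

    The nuclei-pixel fraction is profiled in bins of normal offset from the
    curve.  The two highest-prominence maxima are the nuclear layers; the
    OPL is the minimum-density band between them.  The band with the larger
    integrated nuclei content (density x extent) is labelled ONL — outer
    nuclear layers are denser and thicker than inner ones — so the labels
    follow tissue content, not image orientation.

    Returns ``(onl_mask, inl_mask, info)`` where ``info`` records the OPL
    centre offset and the band edges (in pixels of normal offset).
    """
    pts, offsets = _normal_offsets(binary, curve)
    nuclei = binary.values[pts[:, 0], pts[:, 1]] == 0
    lo, hi = offsets.min(), offsets.max()
    n_bins = max(4, int(np.ceil((hi - lo) / bin_width_px)))
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(offsets, edges) - 1, 0, n_bins - 1)
    totals = np.bincount(which, minlength=n_bins).astype(float)
    dark = np.bincount(which[nuclei], minlength=n_bins).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, dark / totals, 0.0)
    # bins that are almost entirely dark are continuous stain (e.g. the
    # pigmented Ch/RPE band), not a point process of nuclei; exclude them
    frac = np.where(frac > 0.5, 0.0, frac)

    # estimated nucleus radius (from connected-component areas) sets both the
    # smoothing scale and the band-edge padding below
    comp_sizes = np.bincount(sk_measure.label(binary.nuclei_mask, connectivity=2).ravel())[1:]
    comp_sizes = comp_sizes[comp_sizes > 0]
    r_est_px = float(np.sqrt(np.median(comp_sizes) / np.pi)) if comp_sizes.size else 0.0

    # smooth over one nucleus diameter so point-process speckle inside a band
    # cannot masquerade as separate density maxima
    k = max(3, int(round(2.0 * r_est_px / bin_width_px)) | 1)
    smooth = np.convolve(frac, np.ones(k) / k, mode="same")
    peaks, _ = find_peaks(smooth, height=min_peak_frac)
    # the two nuclear layers are the highest peak pair separated by a deep
    # (nuclei-free OPL) valley; speckle peaks within one band never are
    best: tuple[int, int] | None = None
    for i in range(peaks.size):
        for j in range(i + 1, peaks.size):
            pi, pj = int(peaks[i]), int(peaks[j])
            pair_min = min(smooth[pi], smooth[pj])
            if smooth[pi : pj + 1].min() <= 0.25 * pair_min:
                if best is None or pair_min > min(smooth[best[0]], smooth[best[1]]):
                    best = (pi, pj)
    if best is None:
        raise SegmentationError(
            f"expected two nuclei-density maxima separated by a nuclei-free "
            f"valley; found {peaks.size} maxima and no valley"
        )
    p1, p2 = best
    between = smooth[p1 : p2 + 1]
    low = np.flatnonzero(between <= between.min() + 1e-12)
    valley = p1 + int(round(low.mean()))  # centre of the minimum-density run
    floor = min_peak_frac / 2
    pad = int(round(0.75 * r_est_px / bin_width_px))

    def _band(peak: int, inner_limit: int, outer_limit: int) -> tuple[int, int]:
        a = peak
        while a > outer_limit and frac[a - 1] > floor:
            a -= 1
        b = peak
        while b < inner_limit and frac[b + 1] > floor:
            b += 1
        return max(outer_limit, a - pad), min(inner_limit, b + pad)

    band1 = _band(p1, valley, 0)
    band2 = _band(p2, n_bins - 1, valley)
    centers = (edges[:-1] + edges[1:]) / 2.0

    def _mask(band: tuple[int, int]) -> np.ndarray:
        sel = (offsets >= edges[band[0]]) & (offsets < edges[band[1] + 1])
        m = np.zeros_like(binary.region)
        m[pts[sel, 0], pts[sel, 1]] = True
        return m

    def _content(band: tuple[int, int]) -> float:
        return float(dark[band[0] : band[1] + 1].sum())

    if _content(band1) >= _content(band2):
        onl_band, inl_band = band1, band2
    else:
        onl_band, inl_band = band2, band1
    info = {
        "opl_center_offset_px": float(centers[valley]),
        "opl_edges_px": (float(edges[band1[1] + 1]), float(edges[band2[0]])),
        "onl_offset_range_px": (float(edges[onl_band[0]]), float(edges[onl_band[1] + 1])),
        "inl_offset_range_px": (float(edges[inl_band[0]]), float(edges[inl_band[1] + 1])),
    }
    return _mask(onl_band), _mask(inl_band), info


def nuclei_density(
    binary: BinaryNucleiImage,
    region: np.ndarray,
    calibration_nucleus_area_um2: float | None = None,
    layer: str = "ONL",
    method: str = "pixel",
) -> NucleiDensityResult:
    """Density per 100 um^2 over ``region`` from calibrated pixel counts.

    ``pixel`` (default): nuclei_count = nuclei-pixel area / calibration
    area, which degrades gracefully when nuclei clump.  ``component``:
    count connected components instead.  With no explicit calibration the
    median area of the region's connected nuclei components is used; this
    requires at least one component.
    """
    region = np.asarray(region, dtype=bool)
    area_um2 = float(region.sum()) * binary.pixel_size_um**2
    if area_um2 <= 0:
        raise ValidationError("region area must be > 0")
    nuclei = (binary.values == 0) & region
    px_area = binary.pixel_size_um**2
    if calibration_nucleus_area_um2 is None:
        labels = sk_measure.label(nuclei, connectivity=2)
        sizes = np.bincount(labels.ravel())[1:]
        sizes = sizes[sizes > 0]
        if sizes.size == 0:
            if not nuclei.any():
                return NucleiDensityResult(layer, 0.0, area_um2, 0.0, float("nan"))
            raise ValidationError("no isolated components; explicit calibration required")
        calibration_nucleus_area_um2 = float(np.median(sizes)) * px_area
    if calibration_nucleus_area_um2 <= 0:
        raise ValidationError("calibration area must be > 0")
    if method == "pixel":
        count = float(nuclei.sum()) * px_area / calibration_nucleus_area_um2
    elif method == "component":
        count = float(sk_measure.label(nuclei, connectivity=2).max())
    else:
        raise ValidationError(f"unknown counting method {method!r}")
    return NucleiDensityResult(
        layer=layer,
        nuclei_count=count,
        region_area_um2=area_um2,
        density_per_100um2=100.0 * count / area_um2,
        calibration_nucleus_area_um2=float(calibration_nucleus_area_um2),
    )
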