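"""Seeded generators for every input the analysis pipeline consumes.

Three families of artefacts are produced, each with ground truth attached:

* :func:`generate_retina_image` — an H&E-like RGB cross-section of a curved,
  layered retina with planted ruptures (background-coloured gaps crossing
  all layers) and planted nuclei in the nuclear layers;
* :func:`generate_erg_trace` — repeated flash-ERG responses built from
  smooth unimodal lobes whose analytic trough/peak equal the requested
  a-/b-wave amplitudes and latencies;
* :func:`generate_group_measurements` — two-group tables with known
  per-variable location shifts.

All generators are deterministic given (spec, seed): the same spec yields
byte-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from retinaquant._exceptions import ValidationError

__all__ = [
    "LAYER_ORDER",
    "RetinaSpec",
    "GroundTruth",
    "AnnotatedRetinaImage",
    "ERGSpec",
    "SyntheticERGTrace",
    "GroupSpec",
    "generate_retina_image",
    "generate_erg_trace",
    "generate_group_measurements",
]

#: Outer-to-inner layer order used everywhere in the package.
LAYER_ORDER = (
    "ChRPE",
    "PR_outer_segment",
    "PR_inner_segment",
    "ONL",
    "OPL",
    "INL",
    "IPL",
    "GCL",
)

# fixed H&E-like palette (stable luminance contrast for thresholding)
NUCLEUS_RGB = (60, 40, 110)
EOSIN_RGB = (230, 150, 170)
CHRPE_RGB = (180, 120, 140)
BACKGROUND_RGB = (245, 245, 245)

_NUCLEAR_LAYERS = ("ONL", "INL")


@dataclass(frozen=True)
class RetinaSpec:
    """Parameters of one synthetic retinal cross-section."""

    image_size_px: tuple[int, int] = (640, 1500)
    pixel_size_um: float = 1.0
    layer_thicknesses_um: dict[str, float] = field(
        default_factory=lambda: {
            "ChRPE": 42.6,
            "PR_outer_segment": 109.6,
            "PR_inner_segment": 135.8,
            "ONL": 67.0,
            "OPL": 19.9,
            "INL": 49.4,
            "IPL": 53.6,
            "GCL": 12.9,
        }
    )
    curvature: float = 0.03
    n_ruptures: int = 0
    rupture_width_um: float = 20.0
    onl_density_per100um2: float = 0.0
    inl_density_per100um2: float = 0.0
    nucleus_radius_um: float = 1.2
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def total_thickness_um(self) -> float:
        return float(sum(self.layer_thicknesses_um.values()))

    def validate(self) -> None:
        rows, cols = self.image_size_px
        if rows < 8 or cols < 8:
            raise ValidationError("image_size_px too small")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        missing = [k for k in LAYER_ORDER if k not in self.layer_thicknesses_um]
        if missing:
            raise ValidationError(f"layer_thicknesses_um missing layers: {missing}")
        if any(v < 0 for v in self.layer_thicknesses_um.values()):
            raise ValidationError("layer_thicknesses_um must be >= 0")
        if self.curvature < 0:
            raise ValidationError("curvature must be >= 0")
        if self.n_ruptures < 0:
            raise ValidationError("n_ruptures must be >= 0")
        if self.rupture_width_um <= 0:
            raise ValidationError("rupture_width_um must be > 0")
        if self.onl_density_per100um2 < 0 or self.inl_density_per100um2 < 0:
            raise ValidationError("densities must be >= 0")
        if self.nucleus_radius_um <= 0:
            raise ValidationError("nucleus_radius_um must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        height_um = rows * self.pixel_size_um
        sag_um = self.curvature * cols * self.pixel_size_um
        if self.total_thickness_um + 2 * sag_um + 4 * self.pixel_size_um > height_um:
            raise ValidationError(
                "layer_thicknesses_um: stack + bow does not fit in image_size_px"
            )


@dataclass
class GroundTruth:
    """Planted geometry of a synthetic retina image.

    ``boundary_curves`` has shape (n_layers + 1, cols): vertical pixel
    coordinate of each layer interface per column, ordered outer to inner.
    ``rupture_spans`` are arclength intervals in micrometres measured along
    the midline from the left image edge.
    """

    boundary_curves: np.ndarray
    layer_names: tuple[str, ...]
    nuclei_centers: list[tuple[float, float, str]]
    rupture_spans: list[tuple[float, float]]
    layer_thickness_um: dict[str, float]
    midline_row_px: float
    arc_radius_px: float  # inf for a straight retina
    arc_center_px: tuple[float, float]  # (row, col); row=inf when straight
    arclength_total_um: float

    def boundary(self, name_outer: str) -> np.ndarray:
        """Interface curve at the outer edge of ``name_outer``."""
        return self.boundary_curves[self.layer_names.index(name_outer)]


@dataclass
class AnnotatedRetinaImage:
    """RGB pixel grid plus physical scale (and ground truth when synthetic)."""

    rgb: np.ndarray
    pixel_size_um: float
    ground_truth: GroundTruth | None = None


def _place_rupture_centers(
    rng: np.random.Generator, total_um: float, width: float, n: int, margin: float
) -> np.ndarray:
    """Centres of ``n`` disjoint intervals with >= 3*width separation.

    Uses the reduced-domain trick: draw sorted uniforms in the free length
    remaining after reserving the widths, gaps and margins, then re-inflate.
    """
    gap = 3.0 * width
    free = total_um - 2.0 * margin - n * width - (n - 1) * gap
    if free < 0:
        raise ValidationError(
            f"cannot place {n} ruptures of width {width} um with 3x separation "
            f"in {total_um:.0f} um"
        )
    u = np.sort(rng.uniform(0.0, free, size=n))
    return margin + u + np.arange(n) * (width + gap) + width / 2.0


def generate_retina_image(spec: RetinaSpec) -> tuple[AnnotatedRetinaImage, GroundTruth]:
    """Render one synthetic H&E-like retinal cross-section.

    The retina is a stack of layer bands following a circular-arc midline
    (``curvature`` = sag/chord of the arc; 0 means straight).  Layer
    membership of a pixel is decided by its signed radial distance to the
    midline, so the planted per-layer thickness measured along the local
    normal is exact everywhere.  Ruptures are radial background-coloured
    bands crossing the whole stack; nuclei are filled disks planted by a
    seeded Poisson point process in ONL and INL.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size_px
    px = spec.pixel_size_um
    total_px = spec.total_thickness_um / px

    # --- geometry ---------------------------------------------------------
    sag_px = spec.curvature * cols
    apex_row = 2.0 + sag_px + total_px / 2.0  # midline row at the apex (centre col)
    cx = (cols - 1) / 2.0
    straight = sag_px < 1e-9
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    if straight:
        radius = np.inf
        center = (np.inf, cx)
        u_px = yy - apex_row  # signed offset from midline, + = inner (down)
        s_um = xx * px  # arclength from left edge
        arclength_total = (cols - 1) * px
    else:
        # circle through the apex, centre below the image
        half_chord = cx
        radius = (half_chord**2 + sag_px**2) / (2.0 * sag_px)
        cy = apex_row + radius
        center = (cy, cx)
        rho = np.hypot(yy - cy, xx - cx)
        u_px = radius - rho  # + = below midline = inner side
        theta = np.arctan2(xx - cx, cy - yy)  # 0 at apex, increasing with x
        theta_left = -np.arcsin(cx / radius)  # midline angle at column 0
        s_um = radius * (theta - theta_left) * px
        arclength_total = float(2.0 * radius * np.arcsin(cx / radius) * px)

    # interface offsets from the midline, outer (negative) to inner (positive)
    thick_px = np.array([spec.layer_thicknesses_um[k] for k in LAYER_ORDER]) / px
    edges = np.concatenate([[0.0], np.cumsum(thick_px)]) - total_px / 2.0

    # --- base painting ----------------------------------------------------
    img = np.empty((rows, cols, 3), dtype=float)
    img[:] = BACKGROUND_RGB
    in_band = (u_px >= edges[0]) & (u_px < edges[-1])
    img[in_band] = EOSIN_RGB
    chrpe = (u_px >= edges[0]) & (u_px < edges[1])
    img[chrpe] = CHRPE_RGB

    # ground-truth boundary curves (vertical coordinate per column)
    col_idx = np.arange(cols, dtype=float)
    bounds = np.empty((len(LAYER_ORDER) + 1, cols))
    for j, off in enumerate(edges):
        if straight:
            bounds[j] = apex_row + off
        else:
            cy = center[0]
            r_j = radius - off  # inner (positive) offsets sit at smaller radius
            bounds[j] = cy - np.sqrt(r_j**2 - (col_idx - cx) ** 2)

    # --- ruptures ---------------------------------------------------------
    margin = max(2.0 * spec.rupture_width_um, 0.02 * arclength_total)
    spans: list[tuple[float, float]] = []
    if spec.n_ruptures > 0:
        centers = _place_rupture_centers(
            rng, arclength_total, spec.rupture_width_um, spec.n_ruptures, margin
        )
        half = spec.rupture_width_um / 2.0
        spans = [(float(c - half), float(c + half)) for c in centers]

    # --- nuclei -----------------------------------------------------------
    nuclei: list[tuple[float, float, str]] = []
    r_nuc_px = spec.nucleus_radius_um / px
    densities = {"ONL": spec.onl_density_per100um2, "INL": spec.inl_density_per100um2}
    # 60 % area overlap of equal disks corresponds to centre distance ~0.62 r
    min_sep_px = 0.62 * r_nuc_px
    for layer in _NUCLEAR_LAYERS:
        dens = densities[layer]
        if dens <= 0:
            continue
        i = LAYER_ORDER.index(layer)
        lo, hi = edges[i], edges[i + 1]
        # expected count over the *full* band area (minus rupture cuts) so the
        # planted count is unbiased for the density measured over that band;
        # centres are inset by one nucleus radius to avoid clipped disks.
        span_um = sum(b - a for a, b in spans)
        band_area_um2 = (arclength_total - span_um) * (hi - lo) * px
        n_pts = int(rng.poisson(dens * band_area_um2 / 100.0))
        r_nuc_um = spec.nucleus_radius_um
        s_lo, s_hi = r_nuc_um, arclength_total - r_nuc_um
        placed: list[tuple[float, float]] = []
        attempts = 0
        while len(placed) < n_pts and attempts < 50 * n_pts + 100:
            attempts += 1
            s = rng.uniform(s_lo, s_hi)
            if any(a - 1.5 * r_nuc_um <= s <= b + 1.5 * r_nuc_um for a, b in spans):
                continue
            u = rng.uniform(lo + r_nuc_px, hi - r_nuc_px)
            if any(
                (s / px - ps) ** 2 + (u - pu) ** 2 < min_sep_px**2 for ps, pu in placed
            ):
                continue
            placed.append((s / px, u))
        for s_px_val, u in placed:
            x, y = _band_to_pixel(s_px_val, u, straight, apex_row, center, radius)
            nuclei.append((float(x), float(y), layer))
            _paint_disk(img, x, y, r_nuc_px, NUCLEUS_RGB)

    # --- cut ruptures (after nuclei so gaps stay background) -------------
    for a, b in spans:
        cut = in_band & (s_um >= a) & (s_um <= b)
        img[cut] = BACKGROUND_RGB

    # --- noise ------------------------------------------------------------
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    rgb = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        boundary_curves=bounds,
        layer_names=LAYER_ORDER,
        nuclei_centers=nuclei,
        rupture_spans=spans,
        layer_thickness_um={k: float(spec.layer_thicknesses_um[k]) for k in LAYER_ORDER},
        midline_row_px=float(apex_row),
        arc_radius_px=float(radius),
        arc_center_px=(float(center[0]), float(center[1])),
        arclength_total_um=arclength_total,
    )
    return AnnotatedRetinaImage(rgb=rgb, pixel_size_um=px, ground_truth=truth), truth


def _band_to_pixel(s_px, u_px, straight, apex_row, center, radius):
    """Map (arclength, normal offset) in pixels to (x=col, y=row)."""
    if straight:
        return s_px, apex_row + u_px
    cy, cx = center
    theta_left = -np.arcsin(cx / radius)
    theta = theta_left + s_px / radius
    r = radius - u_px
    return cx + r * np.sin(theta), cy - r * np.cos(theta)


def _paint_disk(img: np.ndarray, x: float, y: float, r_px: float, color) -> None:
    rows, cols = img.shape[:2]
    r_int = int(np.ceil(r_px)) + 1
    y0, y1 = max(0, int(y) - r_int), min(rows, int(y) + r_int + 1)
    x0, x1 = max(0, int(x) - r_int), min(cols, int(x) + r_int + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (yy - y) ** 2 + (xx - x) ** 2 <= r_px**2
    img[y0:y1, x0:x1][mask] = color


# ---------------------------------------------------------------------------
# ERG traces
# ---------------------------------------------------------------------------

_VALID_INTENSITIES = (0.3, 0.6, 0.9, 1.2)


@dataclass(frozen=True)
class ERGSpec:
    """Parameters of one synthetic scotopic flash-ERG recording."""

    sampling_rate: float = 2000.0
    duration_ms: float = 250.0
    stimulus_onset_ms: float = 20.0
    a_amplitude_uv: float = 150.0
    a_latency_ms: float = 15.0
    b_amplitude_uv: float = 450.0
    b_latency_ms: float = 45.0
    n_repetitions: int = 16
    noise_sd_uv: float = 0.0
    intensity_log_cds_m2: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0 or self.duration_ms <= 0:
            raise ValidationError("sampling_rate and duration_ms must be > 0")
        if self.n_repetitions < 1:
            raise ValidationError("n_repetitions must be >= 1")
        if self.a_amplitude_uv < 0 or self.b_amplitude_uv < 0:
            raise ValidationError("amplitudes must be >= 0")
        if self.b_latency_ms <= self.a_latency_ms:
            raise ValidationError("b_latency_ms must exceed a_latency_ms")
        if self.stimulus_onset_ms + self.b_latency_ms >= self.duration_ms:
            raise ValidationError("b wave falls outside the record")
        if self.noise_sd_uv < 0:
            raise ValidationError("noise_sd_uv must be >= 0")
        if self.intensity_log_cds_m2 not in _VALID_INTENSITIES:
            raise ValidationError(
                f"intensity_log_cds_m2 must be one of {_VALID_INTENSITIES}"
            )


@dataclass
class SyntheticERGTrace:
    """Raw repetitions on a uniform time grid plus the generating spec."""

    time_ms: np.ndarray
    voltage_uv: np.ndarray  # (n_repetitions, n_samples)
    stimulus_onset_ms: float
    intensity_log_cds_m2: float
    sampling_rate_hz: float
    truth: ERGSpec | None = None


def _gauss_lobe(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def generate_erg_trace(spec: ERGSpec) -> SyntheticERGTrace:
    """Synthesize repeated flash responses with known a/b-wave features.

    The clean response is a negative Gaussian lobe at ``a_latency_ms`` after
    onset (depth ``a_amplitude_uv`` below baseline) followed by a positive
    lobe at ``b_latency_ms`` scaled so the trough-to-peak excursion equals
    ``b_amplitude_uv``.  Lobe widths are a sixth of the a-b separation, so
    cross-talk between lobes is below 1e-5 uV and the analytic extrema are
    exact to the sampling grid.  i.i.d. Gaussian noise is then added per
    repetition.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dt_ms = 1000.0 / spec.sampling_rate
    n = int(round(spec.duration_ms / dt_ms))
    t = np.arange(n) * dt_ms
    t_a = spec.stimulus_onset_ms + spec.a_latency_ms
    t_b = spec.stimulus_onset_ms + spec.b_latency_ms
    sigma = (spec.b_latency_ms - spec.a_latency_ms) / 6.0
    sigma = min(sigma, spec.a_latency_ms / 6.0) if spec.a_latency_ms > 0 else sigma
    clean = np.zeros(n)
    if spec.a_amplitude_uv > 0:
        clean -= spec.a_amplitude_uv * _gauss_lobe(t, t_a, sigma)
    if spec.b_amplitude_uv > 0:
        # peak such that trough-to-peak equals b_amplitude
        peak = spec.b_amplitude_uv - (spec.a_amplitude_uv if spec.a_amplitude_uv > 0 else 0.0)
        clean += peak * _gauss_lobe(t, t_b, sigma)
    reps = clean[None, :] + rng.normal(0.0, spec.noise_sd_uv, size=(spec.n_repetitions, n))
    return SyntheticERGTrace(
        time_ms=t,
        voltage_uv=reps,
        stimulus_onset_ms=spec.stimulus_onset_ms,
        intensity_log_cds_m2=spec.intensity_log_cds_m2,
        sampling_rate_hz=spec.sampling_rate,
        truth=spec,
    )


# ---------------------------------------------------------------------------
# Two-group measurement tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Two-group table generator: per-variable location shifts plus noise."""

    n_per_group: int = 4
    subunit_effects: dict[str, float] = field(
        default_factory=lambda: {
            "alpha-Sg": 0.13,
            "beta-Sg": -0.16,
            "gamma-Sg": -0.78,
            "delta-Sg": -1.08,
            "epsilon-Sg": -0.08,
            "Sspn": -0.18,
        }
    )
    noise_sd: float = 0.05
    distribution: str = "normal"
    baseline: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.distribution not in ("normal", "lognormal"):
            raise ValidationError("distribution must be 'normal' or 'lognormal'")


def generate_group_measurements(spec: GroupSpec) -> pd.DataFrame:
    """Draw a (group, subunit, value) table with planted location shifts.

    Group 1 values are ``baseline + noise``; group 2 values are shifted by
    the per-subunit effect.  With all effects zero the groups are
    exchangeable draws from the same distribution.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for subunit, effect in spec.subunit_effects.items():
        for group, shift in (("group1", 0.0), ("group2", effect)):
            if spec.distribution == "normal":
                vals = spec.baseline + shift + rng.normal(0, spec.noise_sd, spec.n_per_group)
            else:
                vals = shift + np.exp(
                    rng.normal(np.log(spec.baseline), spec.noise_sd, spec.n_per_group)
                )
            for v in vals:
                rows.append({"group": group, "subunit": subunit, "value": float(v)})
    return pd.DataFrame(rows, columns=["group", "subunit", "value"])


def make_variant(spec, **kwargs):
    """Convenience: dataclass ``replace`` that works for all spec types."""
    return replace(spec, **kwargs)
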