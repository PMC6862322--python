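"""Shared fixtures: session-scoped synthetic scenes to keep the suite fast."""

from __future__ import annotations

import numpy as np
import pytest

from retinaquant import imageprep, morphometry, synthgen

DENSITY_LAYERS = {
    "ChRPE": 4, "PR_outer_segment": 6, "PR_inner_segment": 6,
    "ONL": 24, "OPL": 8, "INL": 18, "IPL": 8, "GCL": 4,
}


@pytest.fixture(scope="session")
def wt_spec() -> synthgen.RetinaSpec:
    """Clean curved retina, no ruptures, no nuclei (thickness/curve tests)."""
    return synthgen.RetinaSpec(
        image_size_px=(640, 1500), pixel_size_um=1.0, curvature=0.02, seed=11
    )


@pytest.fixture(scope="session")
def wt_scene(wt_spec):
    img, truth = synthgen.generate_retina_image(wt_spec)
    gray = imageprep.rgb_to_luminance(img.rgb, wt_spec.pixel_size_um)
    mask = imageprep.extract_retina(gray)
    curve = morphometry.fit_retinal_curve(mask)
    return img, truth, gray, mask, curve


@pytest.fixture(scope="session")
def ruptured_spec() -> synthgen.RetinaSpec:
    return synthgen.RetinaSpec(
        image_size_px=(640, 1500),
        pixel_size_um=1.0,
        curvature=0.02,
        n_ruptures=13,
        rupture_width_um=20.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def ruptured_scene(ruptured_spec):
    img, truth = synthgen.generate_retina_image(ruptured_spec)
    gray = imageprep.rgb_to_luminance(img.rgb, ruptured_spec.pixel_size_um)
    mask = imageprep.extract_retina(gray)
    curve = morphometry.fit_retinal_curve(mask)
    return img, truth, gray, mask, curve


@pytest.fixture(scope="session")
def density_spec() -> synthgen.RetinaSpec:
    """High-magnification patch with nucleated ONL/INL."""
    return synthgen.RetinaSpec(
        image_size_px=(360, 800),
        pixel_size_um=0.25,
        layer_thicknesses_um=dict(DENSITY_LAYERS),
        curvature=0.0,
        onl_density_per100um2=2.5,
        inl_density_per100um2=1.6,
        nucleus_radius_um=1.2,
        seed=21,
    )


@pytest.fixture(scope="session")
def density_scene(density_spec):
    img, truth = synthgen.generate_retina_image(density_spec)
    gray = imageprep.rgb_to_luminance(img.rgb, density_spec.pixel_size_um)
    mask = imageprep.extract_retina(gray)
    curve = morphometry.fit_retinal_curve(mask)
    return img, truth, gray, mask, curve


def band_pixels(truth, shape) -> np.ndarray:
    """Boolean mask of pixels between the outer and inner ground-truth curves."""
    rows, cols = shape[:2]
    yy = np.arange(rows)[:, None]
    outer = truth.boundary_curves[0][None, :]
    inner = truth.boundary_curves[-1][None, :]
    return (yy >= outer) & (yy < inner)
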