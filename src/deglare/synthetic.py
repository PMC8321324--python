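"""Synthetic test charts and forward veiling-glare degradation.

Generates Siemens-star resolution targets and degrades them by exact
convolution with the glare kernel — the forward model of the restoration —
so that the induced glare angle is known ground truth.  Also builds seeded
reference/test fixture sets for training and exercising the no-reference
quality model.

The reference charts deliberately stay in the same "imaging domain" as the
canonical test chart (full-contrast stars with neighbouring spoke counts):
a no-reference model trained on statistically alien references biases the
iteration-stopping rule, exactly as NIQE-style metrics require
domain-matched reference corpora on real imagery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gsf import GSFCurveParams, build_kernel
from .richardson_lucy import convolve

__all__ = ["StarSpec", "siemens_star", "fundus_chart", "degrade", "make_fixture_set"]

#: Induced glare angles (degrees) of the default test fixtures.
DEFAULT_TEST_ANGLES = (1.0, 2.0, 5.0, 6.0)

#: Spoke counts sampled for reference charts (even, near the 32-spoke target).
REFERENCE_SPOKES = (24, 26, 28, 30, 34, 36, 38, 40, 42, 44)


@dataclass(frozen=True)
class StarSpec:
    """Siemens-star geometry: square size, spoke count, Michelson-like
    contrast between the two sector levels, and rotation phase (degrees)."""

    size: int = 400
    n_spokes: int = 32
    contrast: float = 1.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("size must be at least 64 pixels")
        if self.n_spokes < 4 or self.n_spokes % 2 != 0:
            raise ValueError("n_spokes must be an even integer >= 4")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")


def siemens_star(spec: StarSpec = StarSpec(), *, supersample: int = 4) -> np.ndarray:
    """Render a centred Siemens star in [0, 1].

    Alternating angular sectors at levels ``(1 - contrast)/2`` and
    ``(1 + contrast)/2`` inside a disc of radius ``0.45 * size``; the
    surround sits at the low level.  Rendered at ``supersample`` times the
    target resolution and box-downsampled to soften aliasing.  Fully
    deterministic.
    """
    n = spec.size * supersample
    centre = (n - 1) / 2.0
    coords = np.arange(n) - centre
    yy = coords[:, None]
    xx = coords[None, :]
    theta = np.arctan2(yy, xx) - np.deg2rad(spec.phase)
    rr = np.hypot(yy, xx)
    sector = np.floor((theta + np.pi) / (2 * np.pi / spec.n_spokes)).astype(int) % 2
    low = (1.0 - spec.contrast) / 2.0
    img = low + spec.contrast * sector
    img = np.where(rr <= 0.45 * n, img, low)
    return img.reshape(spec.size, supersample, spec.size, supersample).mean(axis=(1, 3))


def fundus_chart(
    size: int = 400,
    seed: int = 0,
    *,
    n_vessels: int = 9,
    vessel_contrast: float = 0.18,
    supersample: int = 2,
) -> np.ndarray:
    """Synthetic fundus-like chart: vignetted background, a soft-edged
    bright disc, and thin dark vessel arcs radiating from it.

    A stand-in for retinal photographs in edge-segmentation experiments:
    the faint vessel edges drop below a fixed Canny threshold once veiling
    glare compresses local contrast, and reappear after restoration.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = size * supersample
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    centre = (n - 1) / 2.0
    rr = np.hypot(yy - centre, xx - centre) / (n / 2.0)
    img = 0.50 - 0.10 * rr**2
    disc = (
        centre + 0.25 * n * rng.uniform(-1, 1),
        centre + 0.25 * n * rng.uniform(-1, 1),
    )
    rd = np.hypot(yy - disc[0], xx - disc[1])
    img += 0.22 / (1.0 + np.exp((rd - 0.09 * n) / (0.01 * n)))
    mask = np.zeros((n, n), dtype=bool)
    for _ in range(n_vessels):
        angle = rng.uniform(0.0, 2 * np.pi)
        curvature = rng.uniform(-1.5, 1.5)
        width = rng.uniform(1.2, 2.4) * supersample
        t = np.linspace(0.0, 0.48 * n, 600)
        a = angle + curvature * t / n
        py = disc[0] + t * np.sin(a)
        px = disc[1] + t * np.cos(a)
        inside = (py >= 0) & (py < n) & (px >= 0) & (px < n)
        for y, x in zip(py[inside], px[inside]):
            y0, y1 = int(max(0, y - width - 1)), int(min(n, y + width + 2))
            x0, x1 = int(max(0, x - width - 1)), int(min(n, x + width + 2))
            d = np.hypot(yy[y0:y1, x0:x1] - y, xx[y0:y1, x0:x1] - x)
            mask[y0:y1, x0:x1] |= d <= width
    img = np.where(mask, img - vessel_contrast, img)
    img = np.clip(img, 0.0, 1.0)
    return img.reshape(size, supersample, size, supersample).mean(axis=(1, 3))


def degrade(
    image: np.ndarray,
    glare_angle: float,
    params: GSFCurveParams = GSFCurveParams(),
    degrees_per_pixel: float | None = None,
    *,
    support_factor: float = 3.0,
) -> np.ndarray:
    """Apply the forward veiling-glare model at ``glare_angle`` degrees.

    ``glare_angle = 0`` returns the input unchanged.  ``degrees_per_pixel``
    defaults to a 45-degree field of view across the image width.
    """
    if glare_angle < 0:
        raise ValueError("glare_angle must be non-negative")
    img = np.asarray(image, dtype=float)
    if glare_angle == 0:
        return img.copy()
    dpp = degrees_per_pixel or 45.0 / img.shape[1]
    kernel = build_kernel(
        img.shape, glare_angle, dpp, params, support_factor=support_factor
    )
    return convolve(img, kernel)


def make_fixture_set(
    n_reference: int,
    n_test: int,
    seed: int,
    *,
    size: int = 400,
    test_angles: tuple[float, ...] = DEFAULT_TEST_ANGLES,
    params: GSFCurveParams = GSFCurveParams(),
) -> tuple[list[np.ndarray], list[tuple[np.ndarray, float]]]:
    """Seeded reference charts plus (degraded chart, true angle) test pairs.

    References are clean full-contrast stars whose spoke counts span the
    chart family evenly (a balanced reference corpus: the block features --
    luminance variance and mean sharpness -- scale with chart contrast and
    spoke density, so a contrast-mismatched or spoke-skewed pool would
    displace the pooled Gaussian away from any fully restored chart) and
    whose rotation phases are seeded; tests are the canonical 32-spoke
    full-contrast star degraded at angles cycling through ``test_angles``.
    Identical seeds give bit-identical sets.
    """
    if n_reference < 1 or n_test < 1:
        raise ValueError("fixture counts must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = REFERENCE_SPOKES[0], REFERENCE_SPOKES[-1]
    spans = np.linspace(lo, hi, n_reference) if n_reference > 1 else [32]
    references = []
    for spokes in spans:
        spokes = int(round(spokes / 2) * 2)
        phase = float(rng.uniform(0.0, 360.0))
        references.append(siemens_star(StarSpec(size, spokes, 1.0, phase)))
    target = siemens_star(StarSpec(size, 32, 1.0))
    tests = []
    for i in range(n_test):
        alpha = float(test_angles[i % len(test_angles)])
        tests.append((degrade(target, alpha, params), alpha))
    return references, tests
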