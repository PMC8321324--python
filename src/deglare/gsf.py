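"""CIE glare-spread-function curve and the 2-D veiling-glare kernel.

Intraocular straylight superimposes a wide-angle veil on the retinal image.
The CIE general disability-glare equation gives the relative veiling
luminance ``GSF(theta)`` produced by a glare source at angular distance
``theta`` (degrees), parametrised by observer age and ocular pigmentation.
Here that curve is turned into a normalised 2-D convolution kernel: the
degradation operator of the forward model ``observed = kernel * true``.

The searched glare angle ``alpha`` acts as the angular scale of the veil:
the kernel samples the CIE curve with its angular axis stretched by
``alpha`` (``alpha = 0`` collapses to the identity/delta kernel).  Because
the curve's forward peak is far narrower than one pixel at fundus-camera
sampling (45 deg over a few hundred pixels), the central pixel is assigned
the analytic average of the curve over its own footprint rather than the
point value at zero; all five CIE terms have closed-form radial integrals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GSFCurveParams",
    "GSFKernel",
    "gsf_value",
    "gsf_disc_integral",
    "build_kernel",
    "flip_kernel",
    "save_kernel",
    "load_kernel",
]

#: Angular half-widths (degrees) of the three CIE scatter lobes.
_A1, _A2, _A3 = 0.0046, 0.045, 0.1


@dataclass(frozen=True)
class GSFCurveParams:
    """Observer parameters of the CIE disability-glare curve.

    age
        Observer age in years; wide-angle scatter grows as ``(age/70)**4``.
    pigment_factor
        Ocular pigmentation factor (0 = dark-pigmented, ~1.2 = light blue
        eyes); dimensionless, non-negative.
    """

    age: float = 70.0
    pigment_factor: float = 0.5

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.pigment_factor < 0:
            raise ValueError(
                f"pigment_factor must be non-negative, got {self.pigment_factor}"
            )


def gsf_value(angle, params: GSFCurveParams = GSFCurveParams()):
    """Evaluate the CIE disability-glare curve at ``angle`` degrees.

    Implements the CIE general equation

    .. math::

        GSF(\\theta) = [1 - 0.08 (A/70)^4]
            \\Big[ \\frac{9.2\\cdot 10^6}{(1+(\\theta/0.0046)^2)^{1.5}}
                 + \\frac{1.5\\cdot 10^5}{(1+(\\theta/0.045)^2)^{1.5}} \\Big]
            + [1 + 1.6 (A/70)^4]
            \\Big[ \\frac{400}{1+(\\theta/0.1)^2} + 3\\cdot 10^{-8}\\theta^2
                 + PF\\big( \\frac{1300}{(1+(\\theta/0.1)^2)^{1.5}}
                          + \\frac{0.8}{(1+(\\theta/0.1)^2)^{0.5}} \\big) \\Big]
            + 2.5\\cdot 10^{-3}\\, PF

    with age ``A`` in years and pigment factor ``PF``.  Finite and strictly
    positive for every finite angle, strictly decreasing for ``angle > 0``.

    Accepts scalars or arrays; raises ``ValueError`` on negative angles.
    """
    theta = np.asarray(angle, dtype=float)
    if np.any(theta < 0):
        raise ValueError("glare angle must be non-negative")
    a4 = (params.age / 70.0) ** 4
    pf = params.pigment_factor
    q1 = 1.0 + (theta / _A1) ** 2
    q2 = 1.0 + (theta / _A2) ** 2
    q3 = 1.0 + (theta / _A3) ** 2
    value = (1.0 - 0.08 * a4) * (9.2e6 / q1**1.5 + 1.5e5 / q2**1.5)
    value += (1.0 + 1.6 * a4) * (
        400.0 / q3 + 3e-8 * theta**2 + pf * (1300.0 / q3**1.5 + 0.8 / q3**0.5)
    )
    value += 2.5e-3 * pf
    if np.ndim(angle) == 0:
        return float(value)
    return value


def gsf_disc_integral(radius: float, params: GSFCurveParams = GSFCurveParams()) -> float:
    """Integral of the CIE curve over a disc of ``radius`` degrees.

    Closed form of ``int_0^R GSF(t) 2 pi t dt``; used to average the curve's
    forward peak over the central pixel's footprint.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    R = float(radius)
    a4 = (params.age / 70.0) ** 4
    pf = params.pigment_factor

    def lorentz15(c: float, a: float) -> float:
        # c/(1+(t/a)^2)^1.5 against 2*pi*t dt
        return 2 * np.pi * c * a * a * (1.0 - 1.0 / np.sqrt(1.0 + (R / a) ** 2))

    def lorentz1(c: float, a: float) -> float:
        return np.pi * c * a * a * np.log1p((R / a) ** 2)

    def lorentz05(c: float, a: float) -> float:
        return 2 * np.pi * c * a * a * (np.sqrt(1.0 + (R / a) ** 2) - 1.0)

    total = (1.0 - 0.08 * a4) * (lorentz15(9.2e6, _A1) + lorentz15(1.5e5, _A2))
    total += (1.0 + 1.6 * a4) * (
        lorentz1(400.0, _A3)
        + 3e-8 * 2 * np.pi * R**4 / 4.0
        + pf * (lorentz15(1300.0, _A3) + lorentz05(0.8, _A3))
    )
    total += 2.5e-3 * pf * np.pi * R * R
    return float(total)


@dataclass
class GSFKernel:
    """Normalised 2-D veiling-glare kernel.

    weights
        Square grid with odd side length, non-negative, summing to 1.
    degrees_per_pixel
        Angular calibration of the grid.
    glare_angle
        Angular scale ``alpha`` (degrees) of the veil this kernel models.
    truncation_angle
        Radial angle beyond which weights are exactly zero.
    params
        CIE curve parameters used to generate the weights.
    """

    weights: np.ndarray
    degrees_per_pixel: float
    glare_angle: float
    truncation_angle: float
    params: GSFCurveParams = field(default_factory=GSFCurveParams)

    @property
    def radius(self) -> int:
        """Pixel radius of the grid (side length = 2*radius + 1)."""
        return self.weights.shape[0] // 2

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] % 2 == 0 or w.shape[1] % 2 == 0:
            raise ValueError("kernel grid must be 2-D with odd side lengths")
        if np.any(w < 0):
            raise ValueError("kernel weights must be non-negative")
        self.weights = w


def build_kernel(
    image_shape: tuple[int, int],
    glare_angle: float,
    degrees_per_pixel: float,
    params: GSFCurveParams = GSFCurveParams(),
    *,
    support_factor: float = 3.0,
    crop: bool = True,
) -> GSFKernel:
    """Build the veiling-glare kernel for a glare angle ``glare_angle``.

    The grid's full pixel radius is twice ``max(image_shape)``.  A pixel at
    radial distance ``r`` (angle ``theta = r * degrees_per_pixel``) receives
    the CIE curve value at the stretched angle ``theta / glare_angle``; the
    central pixel receives the curve's analytic average over its own
    footprint.  Weights beyond ``support_factor * glare_angle`` degrees
    (where the stretched curve is negligible) are zero, and the whole grid
    is normalised to unit sum.

    ``glare_angle = 0`` yields the identity (delta) kernel.  With
    ``crop=True`` (default) the all-zero outer margin is removed; cropping
    does not change convolution output.
    """
    if glare_angle < 0:
        raise ValueError("glare_angle must be non-negative")
    if degrees_per_pixel <= 0:
        raise ValueError("degrees_per_pixel must be positive")
    rows, cols = image_shape
    if rows <= 0 or cols <= 0:
        raise ValueError("image_shape must be positive")

    full_radius = 2 * max(rows, cols)
    if glare_angle == 0:
        radius = 0 if crop else full_radius
        weights = np.zeros((2 * radius + 1, 2 * radius + 1))
        weights[radius, radius] = 1.0
        return GSFKernel(weights, degrees_per_pixel, 0.0, 0.0, params)

    truncation = min(support_factor * glare_angle, full_radius * degrees_per_pixel)
    support_px = int(np.floor(truncation / degrees_per_pixel))
    radius = support_px if crop else full_radius
    half = np.arange(-radius, radius + 1)
    rr = np.hypot(half[:, None], half[None, :])
    theta = rr * degrees_per_pixel
    with np.errstate(over="ignore"):
        weights = np.where(
            theta <= truncation, gsf_value(theta / glare_angle, params), 0.0
        )
    # forward-peak average over the central pixel's half-width
    h = degrees_per_pixel / 2.0 / glare_angle
    weights[radius, radius] = gsf_disc_integral(h, params) / (np.pi * h * h)
    weights /= weights.sum()
    return GSFKernel(weights, degrees_per_pixel, glare_angle, truncation, params)


def flip_kernel(kernel: GSFKernel) -> GSFKernel:
    """Reverse the kernel along both axes (the RL adjoint kernel).

    For the radially symmetric glare kernel this is the identity.
    """
    return GSFKernel(
        kernel.weights[::-1, ::-1].copy(),
        kernel.degrees_per_pixel,
        kernel.glare_angle,
        kernel.truncation_angle,
        kernel.params,
    )


def save_kernel(kernel: GSFKernel, path: str | Path) -> None:
    """Write the kernel grid plus its metadata header to an ``.npz`` file."""
    meta = {
        "degrees_per_pixel": kernel.degrees_per_pixel,
        "glare_angle": kernel.glare_angle,
        "truncation_angle": kernel.truncation_angle,
        "age": kernel.params.age,
        "pigment_factor": kernel.params.pigment_factor,
    }
    np.savez(path, weights=kernel.weights, meta=json.dumps(meta))


def load_kernel(path: str | Path) -> GSFKernel:
    with np.load(path) as data:
        meta = json.loads(str(data["meta"]))
        return GSFKernel(
            data["weights"],
            meta["degrees_per_pixel"],
            meta["glare_angle"],
            meta["truncation_angle"],
            GSFCurveParams(meta["age"], meta["pigment_factor"]),
        )
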