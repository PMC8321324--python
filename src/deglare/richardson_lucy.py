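"""Forward glare model and the Richardson-Lucy multiplicative update.

The forward model is ``observed = kernel * true`` (linear shift-invariant
convolution with the normalised glare kernel).  Richardson-Lucy inverts it
iteratively:

    estimate <- estimate * [ (observed / (estimate * K)) * K^T ]

where ``K^T`` is the both-axes-flipped kernel.  Starting from a
non-negative estimate every iterate stays non-negative, and when the
iteration converges it converges to the maximum-likelihood image under the
Poisson noise model.

Convolution runs in the frequency domain after padding the image by edge
replication out to the kernel's support radius (avoids wrap-around
ringing); a direct spatial-domain path exists for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .gsf import GSFKernel, flip_kernel

__all__ = ["RLState", "convolve", "convolve_direct", "rl_step", "rl_deconvolve"]

#: Denominator guard for the multiplicative ratio.
RATIO_EPS = 1e-12


@dataclass
class RLState:
    """Richardson-Lucy iterate: current estimate and iteration counter."""

    estimate: np.ndarray
    iteration: int = 0


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    if not np.all(np.isfinite(img)) or np.any(img < 0):
        raise ValueError("image values must be finite and non-negative")
    return img


def convolve(image: np.ndarray, kernel: GSFKernel) -> np.ndarray:
    """Convolve ``image`` with the glare kernel (edge-replicate boundary).

    Frequency-domain implementation; flux-conserving for interior-supported
    images because the kernel is normalised.  Output is clamped at zero to
    remove FFT round-off undershoot.
    """
    img = _check_image(image)
    pad = kernel.radius
    if pad == 0:
        return img * kernel.weights.sum()
    padded = np.pad(img, pad, mode="edge")
    if kernel.weights.shape[0] > padded.shape[0] or kernel.weights.shape[1] > padded.shape[1]:
        raise ValueError("kernel support exceeds the padded image domain")
    out = fftconvolve(padded, kernel.weights, mode="same")
    out = out[pad:-pad, pad:-pad]
    return np.clip(out, 0.0, None)


def convolve_direct(image: np.ndarray, kernel: GSFKernel) -> np.ndarray:
    """Spatial-domain convolution with the same boundary contract.

    Slow reference path (``scipy.ndimage`` with nearest/replicate padding)
    used to validate the frequency-domain route on small fixtures.
    """
    img = _check_image(image)
    return ndimage.convolve(img, kernel.weights, mode="nearest")


def rl_step(state: RLState, observed: np.ndarray, kernel: GSFKernel) -> RLState:
    """One Richardson-Lucy multiplicative update.

    Returns the next iterate; non-negativity is preserved and the ratio
    denominator is guarded by ``RATIO_EPS``.
    """
    est = _check_image(state.estimate)
    obs = _check_image(observed)
    if est.shape != obs.shape:
        raise ValueError(
            f"estimate shape {est.shape} != observed shape {obs.shape}"
        )
    denom = np.maximum(convolve(est, kernel), RATIO_EPS)
    correction = convolve(obs / denom, flip_kernel(kernel))
    return RLState(est * correction, state.iteration + 1)


def rl_deconvolve(
    observed: np.ndarray, kernel: GSFKernel, n_iterations: int
) -> np.ndarray:
    """Run ``n_iterations`` RL updates starting from the observed image.

    The returned estimate is non-negative but not clipped above 1;
    clipping/rescaling to display range happens only at export time.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    state = RLState(_check_image(observed))
    for _ in range(n_iterations):
        state = rl_step(state, observed, kernel)
    return state.estimate
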