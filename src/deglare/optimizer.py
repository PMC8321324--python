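"""Two-step semi-blind restoration: glare-angle search then iteration
optimisation.

Step 1 (glare-angle detection).  The glare kernel's functional form is
known (CIE curve) but its angular scale ``alpha`` is not.  The search walks
``alpha`` upward from zero in fixed steps; at each candidate it runs a
short fixed-length Richardson-Lucy probe with that kernel and measures the
sharpness of the probe after remapping it to full display range.  An
undersized kernel leaves veil in place (low sharpness); an oversized kernel
overcorrects, inflating the dynamic range faster than it adds gradient, so
the display-range sharpness has an interior maximum at the true angle.
Greedy hill climbing stops at the first decrease and returns the
predecessor (ties keep climbing).

Step 2 (iteration optimisation).  With the detected kernel fixed, full RL
iterations run while each iterate is scored by the trained block-statistics
quality model; the iteration at the maximum score (identified with a small
patience window to ride out block-selection jitter) is the stopping point,
and the best-scoring iterate is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gsf import GSFCurveParams, GSFKernel, build_kernel
from .quality import NIQEModel, niqe_score, sharpness
from .richardson_lucy import RLState, rl_step

logger = logging.getLogger(__name__)

__all__ = ["ITSDConfig", "RestorationResult", "detect_glare_angle",
           "optimize_iterations", "itsd_restore"]


@dataclass
class ITSDConfig:
    """Tunable parameters of the two-step restoration."""

    alpha_step: float = 1.0          # degrees per hill-climbing step
    alpha_max: float = 15.0          # search ceiling, degrees
    max_iterations: int = 200        # RL iteration ceiling in step 2
    probe_iterations: int = 10       # RL updates per step-1 probe
    patience: int = 3                # step-2 iterations without improvement
    degrees_per_pixel: float | None = None   # derived from FOV when None
    field_of_view_deg: float = 45.0
    gsf_params: GSFCurveParams = field(default_factory=GSFCurveParams)
    support_factor: float = 3.0

    def resolve_dpp(self, image_shape: tuple[int, int]) -> float:
        if self.degrees_per_pixel is not None:
            return self.degrees_per_pixel
        return self.field_of_view_deg / image_shape[1]


@dataclass
class RestorationResult:
    """Output of the full two-step restoration."""

    restored: np.ndarray
    detected_alpha: float
    optimal_iterations: int
    sharpness_trace: list[tuple[float, float]]
    niqe_trace: list[tuple[int, float]]
    kernel: GSFKernel


def _display_sharpness(image: np.ndarray) -> float:
    """Mean gradient magnitude after min-max remap to [0, 1].

    Restored probes are judged in display range; out-of-range overshoot
    from overcorrection therefore *divides* the measured gradients.
    """
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        return 0.0
    return sharpness((image - lo) / (hi - lo)).scalar


def _probe(observed: np.ndarray, kernel: GSFKernel, n: int) -> np.ndarray:
    state = RLState(observed)
    for _ in range(n):
        state = rl_step(state, observed, kernel)
    return state.estimate


def detect_glare_angle(
    observed: np.ndarray,
    params: GSFCurveParams = GSFCurveParams(),
    alpha_step: float = 1.0,
    alpha_max: float = 15.0,
    *,
    degrees_per_pixel: float | None = None,
    probe_iterations: int = 10,
    support_factor: float = 3.0,
    field_of_view_deg: float = 45.0,
) -> tuple[float, list[tuple[float, float]]]:
    """Hill-climb the glare angle by probe-deconvolution sharpness.

    Returns ``(alpha, trace)`` where ``trace`` lists every probed
    ``(alpha, sharpness)`` pair and ``alpha`` maximises the trace.  Returns
    0 when the very first deconvolution probe already reduces sharpness
    (undegraded input); returns ``alpha_max`` with a warning when the
    ceiling is reached without a decrease.
    """
    if alpha_step <= 0:
        raise ValueError("alpha_step must be positive")
    if alpha_max < alpha_step:
        raise ValueError("alpha_max must be at least alpha_step")
    obs = np.asarray(observed, dtype=float)
    dpp = degrees_per_pixel or field_of_view_deg / obs.shape[1]

    trace: list[tuple[float, float]] = []
    best_alpha = 0.0
    previous = -np.inf
    alpha = 0.0
    while alpha <= alpha_max + 1e-9:
        kernel = build_kernel(
            obs.shape, alpha, dpp, params, support_factor=support_factor
        )
        probe = obs if alpha == 0 else _probe(obs, kernel, probe_iterations)
        score = _display_sharpness(probe)
        trace.append((alpha, score))
        logger.info("step1 probe alpha=%.1f deg  S=%.6f", alpha, score)
        if score < previous:
            return best_alpha, trace
        best_alpha = alpha
        previous = score
        alpha = round(alpha + alpha_step, 10)
    logger.warning(
        "sharpness still climbing at alpha_max=%.1f deg; returning the ceiling",
        alpha_max,
    )
    return best_alpha, trace


def optimize_iterations(
    observed: np.ndarray,
    kernel: GSFKernel,
    model: NIQEModel,
    max_iterations: int = 200,
    *,
    patience: int = 3,
) -> tuple[int, np.ndarray, list[tuple[int, float]]]:
    """Run RL updates until the trained quality score passes its maximum.

    Each iterate is clipped to display range and scored; the search stops
    after ``patience`` consecutive iterations without improving on the best
    score (or at ``max_iterations``, with a warning).  Returns
    ``(best_iteration, best_estimate, trace)``.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    obs = np.asarray(observed, dtype=float)
    state = RLState(obs)
    trace: list[tuple[int, float]] = []
    best_it, best_score, best_est = 1, -np.inf, obs
    stale = 0
    for it in range(1, max_iterations + 1):
        state = rl_step(state, obs, kernel)
        score = niqe_score(np.clip(state.estimate, 0.0, 1.0), model)
        trace.append((it, score))
        logger.info("step2 iteration=%d  score=%.5f", it, score)
        if score > best_score:
            best_it, best_score, best_est = it, score, state.estimate.copy()
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                return best_it, best_est, trace
    logger.warning(
        "quality score still improving at max_iterations=%d; returning best so far",
        max_iterations,
    )
    return best_it, best_est, trace


def itsd_restore(
    observed: np.ndarray,
    model: NIQEModel,
    config: ITSDConfig = ITSDConfig(),
) -> RestorationResult:
    """Full semi-blind restoration: detect the glare angle, then optimise
    the RL iteration count, returning the best-scoring restored image along
    with both search traces and the learned kernel.

    A detected angle of zero short-circuits to the identity restoration.
    """
    obs = np.asarray(observed, dtype=float)
    dpp = config.resolve_dpp(obs.shape)
    alpha, s_trace = detect_glare_angle(
        obs,
        config.gsf_params,
        config.alpha_step,
        config.alpha_max,
        degrees_per_pixel=dpp,
        probe_iterations=config.probe_iterations,
        support_factor=config.support_factor,
    )
    kernel = build_kernel(
        obs.shape, alpha, dpp, config.gsf_params,
        support_factor=config.support_factor,
    )
    if alpha == 0:
        logger.info("no glare detected; returning the input unchanged")
        return RestorationResult(obs.copy(), 0.0, 1, s_trace, [(1, 0.0)], kernel)
    n_it, restored, q_trace = optimize_iterations(
        obs, kernel, model, config.max_iterations, patience=config.patience
    )
    logger.info("detected alpha=%.1f deg, optimal iterations=%d", alpha, n_it)
    return RestorationResult(restored, alpha, n_it, s_trace, q_trace, kernel)
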