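"""Image-quality metrics: sharpness, SSIM, and the trained block-statistics
no-reference quality model.

Sharpness is the mean gradient magnitude (acutance proxy).  SSIM is the
standard structural-similarity index.  The no-reference model is a trained
NIQE-style evaluator: images are tiled into blocks, each block yields a
small feature vector (mean luminance, luminance variance, mean sharpness),
a multivariate Gaussian is fitted to the pooled features of a reference
image set, and a test image is scored by the symmetric Mahalanobis-type
distance between its own feature Gaussian and the reference Gaussian.

Sign convention: ``score = -distance``, so a *higher* score means the image
is statistically closer to the reference set, and "maximum score" is the
stopping criterion of the iteration optimiser.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.metrics import structural_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "SharpnessMap",
    "SSIMResult",
    "BlockFeatures",
    "NIQEModel",
    "sharpness",
    "ssim",
    "extract_block_features",
    "train_niqe",
    "niqe_score",
    "save_model",
    "load_model",
]

_FEATURE_DIM = 3
_COV_REG = 1e-8


@dataclass
class SharpnessMap:
    """Per-pixel gradient magnitude and its mean."""

    values: np.ndarray
    scalar: float


@dataclass
class SSIMResult:
    """Global SSIM index and the local SSIM map."""

    index: float
    map: np.ndarray


@dataclass
class BlockFeatures:
    """Per-block feature vectors of one image.

    ``features`` has one row per retained block with columns
    (mean luminance, luminance variance, mean sharpness).
    ``n_blocks_total`` counts all complete blocks before selection.
    """

    features: np.ndarray
    block_size: int
    n_blocks_total: int


@dataclass
class NIQEModel:
    """Multivariate Gaussian over block features of a reference image set."""

    mean_vector: np.ndarray
    covariance_matrix: np.ndarray
    block_size: int
    selection_percentile: float
    n_reference_images: int = 0
    n_blocks: int = 0
    degenerate: bool = False


def sharpness(image: np.ndarray) -> SharpnessMap:
    """Gradient-magnitude sharpness map ``S = sqrt(Gx^2 + Gy^2)``.

    Gradients are central differences on interior pixels and one-sided at
    the borders; the scalar is the mean of the map.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError("sharpness requires a 2-D image of at least 2x2 pixels")
    gy, gx = np.gradient(img)
    values = np.hypot(gx, gy)
    return SharpnessMap(values, float(values.mean()))


def ssim(
    test: np.ndarray,
    reference: np.ndarray,
    *,
    gaussian_window: bool = True,
    win_size: int = 11,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float = 1.0,
) -> SSIMResult:
    """Structural similarity between ``test`` and ``reference``.

    Defaults follow the canonical formulation: 11x11 Gaussian window with
    sigma 1.5, K1=0.01, K2=0.03, dynamic range 1.  ``gaussian_window=False``
    switches to a uniform window of the same size.
    """
    a = np.asarray(test, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    index, smap = structural_similarity(
        a,
        b,
        win_size=win_size,
        gaussian_weights=gaussian_window,
        sigma=sigma,
        K1=k1,
        K2=k2,
        data_range=data_range,
        use_sample_covariance=not gaussian_window,
        full=True,
    )
    return SSIMResult(float(index), smap)


def extract_block_features(
    image: np.ndarray,
    block_size: int,
    *,
    selection_percentile: float = 25.0,
) -> BlockFeatures:
    """Tile the image into non-overlapping blocks and extract features.

    Incomplete edge blocks are discarded.  Blocks whose mean sharpness falls
    below ``selection_percentile`` of the per-block sharpness distribution
    (low-information blocks) are dropped; set the percentile to 0 to keep
    every block.
    """
    img = np.asarray(image, dtype=float)
    if block_size <= 1:
        raise ValueError("block_size must be > 1")
    if img.ndim != 2 or img.shape[0] < block_size or img.shape[1] < block_size:
        raise ValueError("image must be at least one block in each dimension")
    br, bc = img.shape[0] // block_size, img.shape[1] // block_size
    crop = img[: br * block_size, : bc * block_size]
    tiles = crop.reshape(br, block_size, bc, block_size)
    smap = sharpness(img).values[: br * block_size, : bc * block_size]
    stiles = smap.reshape(br, block_size, bc, block_size)

    mean_lum = tiles.mean(axis=(1, 3)).ravel()
    var_lum = tiles.var(axis=(1, 3)).ravel()
    mean_sharp = stiles.mean(axis=(1, 3)).ravel()

    if selection_percentile > 0:
        threshold = np.percentile(mean_sharp, selection_percentile)
        keep = mean_sharp >= threshold
    else:
        keep = np.ones_like(mean_sharp, dtype=bool)
    features = np.stack(
        [mean_lum[keep], var_lum[keep], mean_sharp[keep]], axis=1
    )
    return BlockFeatures(features, block_size, int(br * bc))


def _fit_gaussian(features: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    mean = features.mean(axis=0)
    cov = np.cov(features.T, bias=True)  # population form: pooling
    # duplicated references must leave the model unchanged
    cov = np.atleast_2d(cov)
    scale = np.trace(cov) / _FEATURE_DIM
    degenerate = False
    eigvals = np.linalg.eigvalsh(cov)
    if scale == 0 or eigvals.min() < 1e-10 * max(scale, 1e-30):
        degenerate = True
    return mean, cov, degenerate


def train_niqe(
    reference_images: Sequence[np.ndarray],
    block_size: int = 40,
    *,
    selection_percentile: float = 25.0,
) -> NIQEModel:
    """Fit the reference Gaussian over pooled block features.

    Blocks retained by the per-image selection rule are pooled across all
    reference images; the model stores their mean vector and covariance.
    Raises ``ValueError`` when fewer than ``feature_dim + 1`` blocks remain.
    """
    if len(reference_images) == 0:
        raise ValueError("at least one reference image is required")
    pooled = [
        extract_block_features(
            img, block_size, selection_percentile=selection_percentile
        ).features
        for img in reference_images
    ]
    features = np.vstack(pooled)
    if features.shape[0] < _FEATURE_DIM + 1:
        raise ValueError(
            f"need at least {_FEATURE_DIM + 1} retained blocks to fit a "
            f"covariance, got {features.shape[0]}"
        )
    mean, cov, degenerate = _fit_gaussian(features)
    if degenerate:
        warnings.warn(
            "reference block features are (near-)degenerate; covariance "
            "will be regularized",
            RuntimeWarning,
            stacklevel=2,
        )
    return NIQEModel(
        mean_vector=mean,
        covariance_matrix=cov,
        block_size=block_size,
        selection_percentile=selection_percentile,
        n_reference_images=len(reference_images),
        n_blocks=int(features.shape[0]),
        degenerate=degenerate,
    )


def _regularize(cov: np.ndarray) -> np.ndarray:
    scale = np.trace(cov) / _FEATURE_DIM
    eigvals = np.linalg.eigvalsh(cov)
    if scale == 0 or eigvals.min() < 1e-10 * max(scale, 1e-30):
        return cov + np.eye(_FEATURE_DIM) * _COV_REG * max(scale, 1.0)
    return cov


def niqe_score(image: np.ndarray, model: NIQEModel) -> float:
    """Score ``image`` against the trained reference model.

    Fits the test Gaussian to the image's block features (same block size
    and selection rule as training) and returns ``-d`` with

        d = sqrt( (m_r - m_t)^T [ (C_r + C_t)/2 ]^{-1} (m_r - m_t) )

    Zero for an image whose block statistics equal the reference's; more
    negative the further the statistics drift.
    """
    blocks = extract_block_features(
        image, model.block_size, selection_percentile=model.selection_percentile
    )
    if blocks.features.shape[0] < 2:
        raise ValueError("image too small: need at least 2 blocks to score")
    mean_t, cov_t, degenerate = _fit_gaussian(blocks.features)
    if degenerate or model.degenerate:
        logger.warning("degenerate block covariance; regularizing")
    pooled = _regularize((model.covariance_matrix + cov_t) / 2.0)
    diff = model.mean_vector - mean_t
    d2 = float(diff @ np.linalg.solve(pooled, diff))
    return -float(np.sqrt(max(d2, 0.0)))


def save_model(model: NIQEModel, path: str | Path) -> None:
    """Persist the model as JSON (exact float round-trip)."""
    payload = {
        "block_size": model.block_size,
        "selection_percentile": model.selection_percentile,
        "mean_vector": model.mean_vector.tolist(),
        "covariance_matrix": model.covariance_matrix.tolist(),
        "n_reference_images": model.n_reference_images,
        "n_blocks": model.n_blocks,
        "degenerate": model.degenerate,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> NIQEModel:
    payload = json.loads(Path(path).read_text())
    return NIQEModel(
        mean_vector=np.array(payload["mean_vector"], dtype=float),
        covariance_matrix=np.array(payload["covariance_matrix"], dtype=float),
        block_size=int(payload["block_size"]),
        selection_percentile=float(payload["selection_percentile"]),
        n_reference_images=int(payload["n_reference_images"]),
        n_blocks=int(payload["n_blocks"]),
        degenerate=bool(payload["degenerate"]),
    )
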