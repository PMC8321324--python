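"""Image I/O, run configuration, and the flat metrics report.

Images are read with :mod:`imageio` and scaled to floats in [0, 1]
(16-bit inputs keep their full precision before scaling).  RGB inputs are
kept alongside the BT.601 grayscale plane used for restoration.  The
metrics report mirrors the quality columns of the restoration experiments:
sharpness, SSIM, trained quality score and Canny edge counts for the
original/degraded/restored triplet.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .gsf import GSFCurveParams
from .optimizer import ITSDConfig
from .quality import NIQEModel, load_model, niqe_score, save_model, sharpness, ssim
from .segmentation import segment_pair, to_grayscale

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_image",
    "write_image",
    "evaluate",
    "write_report",
    "save_model",
    "load_model",
]


@dataclass
class RunConfig:
    """Validated configuration for the command-line pipeline."""

    age: float = 70.0
    pigment_factor: float = 0.5
    field_of_view_deg: float = 45.0
    degrees_per_pixel: float | None = None
    alpha_step: float = 1.0
    alpha_max: float = 15.0
    max_iterations: int = 200
    probe_iterations: int = 10
    patience: int = 3
    support_factor: float = 3.0
    block_size: int = 40
    selection_percentile: float = 25.0
    canny_sensitivity: float = 0.2
    canny_sigma: float = 1.4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        config.validate()
        return config

    def validate(self) -> None:
        if self.alpha_step <= 0 or self.alpha_max < self.alpha_step:
            raise ValueError("require alpha_step > 0 and alpha_max >= alpha_step")
        if self.max_iterations < 1 or self.probe_iterations < 1:
            raise ValueError("iteration counts must be >= 1")
        if not 0 < self.canny_sensitivity < 1:
            raise ValueError("canny_sensitivity must lie in (0, 1)")
        GSFCurveParams(self.age, self.pigment_factor)

    def gsf_params(self) -> GSFCurveParams:
        return GSFCurveParams(self.age, self.pigment_factor)

    def itsd(self) -> ITSDConfig:
        return ITSDConfig(
            alpha_step=self.alpha_step,
            alpha_max=self.alpha_max,
            max_iterations=self.max_iterations,
            probe_iterations=self.probe_iterations,
            patience=self.patience,
            degrees_per_pixel=self.degrees_per_pixel,
            field_of_view_deg=self.field_of_view_deg,
            gsf_params=self.gsf_params(),
            support_factor=self.support_factor,
        )

    def log_effective(self) -> None:
        logger.info("effective config: %s", asdict(self))


def read_image(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a raster image as ``(grayscale, rgb-or-None)`` floats in [0,1]."""
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise IOError(f"cannot read image file {path}") from exc
    arr = np.asarray(raw)
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(float) / 65535.0
    else:
        arr = arr.astype(float)
        if arr.max() > 1.0:
            arr = arr / arr.max()
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        return to_grayscale(arr), arr
    return arr, None


def write_image(image: np.ndarray, path: str | Path, *, bit_depth: int = 16) -> None:
    """Write an image in [0, 1] as an 8- or 16-bit raster file."""
    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if arr.ndim == 3 and bit_depth == 16:
        bit_depth = 8  # 16-bit colour PNG is not portable across backends
    if bit_depth == 16:
        out = np.round(arr * 65535.0).astype(np.uint16)
    elif bit_depth == 8:
        out = np.round(arr * 255.0).astype(np.uint8)
    elif bit_depth == 1:
        out = (arr > 0.5).astype(np.uint8) * 255
    else:
        raise ValueError("bit_depth must be 1, 8 or 16")
    try:
        iio.imwrite(path, out)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write image file {path}") from exc


def evaluate(
    original: np.ndarray,
    degraded: np.ndarray,
    restored: np.ndarray,
    *,
    model: NIQEModel | None = None,
    canny_sensitivity: float = 0.2,
) -> dict[str, float]:
    """Flat metrics report for an original/degraded/restored triplet."""
    restored_c = np.clip(restored, 0.0, 1.0)
    report: dict[str, float] = {
        "sharpness_original": sharpness(original).scalar,
        "sharpness_degraded": sharpness(degraded).scalar,
        "sharpness_restored": sharpness(restored_c).scalar,
        "ssim_degraded": ssim(degraded, original).index,
        "ssim_restored": ssim(restored_c, original).index,
    }
    if model is not None:
        report["niqe_score_degraded"] = niqe_score(degraded, model)
        report["niqe_score_restored"] = niqe_score(restored_c, model)
    seg_deg, seg_rest = segment_pair(degraded, restored_c, canny_sensitivity)
    report["edge_pixels_degraded"] = float(seg_deg.edge_pixel_count)
    report["edge_pixels_restored"] = float(seg_rest.edge_pixel_count)
    return report


def write_report(report: dict[str, float], path: str | Path) -> None:
    """Write a flat report as JSON or CSV depending on the suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(report, indent=1))
    else:
        lines = ["metric,value"] + [f"{k},{v}" for k, v in report.items()]
        path.write_text("\n".join(lines) + "\n")
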