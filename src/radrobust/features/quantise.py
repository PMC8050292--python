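"""Grey-level quantisation (re-binning) of ROI intensities.

Texture matrices are built on discretised grey levels 1..Ng.  Two schemes are
supported: a fixed number of bins spread over the ROI's own intensity range
(the scheme preferred for cohorts whose intensity ranges vary little), and a
fixed bin width in HU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["QuantisationConfig", "quantise_roi", "quantise_values"]


@dataclass(frozen=True)
class QuantisationConfig:
    """How ROI intensities are mapped to discrete grey levels."""

    mode: str = "fixed_bin_count"
    n_bins: int = 40
    bin_width: float = 25.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_bin_count", "fixed_bin_width"):
            raise ValueError(f"unknown quantisation mode {self.mode!r}")
        if self.mode == "fixed_bin_count" and self.n_bins < 2:
            raise ValueError("fixed_bin_count requires n_bins >= 2")
        if self.mode == "fixed_bin_width" and self.bin_width <= 0:
            raise ValueError("fixed_bin_width requires bin_width > 0")


def quantise_values(values: np.ndarray, config: QuantisationConfig) -> tuple[np.ndarray, float, float]:
    """Discretise a 1D array of ROI intensities to grey levels 1..Ng.

    Returns ``(grey_levels, x_min, x_max)``.  In fixed-bin-count mode the
    levels are ``floor((x - x_min) / w) + 1`` with ``w = (x_max - x_min) / n``,
    the maximum clipped into the top bin; a constant ROI maps to a single
    level with a warning.  In fixed-bin-width mode the level is
    ``floor((x - x_min) / width) + 1``.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI cannot be quantised")
    x_min = float(x.min())
    x_max = float(x.max())
    if config.mode == "fixed_bin_count":
        if x_max == x_min:
            warnings.warn(
                "constant ROI: all voxels assigned grey level 1", RuntimeWarning, stacklevel=2
            )
            return np.ones(x.size, dtype=np.int64), x_min, x_max
        width = (x_max - x_min) / config.n_bins
        gl = np.floor((x - x_min) / width).astype(np.int64) + 1
        np.clip(gl, 1, config.n_bins, out=gl)
    else:
        gl = np.floor((x - x_min) / config.bin_width).astype(np.int64) + 1
    return gl, x_min, x_max


def quantise_roi(image, mask, config: QuantisationConfig) -> tuple[np.ndarray, float, float]:
    """Quantise the masked voxels of ``image``; outside-mask voxels are 0.

    Returns a grey-level volume (int array, 0 outside the ROI) together with
    the ROI intensity extrema used for the mapping.
    """
    m = np.asarray(mask.values, dtype=bool)
    if not m.any():
        raise ValueError("mask has no foreground voxels")
    if m.shape != image.values.shape:
        raise ValueError("image and mask grids differ")
    gl_flat, x_min, x_max = quantise_values(image.values[m], config)
    out = np.zeros(image.values.shape, dtype=np.int64)
    out[m] = gl_flat
    return out, x_min, x_max
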