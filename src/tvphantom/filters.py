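"""Conventional comparison filters: local-adaptive Wiener and median.

Both use replicate padding so the benchmark arms differ only by algorithm,
never by border policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .image import Image

_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class WindowSpec:
    """Odd-sized rectangular filter window (defaults 3x3)."""

    height: int = 3
    width: int = 3

    def __post_init__(self) -> None:
        for name, v in (("height", self.height), ("width", self.width)):
            if v < 1 or v % 2 == 0:
                raise ConfigurationError(f"window {name} must be odd and >= 1, got {v}")

    @property
    def size(self) -> tuple[int, int]:
        return (self.height, self.width)


def _check_window(img: Image, win: WindowSpec) -> None:
    if win.height > img.shape[0] or win.width > img.shape[1]:
        raise ConfigurationError(
            f"window {win.size} larger than image {img.shape}"
        )


def wiener_filter(img: Image, win: WindowSpec = WindowSpec(),
                  noise_variance: float | None = None) -> Image:
    """Per-pixel local-adaptive Wiener estimate.

    out = mu + max(var - v, 0) / max(var, floor) * (in - mu)

    where mu and var are the window mean and variance (replicate padding)
    and v is the noise variance, estimated as the mean of all local
    variances when not supplied. The gain lies in [0, 1], so each output
    pixel lies between the local mean and the input value.
    """
    _check_window(img, win)
    if noise_variance is not None and noise_variance < 0:
        raise ConfigurationError("noise_variance must be >= 0")
    v = img.values
    mu = ndimage.uniform_filter(v, size=win.size, mode="nearest")
    mu2 = ndimage.uniform_filter(v * v, size=win.size, mode="nearest")
    var = np.maximum(mu2 - mu * mu, 0.0)
    nv = float(var.mean()) if noise_variance is None else float(noise_variance)
    gain = np.maximum(var - nv, 0.0) / np.maximum(var, _VAR_FLOOR)
    out = mu + gain * (v - mu)
    return img.with_values(out, stage=f"wiener({win.height}x{win.width})")


def median_filter(img: Image, win: WindowSpec = WindowSpec()) -> Image:
    """Per-pixel window median with replicate padding.

    Even-count windows (never the default) take the lower median, via a rank
    filter at rank (n - 1) // 2.
    """
    _check_window(img, win)
    n = win.height * win.width
    out = ndimage.rank_filter(img.values, rank=(n - 1) // 2, size=win.size,
                              mode="nearest")
    return img.with_values(out, stage=f"median({win.height}x{win.width})")
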