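"""The 2-D grayscale image container used by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Image:
    """A 2-D grid of real intensities with a physical pixel pitch.

    Parameters
    ----------
    values : ndarray
        M x N array of finite real intensities (stored as float64).
    pixel_mm : float
        Physical pixel pitch in millimetres (isotropic).
    provenance : str
        Free-text tag recording which stages produced the image.
    """

    values: np.ndarray
    pixel_mm: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.values.shape}")
        if min(self.values.shape) < 2:
            raise ValueError(f"image must be at least 2x2, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        if self.pixel_mm <= 0:
            raise ValueError(f"pixel_mm must be positive, got {self.pixel_mm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, stage: str | None = None) -> "Image":
        """Return a new image with replaced pixel data and an appended stage tag."""
        prov = self.provenance if stage is None else _append_stage(self.provenance, stage)
        return Image(values=values, pixel_mm=self.pixel_mm, provenance=prov)

    def copy(self) -> "Image":
        return replace(self, values=self.values.copy())


def _append_stage(provenance: str, stage: str) -> str:
    return stage if not provenance else f"{provenance} | {stage}"
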