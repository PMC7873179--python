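"""Shared containers used by more than one analysis arm."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageSeries:
    """A 2-D cine image series with physical metadata.

    Attributes
    ----------
    data
        Array of shape ``(rows, cols, n_frames)``, intensity units.
    pixel_spacing_mm
        Isotropic in-plane pixel spacing. Image coordinates are in mm with
        the origin at the centre of pixel ``(0, 0)``: ``x = col * spacing``,
        ``y = row * spacing``.
    frame_interval_s
        Time between consecutive frames.
    """

    data: np.ndarray
    pixel_spacing_mm: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected (rows, cols, time) array, got ndim={self.data.ndim}")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape
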