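"""FLIM image container: per-pixel photon counts plus photon-weighted
lifetime sums, the native product of a time-resolved confocal scan."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = ["FlimImage"]


@dataclass
class FlimImage:
    """Raster of photon counts and photon-weighted lifetime sums.

    ``lifetime_weighted_sum[y, x]`` holds the sum of per-photon lifetimes
    (ns) recorded at that pixel, so the mean lifetime of any pixel set is
    ``sum(lifetime_weighted_sum) / sum(photon_counts)`` — pooling photons
    exactly.  Coordinate convention: 0-based, origin top-left, x = column,
    y = row, pixel centers on integer coordinates.
    """

    photon_counts: np.ndarray
    lifetime_weighted_sum: np.ndarray
    pixel_size_nm: float
    cell_id: str = ""

    def __post_init__(self):
        self.photon_counts = np.asarray(self.photon_counts)
        self.lifetime_weighted_sum = np.asarray(self.lifetime_weighted_sum, dtype=float)
        if self.photon_counts.shape != self.lifetime_weighted_sum.shape:
            raise InvalidParameterError("count and lifetime planes must match in shape")
        if self.photon_counts.ndim != 2:
            raise InvalidParameterError("FlimImage planes must be 2-D")
        if self.pixel_size_nm <= 0:
            raise InvalidParameterError("pixel_size_nm must be positive")
        if np.any(self.photon_counts < 0):
            raise InvalidParameterError("photon counts must be non-negative")
        if np.any((self.photon_counts == 0) & (self.lifetime_weighted_sum != 0)):
            raise InvalidParameterError(
                "lifetime_weighted_sum must be 0 wherever photon_counts is 0"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.photon_counts.shape

    def mean_lifetime_map(self) -> np.ndarray:
        """Per-pixel mean lifetime (ns); NaN where no photons."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.photon_counts > 0,
                self.lifetime_weighted_sum / np.maximum(self.photon_counts, 1),
                np.nan,
            )
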