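"""Ratiometric Fura-2 Ca2+ conversion and colocalization quantification.

The ratiometric conversion follows the classic two-wavelength calibration:
with R = F340/F380,

    [Ca2+] = Kd * beta * (R - Rmin) / (Rmax - R)

strictly increasing in R on [Rmin, Rmax) and equal to Kd at the
calibration midpoint where ``beta (R - Rmin)/(Rmax - R) = 1``.
Colocalization of two immunofluorescence channels is quantified as the
Pearson correlation of pixel intensities over an optional mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .sim_channels import Fura2Calibration

__all__ = ["Fura2Calibration", "ImagePair", "grynkiewicz",
           "pearson_colocalization"]

logger = logging.getLogger(__name__)


def grynkiewicz(r, calib: Fura2Calibration) -> np.ndarray:
    """Convert Fura-2 ratios to free Ca2+ (nM).

    Ratios at or above ``r_max`` are saturated: they are flagged, returned
    as NaN and must be excluded from downstream statistics.  Ratios below
    ``r_min`` (noise undershoot) are likewise flagged and returned as NaN.
    """
    r = np.asarray(r, dtype=float)
    saturated = r >= calib.r_max
    below = r < calib.r_min
    n_bad = int(saturated.sum() + below.sum())
    if n_bad:
        logger.warning("grynkiewicz: %d sample(s) outside [r_min, r_max) "
                       "flagged as NaN (%d saturated, %d below range)",
                       n_bad, int(saturated.sum()), int(below.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        ca = calib.kd * calib.beta * (r - calib.r_min) / (calib.r_max - r)
    ca = np.where(saturated | below, np.nan, ca)
    return ca


@dataclass
class ImagePair:
    """Two equal-shape intensity rasters with an optional boolean mask."""

    a: np.ndarray
    b: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape:
            raise ValueError("images must have equal shape")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.a.shape:
                raise ValueError("mask shape must match the images")


def pearson_colocalization(pair: ImagePair) -> float:
    """Pearson correlation of the two rasters over the mask, in [-1, 1].

    Invariant under affine rescaling of either channel's intensities, so
    detector gain and offset do not affect the coefficient.
    """
    if pair.mask is not None:
        x, y = pair.a[pair.mask], pair.b[pair.mask]
    else:
        x, y = pair.a.ravel(), pair.b.ravel()
    if x.size < 2:
        raise ValueError("need at least two masked pixels")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a raster; correlation undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(np.clip(r, -1.0, 1.0))
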