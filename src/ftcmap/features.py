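"""Phase x band feature extraction from realigned annual series.

Trees hold a greenness plateau through the middle of the growing season
while herbaceous vegetation rises and falls in a parabola-like arc. After
realignment the midpoint of every pixel's growing season sits at composite
23 (DOY 185-192), so the shoulders of the season fall at fixed calendar
positions: composite 17 (DOY 137-144) about one and a half months before
the midpoint and composite 29 (DOY 233-240) after it. Together with the
annual NDVI maximum and minimum these give four phases; reading NDVI, red
and SWIR2.1 at each yields the twelve predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phenology import RealignedSeries

#: fixed shoulder composites in realigned coordinates
C_GROW_LEFT = 17
C_GROW_RIGHT = 29

PHASE_NAMES = ("ndvi_max", "ndvi_min", "grow_left", "grow_right")
BAND_NAMES = ("ndvi", "red", "swir")
#: canonical feature order: phases (max, min, left, right) x bands (ndvi, red, swir)
FEATURE_NAMES = tuple(f"{p}.{b}" for p in PHASE_NAMES for b in BAND_NAMES)

__all__ = [
    "C_GROW_LEFT",
    "C_GROW_RIGHT",
    "FEATURE_NAMES",
    "PhaseSet",
    "locate_phases",
    "extract_features",
]


@dataclass(frozen=True)
class PhaseSet:
    """Composite indices of the four feature-extraction phases."""

    c_ndvimax: int
    c_ndvimin: int
    c_left: int = C_GROW_LEFT
    c_right: int = C_GROW_RIGHT

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.c_ndvimax, self.c_ndvimin, self.c_left, self.c_right)


def locate_phases(r: RealignedSeries) -> PhaseSet:
    """Locate the four phases on a gap-free realigned series.

    The NDVI maximum/minimum phases are the argmax/argmin of the smoothed
    realigned NDVI, ties breaking to the earliest composite; the shoulder
    phases are fixed at composites 17 and 29.
    """
    ndvi = r.series.ndvi
    if not np.isfinite(ndvi).all():
        raise ValueError("realigned NDVI must be gap-free")
    return PhaseSet(c_ndvimax=int(np.argmax(ndvi)), c_ndvimin=int(np.argmin(ndvi)))


def extract_features(r: RealignedSeries, p: PhaseSet | None = None) -> np.ndarray:
    """Read the 12-vector of NDVI/red/SWIR values at the four phase composites.

    Order follows :data:`FEATURE_NAMES`. Any non-finite value at a phase
    composite rejects the pixel.
    """
    if p is None:
        p = locate_phases(r)
    s = r.series
    out = np.empty(12, dtype=float)
    for i, c in enumerate(p.as_tuple()):
        out[3 * i : 3 * i + 3] = (s.ndvi[c], s.red[c], s.swir[c])
    if not np.isfinite(out).all():
        raise ValueError("fill value at a phase composite; pixel rejected")
    return out
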