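"""Preprocessing of annual 8-day composite series.

An annual series holds 46 eight-day composites of NDVI, red and SWIR2.1
reflectance (optionally daytime land-surface temperature) together with
per-composite QA flags. Composite ``c`` covers day-of-year ``8c+1`` to
``8c+8``; composite 45 absorbs the 2-day year remainder and leap days are
ignored.

This module turns flagged, gappy raw series into continuous gap-free ones:

* non-clear composites (cloud / snow / water / fill) are masked to NaN,
* NDVI is reconstructed by a periodic truncated-harmonic fit with iterative
  rejection of contaminated (anomalously dark) observations, pulling the
  curve toward the upper envelope of the clear-sky points,
* red / SWIR2.1 (and LST) gaps are filled by periodic linear interpolation,
* the 2x-coarser SWIR2.1 grid can be duplicated onto the finer target grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

N_COMPOSITES = 46
#: number of retained harmonics in the periodic NDVI smoother
N_HARMONICS = 16
#: observations more than this far below the fit are treated as contaminated (NDVI units)
REJECT_MARGIN = 0.05
#: minimum clear composites for a pixel to be usable at all
MIN_CLEAR_FOR_SMOOTHING = 8

__all__ = [
    "N_COMPOSITES",
    "QAFlag",
    "AnnualSeries",
    "MultiYearStack",
    "UnusablePixelError",
    "composite_start_doy",
    "compute_ndvi",
    "mask_series",
    "interpolate_gaps_circular",
    "fill_smooth",
    "preprocess_series",
    "upsample_coarse_band",
]


class QAFlag(IntEnum):
    """Per-composite quality flag."""

    CLEAR = 0
    CLOUD = 1
    SNOW = 2
    WATER = 3
    FILL = 4


class UnusablePixelError(ValueError):
    """Raised when a pixel has too few clear observations to reconstruct."""


def composite_start_doy(c: int | np.ndarray) -> int | np.ndarray:
    """Starting day-of-year of composite ``c`` (composite 0 starts on DOY 1)."""
    return 8 * np.asarray(c) + 1 if np.ndim(c) else 8 * int(c) + 1


def _as46(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (N_COMPOSITES,):
        raise ValueError(f"{name} must have shape ({N_COMPOSITES},), got {a.shape}")
    return a


@dataclass
class AnnualSeries:
    """One pixel-year of 8-day composites.

    All value arrays have length 46; missing values are NaN. ``lst`` (daytime
    land-surface temperature, kelvin) is optional.
    """

    ndvi: np.ndarray
    red: np.ndarray
    swir: np.ndarray
    qa: np.ndarray
    lst: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ndvi = _as46(self.ndvi, "ndvi")
        self.red = _as46(self.red, "red")
        self.swir = _as46(self.swir, "swir")
        qa = np.asarray(self.qa)
        if qa.shape != (N_COMPOSITES,):
            raise ValueError(f"qa must have shape ({N_COMPOSITES},)")
        self.qa = qa.astype(np.uint8)
        if self.lst is not None:
            self.lst = _as46(self.lst, "lst")

    @property
    def n_clear(self) -> int:
        return int(np.sum(self.qa == QAFlag.CLEAR))

    def bands(self) -> dict[str, np.ndarray]:
        out = {"ndvi": self.ndvi, "red": self.red, "swir": self.swir}
        if self.lst is not None:
            out["lst"] = self.lst
        return out


@dataclass
class MultiYearStack:
    """Ordered annual series for one pixel across years."""

    years: list[AnnualSeries]
    labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.years:
            raise ValueError("MultiYearStack needs at least one year")
        if not self.labels:
            self.labels = list(range(len(self.years)))
        if len(self.labels) != len(self.years):
            raise ValueError("labels and years length mismatch")


def compute_ndvi(red, nir):
    """(NIR - red) / (NIR + red), clipped to [-1, 1]; NaN where the sum is 0."""
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (nir - red) / np.where(denom == 0, 1.0, denom), np.nan)
    return np.clip(out, -1.0, 1.0) if np.ndim(out) else float(np.clip(out, -1.0, 1.0))


def mask_series(s: AnnualSeries) -> AnnualSeries:
    """Set every non-clear composite to NaN; clear composites pass through bit-exact."""
    bad = s.qa != QAFlag.CLEAR

    def m(a):
        if a is None:
            return None
        out = a.copy()
        out[bad] = np.nan
        return out

    return AnnualSeries(ndvi=m(s.ndvi), red=m(s.red), swir=m(s.swir), qa=s.qa.copy(), lst=m(s.lst))


def interpolate_gaps_circular(values: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Fill NaN/invalid entries by linear interpolation with periodic wrap."""
    values = _as46(values, "values")
    if valid is None:
        valid = np.isfinite(values)
    valid = np.asarray(valid, dtype=bool)
    if valid.all():
        return values.copy()
    if not valid.any():
        raise UnusablePixelError("no valid observations to interpolate from")
    idx = np.arange(N_COMPOSITES)
    vi = idx[valid]
    out = values.copy()
    # tile valid points one period to each side so interpolation wraps
    ex = np.concatenate([vi - N_COMPOSITES, vi, vi + N_COMPOSITES])
    ey = np.tile(values[vi], 3)
    out[~valid] = np.interp(idx[~valid], ex, ey)
    return out


def _lowpass(y: np.ndarray, n_harmonics: int) -> np.ndarray:
    spec = np.fft.rfft(y)
    spec[n_harmonics + 1 :] = 0.0
    return np.fft.irfft(spec, n=y.shape[0])


def fill_smooth(
    ndvi: np.ndarray,
    valid: np.ndarray | None = None,
    *,
    n_harmonics: int = N_HARMONICS,
    reject_margin: float = REJECT_MARGIN,
    max_iter: int = 10,
) -> np.ndarray:
    """Gap-fill and smooth one annual NDVI series toward its upper envelope.

    The series is fit with a periodic truncated-harmonic (low-pass Fourier)
    curve. Observations falling more than ``reject_margin`` *below* the fit
    are treated as contaminated (residual cloud or shadow darkens NDVI, it
    does not brighten it), removed, and the fit repeated until the rejected
    set stabilises or ``max_iter`` passes. The final curve is evaluated at
    all 46 composites.

    The operator is bitwise equivariant to circular rotation of its input
    (the series is anchored at its maximum before fitting, so rotate-then-
    smooth and smooth-then-rotate agree exactly) and is a projection on its
    own output (applying it twice changes nothing); downstream realignment
    invariance tests rely on both.

    Raises :class:`UnusablePixelError` with fewer than 8 valid observations.
    """
    ndvi = _as46(ndvi, "ndvi")
    if valid is None:
        valid = np.isfinite(ndvi)
    valid = np.asarray(valid, dtype=bool) & np.isfinite(ndvi)
    if valid.sum() < MIN_CLEAR_FOR_SMOOTHING:
        raise UnusablePixelError(
            f"only {int(valid.sum())} clear composites; need >= {MIN_CLEAR_FOR_SMOOTHING}"
        )
    # canonical anchor: earliest argmax among valid observations rotates with
    # the input, so the fit below sees the same byte sequence for any rotation
    anchor = int(np.argmax(np.where(valid, ndvi, -np.inf)))
    ndvi = np.roll(ndvi, -anchor)
    valid = np.roll(valid, -anchor)
    good = valid.copy()
    for _ in range(max_iter):
        fit = _lowpass(interpolate_gaps_circular(ndvi, good), n_harmonics)
        contaminated = valid & (fit - ndvi > reject_margin)
        new_good = valid & ~contaminated
        if new_good.sum() < MIN_CLEAR_FOR_SMOOTHING:
            break  # keep the previous rejection set rather than starve the fit
        if np.array_equal(new_good, good):
            good = new_good
            break
        good = new_good
    return np.roll(_lowpass(interpolate_gaps_circular(ndvi, good), n_harmonics), anchor)


def preprocess_series(raw: AnnualSeries) -> AnnualSeries:
    """Mask non-clear composites, smooth NDVI, and gap-fill the reflectance bands.

    Returns a gap-free series (QA preserved from the input). Red/SWIR (and
    LST when present) are filled by periodic linear interpolation only; the
    envelope smoother is applied to NDVI.
    """
    masked = mask_series(raw)
    ndvi = fill_smooth(masked.ndvi)
    red = interpolate_gaps_circular(masked.red)
    swir = interpolate_gaps_circular(masked.swir)
    lst = interpolate_gaps_circular(masked.lst) if masked.lst is not None else None
    return AnnualSeries(ndvi=ndvi, red=red, swir=swir, qa=raw.qa.copy(), lst=lst)


def upsample_coarse_band(coarse: np.ndarray, target_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Duplicate each 2x-coarser cell onto its 2x2 fine cells (nearest neighbour).

    ``target_shape`` may trim one row/column when the fine grid has odd size
    (coarse dims are ceil(target/2)).
    """
    coarse = np.asarray(coarse)
    if coarse.ndim != 2:
        raise ValueError("coarse grid must be 2-D")
    fine = np.repeat(np.repeat(coarse, 2, axis=0), 2, axis=1)
    if target_shape is not None:
        tr, tc = target_shape
        if not (tr <= fine.shape[0] <= tr + 1 and tc <= fine.shape[1] <= tc + 1):
            raise ValueError(
                f"coarse grid {coarse.shape} does not match target {target_shape} at 2x"
            )
        fine = fine[:tr, :tc]
    return fine
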