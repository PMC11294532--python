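"""Growing-season detection and phenological realignment.

Geographic differences in growing-season timing are removed by circularly
rotating each pixel's annual series so that the midpoint of its growing
season lands on the centre of the calendar year (composite 23, DOY 185-192).

The growing season is detected on a multi-year mean NDVI reference curve as
the circular run of composites whose NDVI exceeds half the annual amplitude
above the minimum. Pixels with amplitude below 0.2 are treated as evergreen
and their midpoint is the circular mean of the 18 greenest composites. When
several runs exceed the threshold, daytime land-surface temperature decides
the primary (warm-season) run; without LST the longest run wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import AnnualSeries, MultiYearStack, N_COMPOSITES, UnusablePixelError

#: amplitude below which a pixel is treated as evergreen (NDVI units)
EVERGREEN_AMPLITUDE = 0.2
#: amplitude below which the series is essentially flat and no shift is applied
FLAT_AMPLITUDE = 0.02
#: target composite for the growing-season midpoint (DOY 185-192)
CENTER_COMPOSITE = 23
#: number of greenest composites used for the evergreen midpoint
N_TOP_EVERGREEN = 18
#: maximum composites allowed to have no finite value across years
MAX_EMPTY_COMPOSITES = 10

__all__ = [
    "EVERGREEN_AMPLITUDE",
    "FLAT_AMPLITUDE",
    "CENTER_COMPOSITE",
    "ReferencePhenology",
    "GrowingSeason",
    "RealignedSeries",
    "reference_series",
    "detect_growing_season",
    "midpoint_evergreen",
    "circular_mean_composite",
    "realign",
]


@dataclass
class ReferencePhenology:
    """Multi-year mean NDVI seasonal curve with its amplitude and run threshold."""

    ref_ndvi: np.ndarray

    def __post_init__(self) -> None:
        self.ref_ndvi = np.asarray(self.ref_ndvi, dtype=float)
        if self.ref_ndvi.shape != (N_COMPOSITES,):
            raise ValueError("ref_ndvi must have 46 composites")

    @property
    def amplitude(self) -> float:
        return float(np.nanmax(self.ref_ndvi) - np.nanmin(self.ref_ndvi))

    @property
    def threshold(self) -> float:
        return float(np.nanmin(self.ref_ndvi) + self.amplitude / 2.0)


@dataclass
class GrowingSeason:
    """Detected growing season: circular runs above threshold and the chosen one.

    ``runs`` are (start, length) pairs on the 46-composite circle; evergreen
    pixels carry no runs and ``run_length`` 0.
    """

    runs: list[tuple[int, int]]
    primary_run: tuple[int, int] | None
    midpoint: int
    evergreen: bool

    @property
    def run_length(self) -> int:
        return 0 if self.primary_run is None else self.primary_run[1]


@dataclass
class RealignedSeries:
    """An annual series rotated so the growing-season midpoint sits at composite 23."""

    series: AnnualSeries
    shift: int  # signed composite offset applied, in -22..23
    center_composite: int = CENTER_COMPOSITE


def reference_series(stack: MultiYearStack | list[np.ndarray]) -> ReferencePhenology:
    """Per-composite mean NDVI over years, ignoring NaN.

    Composites with no finite value in any year stay NaN; more than
    ``MAX_EMPTY_COMPOSITES`` such composites make the pixel unusable.
    """
    if isinstance(stack, MultiYearStack):
        arrays = [y.ndvi for y in stack.years]
    else:
        arrays = [np.asarray(a, dtype=float) for a in stack]
    data = np.vstack(arrays)
    with np.errstate(invalid="ignore"):
        counts = np.isfinite(data).sum(axis=0)
        ref = np.where(counts > 0, np.nansum(np.where(np.isfinite(data), data, 0.0), axis=0), np.nan)
        ref = ref / np.where(counts > 0, counts, 1)
    n_empty = int((counts == 0).sum())
    if n_empty > MAX_EMPTY_COMPOSITES:
        raise UnusablePixelError(f"{n_empty} composites have no finite NDVI in any year")
    return ReferencePhenology(ref_ndvi=ref)


def _circular_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal circular runs of True as (start, length), ordered by start."""
    n = mask.size
    if mask.all():
        return [(0, n)]
    if not mask.any():
        return []
    # rotate so the sequence starts on a False, then runs cannot straddle the cut
    first_false = int(np.argmin(mask))
    rolled = np.roll(mask, -first_false)
    runs: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(rolled):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append(((start + first_false) % n, i - start))
            start = None
    if start is not None:
        runs.append(((start + first_false) % n, n - start))
    return sorted(runs)


def circular_mean_composite(indices: np.ndarray) -> float:
    """Circular mean of composite indices on the 46-composite year, in [0, 46)."""
    ang = 2.0 * np.pi * np.asarray(indices, dtype=float) / N_COMPOSITES
    mean_ang = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return float((mean_ang * N_COMPOSITES / (2.0 * np.pi)) % N_COMPOSITES)


def _round_composite(x: float) -> int:
    """Nearest composite index, half-way ties toward the smaller index."""
    x = x % N_COMPOSITES
    i = int(np.floor(x))
    frac = x - i
    if frac > 0.5 + 1e-9:
        i += 1
    elif abs(frac - 0.5) <= 1e-9:
        pass  # tie: keep smaller
    return i % N_COMPOSITES


def midpoint_evergreen(ref: ReferencePhenology) -> int:
    """Midpoint composite for evergreen pixels from the 18 greenest composites.

    Essentially-flat series (amplitude < 0.02) take the identity midpoint 23.
    Ties among NDVI values break toward the earlier composite.
    """
    if ref.amplitude < FLAT_AMPLITUDE:
        return CENTER_COMPOSITE
    ndvi = ref.ref_ndvi
    order = np.lexsort((np.arange(N_COMPOSITES), -ndvi))
    top = order[:N_TOP_EVERGREEN]
    return _round_composite(circular_mean_composite(top))


def detect_growing_season(
    ref: ReferencePhenology, lst: np.ndarray | None = None
) -> GrowingSeason:
    """Detect the primary growing season and its midpoint.

    Amplitude below 0.2 takes the evergreen branch. Otherwise the circular
    runs of ``ref_ndvi > threshold`` are found; with several runs the one
    with the highest mean daytime LST wins (longest run, earliest start, if
    LST is unavailable). The midpoint is the central composite of the
    primary run, ``start + (length-1)//2`` on the circle.
    """
    if not np.isfinite(ref.ref_ndvi).all():
        raise UnusablePixelError("reference NDVI contains non-finite composites")
    if ref.amplitude < EVERGREEN_AMPLITUDE:
        return GrowingSeason(runs=[], primary_run=None,
                             midpoint=midpoint_evergreen(ref), evergreen=True)
    mask = ref.ref_ndvi > ref.threshold
    runs = _circular_runs(mask)
    assert runs, "amplitude >= 0.2 implies the maximum exceeds the threshold"
    if len(runs) == 1 or lst is None:
        primary = max(runs, key=lambda r: (r[1], -r[0]))
    else:
        lst = np.asarray(lst, dtype=float)

        def run_mean_lst(run: tuple[int, int]) -> float:
            start, length = run
            idx = (start + np.arange(length)) % N_COMPOSITES
            return float(np.nanmean(lst[idx]))

        primary = max(runs, key=lambda r: (run_mean_lst(r), r[1], -r[0]))
    start, length = primary
    midpoint = (start + (length - 1) // 2) % N_COMPOSITES
    return GrowingSeason(runs=runs, primary_run=primary, midpoint=midpoint, evergreen=False)


def realign(s: AnnualSeries, midpoint: int) -> RealignedSeries:
    """Rotate every band so the composite at ``midpoint`` lands on composite 23.

    The rotation is a pure circular permutation of whole composites: value
    multisets are preserved exactly and the shift is reported as a signed
    offset in -22..23.
    """
    if not 0 <= midpoint < N_COMPOSITES:
        raise ValueError("midpoint must be a composite index in 0..45")
    shift = (CENTER_COMPOSITE - midpoint) % N_COMPOSITES
    signed = shift - N_COMPOSITES if shift > CENTER_COMPOSITE else shift

    def rot(a):
        return None if a is None else np.roll(a, shift)

    rotated = AnnualSeries(
        ndvi=rot(s.ndvi), red=rot(s.red), swir=rot(s.swir),
        qa=np.roll(s.qa, shift), lst=rot(s.lst),
    )
    return RealignedSeries(series=rotated, shift=signed)
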