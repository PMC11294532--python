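"""Fractional training references from categorical forest maps.

Categorical forest/non-forest rasters at finer resolution are aggregated to
fractional tree cover on the working grid (percentage of tree-labelled
subcells per cell), several products are combined into a per-pixel mean
(TC_RefMean) and mean absolute deviation (MAE_Ref), unreliable areas are
excluded, and a class-balanced training table is assembled by down-sampling
the overwhelming 0% and 100% cover bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

#: per-pixel product disagreement above which training samples are excluded (%)
MAE_REF_MAX = 10.0
#: minimum clear-sky composites per year for a training pixel
MIN_CLEAR_OBS = 25
#: minimum growing-season length for seasonal training pixels (composites, ~3 months)
MIN_SEASON_COMPOSITES = 12

#: land-cover codes excluded from training and mapping
LC_WATER = 1
LC_SNOW_ICE = 2
LC_BARREN = 3
LC_VEGETATED = 0
EXCLUDED_LANDCOVER = frozenset({LC_WATER, LC_SNOW_ICE, LC_BARREN})

__all__ = [
    "MAE_REF_MAX",
    "MIN_CLEAR_OBS",
    "MIN_SEASON_COMPOSITES",
    "ReferenceCoverSet",
    "TrainingSet",
    "aggregate_categorical",
    "combine_products",
    "apply_exclusions",
    "balance_samples",
]


@dataclass
class ReferenceCoverSet:
    """Combined fractional reference: per-product fractions, their mean and spread."""

    product_fractions: list[np.ndarray]
    tc_ref_mean: np.ndarray
    mae_ref: np.ndarray
    valid_mask: np.ndarray


@dataclass
class TrainingSet:
    """Balanced training table plus its per-bin histogram and balancing seed."""

    table: pd.DataFrame
    bin_counts: np.ndarray  # 101 integer tree-cover bins
    seed: int

    def __len__(self) -> int:
        return len(self.table)


def aggregate_categorical(binary: np.ndarray, factor: int) -> np.ndarray:
    """Percentage of tree-labelled subcells per coarse cell.

    ``binary`` holds 1 (tree), 0 (non-tree) or NaN (invalid subcell); cells
    where fewer than half the subcells are valid become NaN.
    """
    binary = np.asarray(binary, dtype=float)
    if binary.ndim != 2:
        raise ValueError("binary map must be 2-D")
    if binary.shape[0] % factor or binary.shape[1] % factor:
        raise ValueError(
            f"map shape {binary.shape} is not a multiple of factor {factor}"
        )
    rows, cols = binary.shape[0] // factor, binary.shape[1] // factor
    blocks = binary.reshape(rows, factor, cols, factor)
    valid = np.isfinite(blocks)
    n_valid = valid.sum(axis=(1, 3))
    n_tree = np.nansum(blocks, axis=(1, 3))
    with np.errstate(invalid="ignore"):
        frac = 100.0 * n_tree / np.where(n_valid > 0, n_valid, 1)
    frac[n_valid < 0.5 * factor * factor] = np.nan
    return frac


def combine_products(fraction_grids: list[np.ndarray]) -> ReferenceCoverSet:
    """Per-pixel mean (TC_RefMean) and mean absolute deviation (MAE_Ref) of products.

    A pixel is valid only where every product has a finite fraction.
    """
    if len(fraction_grids) < 2:
        raise ValueError("need at least two products to combine")
    stack = np.stack([np.asarray(g, dtype=float) for g in fraction_grids])
    valid = np.isfinite(stack).all(axis=0)
    with np.errstate(invalid="ignore"):
        mean = stack.mean(axis=0)
        mae = np.abs(stack - mean).mean(axis=0)
    mean = np.where(valid, mean, np.nan)
    mae = np.where(valid, mae, np.nan)
    return ReferenceCoverSet(
        product_fractions=list(stack), tc_ref_mean=mean, mae_ref=mae, valid_mask=valid
    )


def apply_exclusions(
    ref: ReferenceCoverSet,
    clear_counts: np.ndarray,
    run_length: np.ndarray,
    evergreen: np.ndarray,
    landcover: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of pixels reliable enough for training.

    A pixel is excluded when the products disagree (MAE_Ref strictly above
    10%), when fewer than 25 clear-sky composites were observed, when a
    seasonal (non-evergreen) pixel's growing season is shorter than 12
    composites (~3 months), or when the land cover is water, permanent
    snow/ice or barren. Evergreen pixels are exempt from the season-length
    rule (they have no run).
    """
    mask = ref.valid_mask.copy()
    with np.errstate(invalid="ignore"):
        mask &= ~(ref.mae_ref > MAE_REF_MAX)
        mask &= np.asarray(clear_counts) >= MIN_CLEAR_OBS
        seasonal_ok = np.asarray(evergreen, dtype=bool) | (
            np.asarray(run_length) >= MIN_SEASON_COMPOSITES
        )
        mask &= seasonal_ok
    if landcover is not None:
        mask &= ~np.isin(np.asarray(landcover), list(EXCLUDED_LANDCOVER))
    return mask


def _target_bin(targets: np.ndarray) -> np.ndarray:
    """Integer tree-cover bin, round half up, clipped to 0..100."""
    return np.clip(np.floor(np.asarray(targets, dtype=float) + 0.5).astype(int), 0, 100)


def balance_samples(
    features: np.ndarray,
    targets: np.ndarray,
    pixel_ids: np.ndarray | None = None,
    cap0: int = 1000,
    cap100: int = 1000,
    seed: int = 0,
) -> TrainingSet:
    """Down-sample the 0% and 100% cover bins to their caps; keep all other bins.

    Selection within a capped bin is uniform at random under ``seed``; rows
    themselves (features, target, id) are never altered, only membership.
    """
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if cap0 < 0 or cap100 < 0:
        raise ValueError("caps must be >= 0")
    if features.shape[0] != targets.shape[0]:
        raise ValueError("features and targets row counts differ")
    if pixel_ids is None:
        pixel_ids = np.arange(features.shape[0])
    pixel_ids = np.asarray(pixel_ids)

    bins = _target_bin(targets)
    rng = np.random.default_rng(seed)
    keep = np.ones(features.shape[0], dtype=bool)
    for b, cap in ((0, cap0), (100, cap100)):
        idx = np.flatnonzero(bins == b)
        if idx.size > cap:
            drop = rng.choice(idx, size=idx.size - cap, replace=False)
            keep[drop] = False

    table = pd.DataFrame(features[keep], columns=list(FEATURE_NAMES))
    table["target"] = targets[keep]
    table["pixel_id"] = pixel_ids[keep]
    bin_counts = np.bincount(bins[keep], minlength=101)
    return TrainingSet(table=table.reset_index(drop=True), bin_counts=bin_counts, seed=seed)
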