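"""End-to-end orchestration: scene stacks to feature tables to cover maps.

Per pixel: mask flagged composites, reconstruct the NDVI annual curve,
detect the growing season on the (multi-year mean) reference curve, realign
the year so the season midpoint sits at composite 23, and read the twelve
phase x band features. Scene-level helpers then assemble training tables
against fractional references and map tree cover with a trained network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import features as feat
from . import model as mdl
from . import phenology as phen
from . import preprocess as pre
from . import refdata
from .simscene import Scene, SceneTruth, SimConfig, simulate_products

__all__ = ["SceneFeatures", "process_scene", "build_reference", "predict_scene"]


@dataclass
class SceneFeatures:
    """Per-pixel pipeline outputs for one scene-year."""

    features: np.ndarray  # (rows, cols, 12), NaN where invalid
    valid: np.ndarray  # pixels that survived preprocessing
    clear_counts: np.ndarray
    run_length: np.ndarray
    evergreen: np.ndarray
    midpoint: np.ndarray
    shift: np.ndarray  # signed realignment shift actually applied
    max_ndvi: np.ndarray  # annual maximum of the smoothed NDVI

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape

    def table(self) -> np.ndarray:
        """Features flattened to (rows*cols, 12)."""
        return self.features.reshape(-1, 12)


def process_pixel(series: pre.AnnualSeries) -> tuple[np.ndarray, dict]:
    """Run one pixel-year through preprocessing, realignment and extraction."""
    clean = pre.preprocess_series(series)
    ref = phen.reference_series([clean.ndvi])
    season = phen.detect_growing_season(ref, lst=clean.lst)
    realigned = phen.realign(clean, season.midpoint)
    fv = feat.extract_features(realigned)
    meta = {
        "clear": series.n_clear,
        "run_length": season.run_length,
        "evergreen": season.evergreen,
        "midpoint": season.midpoint,
        "shift": realigned.shift,
        "max_ndvi": float(np.max(clean.ndvi)),
    }
    return fv, meta


def process_scene(scene: Scene) -> SceneFeatures:
    """Per-pixel pipeline over a whole scene; unusable pixels are flagged invalid."""
    rows, cols = scene.shape
    out = SceneFeatures(
        features=np.full((rows, cols, 12), np.nan),
        valid=np.zeros((rows, cols), dtype=bool),
        clear_counts=np.zeros((rows, cols), dtype=int),
        run_length=np.zeros((rows, cols), dtype=int),
        evergreen=np.zeros((rows, cols), dtype=bool),
        midpoint=np.full((rows, cols), -1, dtype=int),
        shift=np.zeros((rows, cols), dtype=int),
        max_ndvi=np.full((rows, cols), np.nan),
    )
    for i in range(rows):
        for j in range(cols):
            series = scene.pixel(i, j)
            out.clear_counts[i, j] = series.n_clear
            try:
                fv, meta = process_pixel(series)
            except (pre.UnusablePixelError, ValueError):
                continue
            out.features[i, j] = fv
            out.valid[i, j] = True
            out.run_length[i, j] = meta["run_length"]
            out.evergreen[i, j] = meta["evergreen"]
            out.midpoint[i, j] = meta["midpoint"]
            out.shift[i, j] = meta["shift"]
            out.max_ndvi[i, j] = meta["max_ndvi"]
    return out


def build_reference(truth: SceneTruth, cfg: SimConfig) -> refdata.ReferenceCoverSet:
    """Simulate the four categorical products and combine them into references."""
    products = simulate_products(truth, cfg)
    grids = [refdata.aggregate_categorical(p.astype(float), cfg.subgrid_factor) for p in products]
    return refdata.combine_products(grids)


def predict_scene(model: mdl.TrainedModel, sf: SceneFeatures) -> np.ndarray:
    """Apply a trained network to a processed scene, with the NDVI post-mask."""
    rows, cols = sf.shape
    cover = mdl.predict(model, sf.table()).reshape(rows, cols)
    return mdl.postprocess(cover, sf.max_ndvi)
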