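"""Synthetic MODIS-like scenes with known fractional tree cover truth.

A two-endmember mixture model drives the simulation: a tree endmember whose
NDVI holds a sustained plateau through the growing season (steep logistic
green-up and senescence) and a herbaceous endmember whose shallow logistics
produce a downward-facing parabola-like arc. Reflectance (red, NIR, SWIR2.1)
mixes linearly with the tree area fraction; NDVI is computed from the mixed
red/NIR, never mixed directly. Each pixel may be circularly shifted by whole
composites to emulate geographic phenology differences, perturbed by
Gaussian reflectance noise, and masked by i.i.d. per-composite cloud.

Pseudo high-resolution categorical tree/non-tree products are generated by
quota labelling of subcells (so zero-error aggregation recovers the truth
exactly) followed by per-product omission/commission flips; one product
additionally suppresses tree labels below a "tall dense" cover threshold,
mimicking products that only map significant clusters of tall vegetation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import AnnualSeries, N_COMPOSITES, QAFlag, compute_ndvi

__all__ = [
    "EndmemberSpec",
    "SceneTruth",
    "SimConfig",
    "Scene",
    "default_tree_spec",
    "default_herb_spec",
    "endmember_curves",
    "endmember_nir",
    "simulate_pixel",
    "simulate_scene",
    "simulate_products",
    "random_scene_truth",
]


@dataclass(frozen=True)
class EndmemberSpec:
    """Spectral-temporal signature of a pure cover type.

    NDVI follows a double logistic between ``vmin`` and ``vmax`` with
    green-up/senescence inflection composites and per-composite steepness
    rates; red and SWIR2.1 reflectance decrease affinely from their dormancy
    values (``*_base``) to their peak-season values (``*_min``) as NDVI rises.
    """

    vmin: float
    vmax: float
    green_up: float
    senescence: float
    steepness_up: float
    steepness_down: float
    red_base: float
    red_min: float
    swir_base: float
    swir_min: float

    def __post_init__(self) -> None:
        if self.vmax < self.vmin:
            raise ValueError("vmax must be >= vmin")
        for name in ("red_base", "red_min", "swir_base", "swir_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.red_min > self.red_base or self.swir_min > self.swir_base:
            raise ValueError("peak-season reflectance must not exceed dormancy reflectance")
        if self.green_up % N_COMPOSITES >= self.senescence % N_COMPOSITES:
            raise ValueError("green_up must precede senescence within the year")


def default_tree_spec() -> EndmemberSpec:
    """Deciduous-forest-like endmember: fast green-up, sustained NDVI plateau."""
    return EndmemberSpec(
        vmin=0.25, vmax=0.85, green_up=12.0, senescence=34.0,
        steepness_up=2.0, steepness_down=2.0,
        red_base=0.12, red_min=0.03, swir_base=0.25, swir_min=0.10,
    )


def default_herb_spec() -> EndmemberSpec:
    """Grass/cropland-like endmember: slow rise and fall, single rounded peak."""
    return EndmemberSpec(
        vmin=0.15, vmax=0.75, green_up=16.0, senescence=30.0,
        steepness_up=0.3, steepness_down=0.3,
        red_base=0.15, red_min=0.06, swir_base=0.30, swir_min=0.15,
    )


def endmember_curves(spec: EndmemberSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """46-composite NDVI, red and SWIR2.1 curves for one endmember.

    A degenerate amplitude (vmin == vmax) yields constant curves at the
    dormancy values.
    """
    c = np.arange(N_COMPOSITES, dtype=float)
    logistic = 1.0 / (1.0 + np.exp(-spec.steepness_up * (c - spec.green_up))) - 1.0 / (
        1.0 + np.exp(-spec.steepness_down * (c - spec.senescence))
    )
    ndvi = spec.vmin + (spec.vmax - spec.vmin) * logistic
    if spec.vmax > spec.vmin:
        g = (ndvi - spec.vmin) / (spec.vmax - spec.vmin)
    else:
        g = np.zeros(N_COMPOSITES)
    red = spec.red_base + (spec.red_min - spec.red_base) * g
    swir = spec.swir_base + (spec.swir_min - spec.swir_base) * g
    return ndvi, red, swir


def endmember_nir(ndvi: np.ndarray, red: np.ndarray) -> np.ndarray:
    """NIR reflectance consistent with a given NDVI and red curve."""
    return red * (1.0 + ndvi) / (1.0 - ndvi)


@dataclass
class SceneTruth:
    """True tree-cover fractions (%) and per-pixel phenology shifts for a scene."""

    fraction: np.ndarray
    pheno_shift: np.ndarray
    pixel_size: float = 231.65635826
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.fraction = np.asarray(self.fraction, dtype=float)
        self.pheno_shift = np.asarray(self.pheno_shift, dtype=int)
        if self.fraction.shape != self.pheno_shift.shape:
            raise ValueError("fraction and pheno_shift grids must be conformable")
        if np.any((self.fraction < 0) | (self.fraction > 100)):
            raise ValueError("fraction must lie in [0, 100]")
        if np.any(np.abs(self.pheno_shift) > 45):
            raise ValueError("pheno_shift must lie in -45..45")

    @property
    def shape(self) -> tuple[int, int]:
        return self.fraction.shape


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions.

    ``product_error`` holds (omission, commission) rates for each of the four
    pseudo products; the last product also suppresses tree labels wherever the
    true cover is below ``tall_dense_threshold`` (%), emulating maps restricted
    to significant clusters of tall dense vegetation.
    """

    noise_sd: float = 0.01
    cloud_prob: float = 0.1
    seed: int = 0
    subgrid_factor: int = 10
    product_error: tuple[tuple[float, float], ...] = (
        (0.05, 0.05),
        (0.08, 0.04),
        (0.10, 0.05),
        (0.02, 0.01),
    )
    tall_dense_threshold: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cloud_prob <= 1.0:
            raise ValueError("cloud_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.subgrid_factor < 1:
            raise ValueError("subgrid_factor must be >= 1")
        for om, com in self.product_error:
            if not (0.0 <= om <= 1.0 and 0.0 <= com <= 1.0):
                raise ValueError("product error rates must be in [0, 1]")

    @classmethod
    def zero_error(cls, seed: int = 0, subgrid_factor: int = 10) -> "SimConfig":
        """Noise-free, cloud-free, error-free conditions (exact-closure preset)."""
        return cls(
            noise_sd=0.0, cloud_prob=0.0, seed=seed, subgrid_factor=subgrid_factor,
            product_error=((0.0, 0.0),) * 4, tall_dense_threshold=0.0,
        )


@dataclass
class Scene:
    """Simulated stack: per-band arrays of shape (46, rows, cols) plus retained truth."""

    ndvi: np.ndarray
    red: np.ndarray
    swir: np.ndarray
    lst: np.ndarray
    qa: np.ndarray
    truth: SceneTruth

    @property
    def shape(self) -> tuple[int, int]:
        return self.truth.shape

    def pixel(self, i: int, j: int) -> AnnualSeries:
        return AnnualSeries(
            ndvi=self.ndvi[:, i, j], red=self.red[:, i, j],
            swir=self.swir[:, i, j], qa=self.qa[:, i, j], lst=self.lst[:, i, j],
        )


def _lst_curve() -> np.ndarray:
    """Synthetic daytime LST (K) tracking the seasonal cycle, 270-300 K."""
    c = np.arange(N_COMPOSITES, dtype=float)
    return 270.0 + 30.0 * 0.5 * (1.0 - np.cos(2.0 * np.pi * (c - 0.5) / N_COMPOSITES))


def _mixed_reflectance(
    fraction: np.ndarray, tree: EndmemberSpec, herb: EndmemberSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear area-weighted reflectance mix; broadcasts fraction over composites."""
    w = np.asarray(fraction, dtype=float) / 100.0
    t_ndvi, t_red, t_swir = endmember_curves(tree)
    h_ndvi, h_red, h_swir = endmember_curves(herb)
    t_nir = endmember_nir(t_ndvi, t_red)
    h_nir = endmember_nir(h_ndvi, h_red)
    shape = (N_COMPOSITES,) + (1,) * np.ndim(w)
    mix = lambda a, b: a.reshape(shape) * w + b.reshape(shape) * (1.0 - w)
    return mix(t_red, h_red), mix(t_nir, h_nir), mix(t_swir, h_swir)


def simulate_pixel(
    fraction: float,
    shift: int,
    tree: EndmemberSpec | None = None,
    herb: EndmemberSpec | None = None,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> AnnualSeries:
    """Simulate one pixel-year at the given tree fraction and phenology shift."""
    if not 0.0 <= fraction <= 100.0:
        raise ValueError("fraction must be in [0, 100]")
    tree = tree or default_tree_spec()
    herb = herb or default_herb_spec()
    cfg = cfg or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    red, nir, swir = _mixed_reflectance(np.float64(fraction), tree, herb)
    red, nir, swir = (np.roll(a, int(shift)) for a in (red, nir, swir))
    lst = np.roll(_lst_curve(), int(shift))
    if cfg.noise_sd > 0:
        red = np.clip(red + rng.normal(0.0, cfg.noise_sd, N_COMPOSITES), 0.0, 1.0)
        nir = np.clip(nir + rng.normal(0.0, cfg.noise_sd, N_COMPOSITES), 0.0, 1.0)
        swir = np.clip(swir + rng.normal(0.0, cfg.noise_sd, N_COMPOSITES), 0.0, 1.0)
    ndvi = compute_ndvi(red, nir)
    qa = np.where(
        rng.random(N_COMPOSITES) < cfg.cloud_prob, QAFlag.CLOUD, QAFlag.CLEAR
    ).astype(np.uint8)
    return AnnualSeries(ndvi=ndvi, red=red, swir=swir, qa=qa, lst=lst)


def simulate_scene(
    truth: SceneTruth,
    tree: EndmemberSpec | None = None,
    herb: EndmemberSpec | None = None,
    cfg: SimConfig | None = None,
) -> Scene:
    """Simulate a full scene (vectorised over pixels); deterministic under seed."""
    tree = tree or default_tree_spec()
    herb = herb or default_herb_spec()
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    rows, cols = truth.shape

    red, nir, swir = _mixed_reflectance(truth.fraction, tree, herb)
    lst = np.broadcast_to(_lst_curve().reshape(-1, 1, 1), red.shape).copy()
    # per-pixel circular rotation by the phenology shift
    idx = (np.arange(N_COMPOSITES).reshape(-1, 1, 1) - truth.pheno_shift[None, :, :]) % N_COMPOSITES
    take = lambda a: np.take_along_axis(a, idx, axis=0)
    red, nir, swir, lst = take(red), take(nir), take(swir), take(lst)
    if cfg.noise_sd > 0:
        shape = red.shape
        red = np.clip(red + rng.normal(0.0, cfg.noise_sd, shape), 0.0, 1.0)
        nir = np.clip(nir + rng.normal(0.0, cfg.noise_sd, shape), 0.0, 1.0)
        swir = np.clip(swir + rng.normal(0.0, cfg.noise_sd, shape), 0.0, 1.0)
    ndvi = compute_ndvi(red, nir)
    qa = np.where(
        rng.random(red.shape) < cfg.cloud_prob, QAFlag.CLOUD, QAFlag.CLEAR
    ).astype(np.uint8)
    return Scene(ndvi=ndvi, red=red, swir=swir, lst=lst, qa=qa, truth=truth)


def simulate_products(truth: SceneTruth, cfg: SimConfig | None = None) -> list[np.ndarray]:
    """Four pseudo high-resolution binary tree/non-tree rasters.

    Each 250 m cell is split into ``subgrid_factor``^2 subcells and exactly
    ``round(fraction x subcells / 100)`` of them are labelled tree at
    seeded-random positions (quota labelling), so aggregation at zero error
    recovers the truth. Omission/commission flips then perturb each product;
    the last product drops tree labels below the tall-dense threshold.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    f = cfg.subgrid_factor
    rows, cols = truth.shape
    n_sub = f * f
    quota = np.floor(truth.fraction * n_sub / 100.0 + 0.5).astype(int)

    products: list[np.ndarray] = []
    n_products = len(cfg.product_error)
    for p, (om, com) in enumerate(cfg.product_error):
        # independent subcell arrangement per product: rank random draws per cell
        ranks = np.argsort(rng.random((rows * cols, n_sub)), axis=1).argsort(axis=1)
        labels = (ranks < quota.reshape(-1, 1)).astype(np.uint8)
        if om > 0 or com > 0:
            u = rng.random((rows * cols, n_sub))
            flip = np.where(labels == 1, u < om, u < com)
            labels = np.where(flip, 1 - labels, labels).astype(np.uint8)
        if p == n_products - 1 and cfg.tall_dense_threshold > 0:
            sparse = (truth.fraction < cfg.tall_dense_threshold).reshape(-1, 1)
            labels = np.where(sparse, 0, labels).astype(np.uint8)
        grid = (
            labels.reshape(rows, cols, f, f).transpose(0, 2, 1, 3).reshape(rows * f, cols * f)
        )
        products.append(grid)
    return products


def random_scene_truth(
    rows: int,
    cols: int,
    seed: int = 0,
    max_shift: int = 20,
    pixel_size: float = 231.65635826,
) -> SceneTruth:
    """Uniform-random tree fractions and integer phenology shifts."""
    rng = np.random.default_rng(seed)
    fraction = rng.uniform(0.0, 100.0, (rows, cols))
    shift = rng.integers(-max_shift, max_shift + 1, (rows, cols))
    return SceneTruth(fraction=fraction, pheno_shift=shift, pixel_size=pixel_size)
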