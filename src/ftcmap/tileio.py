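"""Raster tile and scene I/O in the dataset's naming and format conventions.

Tree-cover tiles are single-band unsigned 8-bit GeoTIFFs (values 0-100 %,
nodata 255, band "TreeCover") on a 4800 x 4800 sinusoidal grid, named
``GLOBMAPFTC.AYYYY001.hHHvVV.V01.tif`` with two-digit horizontal (0-35) and
vertical (0-17) tile indices. Synthetic scenes are written as one
multi-band GeoTIFF per variable (46 bands = 46 composites).

Georeferencing is carried by the standard GeoTIFF ModelPixelScale and
ModelTiepoint tags plus a JSON image description; the sinusoidal projection
is recorded as metadata (no reprojection is performed here).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np
import tifffile

__all__ = [
    "TileSpec",
    "tile_name",
    "parse_tile_name",
    "write_tile",
    "read_tile",
    "write_scene",
    "read_scene",
]

NODATA = 255
TILE_ROWS = 4800
TILE_COLS = 4800
H_MAX = 35
V_MAX = 17
_NAME_RE = re.compile(r"^GLOBMAPFTC\.A(\d{4})001\.h(\d{2})v(\d{2})\.V01\.tif$")

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class TileSpec:
    """Metadata of one tree-cover tile."""

    year: int
    h: int
    v: int
    rows: int = TILE_ROWS
    cols: int = TILE_COLS
    pixel_size: float = 231.65635826
    origin: tuple[float, float] = (0.0, 0.0)
    projection: str = "sinusoidal"
    nodata: int = NODATA

    def __post_init__(self) -> None:
        _check_indices(self.h, self.v)


def _check_indices(h: int, v: int) -> None:
    if not (0 <= h <= H_MAX and 0 <= v <= V_MAX):
        raise ValueError(f"tile indices out of range: h={h} (0..{H_MAX}), v={v} (0..{V_MAX})")


def tile_name(year: int, h: int, v: int) -> str:
    """Dataset file name for (year, h, v), zero-padded tile indices."""
    _check_indices(h, v)
    return f"GLOBMAPFTC.A{int(year):04d}001.h{h:02d}v{v:02d}.V01.tif"


def parse_tile_name(name: str) -> tuple[int, int, int]:
    """Inverse of :func:`tile_name`: (year, h, v)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"not a valid tile name: {name!r}")
    year, h, v = (int(g) for g in m.groups())
    _check_indices(h, v)
    return year, h, v


def _geo_tags(pixel_size: float, origin: tuple[float, float], nodata: int | None):
    ox, oy = origin
    tags = [
        (_TAG_PIXEL_SCALE, "d", 3, (pixel_size, pixel_size, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0), True),
    ]
    if nodata is not None:
        s = str(nodata).encode() + b"\x00"
        tags.append((_TAG_GDAL_NODATA, "s", len(s), s, True))
    return tags


def write_tile(grid: np.ndarray, spec: TileSpec, path) -> None:
    """Write one tile as uint8 GeoTIFF; NaN becomes nodata (255).

    Values must lie in 0..100 or equal the nodata code.
    """
    grid = np.asarray(grid)
    if grid.shape != (spec.rows, spec.cols):
        raise ValueError(f"grid shape {grid.shape} != tile shape {(spec.rows, spec.cols)}")
    data = grid.astype(float)
    data = np.where(np.isfinite(data), data, spec.nodata)
    bad = (data != spec.nodata) & ((data < 0) | (data > 100))
    if bad.any():
        raise ValueError("tile values must lie in [0, 100] or be nodata")
    data = np.round(data).astype(np.uint8)
    desc = json.dumps(
        {
            "layer": "TreeCover",
            "units": "percent",
            "year": spec.year,
            "h": spec.h,
            "v": spec.v,
            "projection": spec.projection,
            "nodata": spec.nodata,
        }
    )
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        description=desc,
        extratags=_geo_tags(spec.pixel_size, spec.origin, spec.nodata),
    )


def read_tile(path) -> tuple[np.ndarray, TileSpec]:
    """Read a tile written by :func:`write_tile`; bit-exact round trip."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        grid = page.asarray()
        desc = {}
        if page.description:
            try:
                desc = json.loads(page.description)
            except json.JSONDecodeError as exc:
                raise ValueError(f"malformed tile description in {path}") from exc
        scale = page.tags.get(_TAG_PIXEL_SCALE)
        tie = page.tags.get(_TAG_TIEPOINT)
        pixel_size = float(scale.value[0]) if scale is not None else 231.65635826
        origin = (float(tie.value[3]), float(tie.value[4])) if tie is not None else (0.0, 0.0)
    spec = TileSpec(
        year=int(desc.get("year", 0)),
        h=int(desc.get("h", 0)),
        v=int(desc.get("v", 0)),
        rows=grid.shape[0],
        cols=grid.shape[1],
        pixel_size=pixel_size,
        origin=origin,
        projection=desc.get("projection", "sinusoidal"),
        nodata=int(desc.get("nodata", NODATA)),
    )
    return grid, spec


def write_scene(scene, out_dir) -> None:
    """Write a simulated scene: one multi-band GeoTIFF per variable plus truth."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geo = _geo_tags(scene.truth.pixel_size, scene.truth.origin, None)
    for name in ("ndvi", "red", "swir", "lst"):
        tifffile.imwrite(
            out / f"{name}.tif",
            getattr(scene, name).astype(np.float32),
            photometric="minisblack",
            description=json.dumps({"variable": name, "bands": "46 eight-day composites"}),
            extratags=geo,
        )
    tifffile.imwrite(out / "qa.tif", scene.qa.astype(np.uint8), photometric="minisblack")
    tifffile.imwrite(
        out / "truth_fraction.tif",
        scene.truth.fraction.astype(np.float32),
        photometric="minisblack",
        extratags=geo,
    )
    tifffile.imwrite(
        out / "truth_shift.tif",
        scene.truth.pheno_shift.astype(np.int16),
        photometric="minisblack",
    )


def read_scene(scene_dir):
    """Read a scene directory written by :func:`write_scene`."""
    from pathlib import Path

    from .simscene import Scene, SceneTruth

    d = Path(scene_dir)
    bands = {
        name: tifffile.imread(d / f"{name}.tif").astype(float)
        for name in ("ndvi", "red", "swir", "lst")
    }
    qa = tifffile.imread(d / "qa.tif").astype(np.uint8)
    fraction = tifffile.imread(d / "truth_fraction.tif").astype(float)
    shift = tifffile.imread(d / "truth_shift.tif").astype(int)
    with tifffile.TiffFile(d / "truth_fraction.tif") as tf:
        scale = tf.pages[0].tags.get(_TAG_PIXEL_SCALE)
        pixel_size = float(scale.value[0]) if scale is not None else 231.65635826
    truth = SceneTruth(fraction=fraction, pheno_shift=shift, pixel_size=pixel_size)
    return Scene(qa=qa, truth=truth, **bands)
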