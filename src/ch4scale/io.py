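"""Read and write land-cover rasters (ESRI ASCII grid, GeoTIFF).

Both formats are lossless for integer class codes. The codebook and CRS do
not fit in either format's header, so ``write_grid`` stores them in a JSON
sidecar (``<path>.aux.json``) which ``read_grid`` picks up when present;
without a sidecar the codebook defaults to ``class_<code>`` names.

GeoTIFF is handled with :mod:`tifffile`, writing the standard GeoTIFF pixel
scale tag (ModelPixelScaleTag, 33550) and the GDAL nodata tag (42113), which
GIS software reads back. ESRI ASCII uses the classic
``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` header with
space-delimited integers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .landcover import HarmonizationMap, LandCoverGrid

__all__ = ["read_grid", "write_grid", "load_harmonization_map"]

_ASCII_SUFFIXES = {".asc", ".txt"}
_TIFF_SUFFIXES = {".tif", ".tiff"}

_MODEL_PIXEL_SCALE = 33550
_GDAL_NODATA = 42113


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in {"ascii_grid", "geotiff"}:
            raise ValueError(f"unknown format {fmt!r}; use 'ascii_grid' or 'geotiff'")
        return fmt
    suffix = path.suffix.lower()
    if suffix in _ASCII_SUFFIXES:
        return "ascii_grid"
    if suffix in _TIFF_SUFFIXES:
        return "geotiff"
    raise ValueError(f"cannot infer raster format from suffix {suffix!r} of {path}")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".aux.json")


def write_grid(grid: LandCoverGrid, path: str | Path, fmt: str | None = None) -> None:
    """Write a grid plus a JSON sidecar with codebook, nodata and pixel size."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "ascii_grid":
        _write_ascii(grid, path)
    else:
        _write_geotiff(grid, path)
    sidecar = {
        "pixel_size_m": grid.pixel_size_m,
        "nodata_code": grid.nodata_code,
        "codebook": {str(k): v for k, v in grid.codebook.items()},
        "crs": grid.crs,
        "class_fractions": {
            grid.codebook[c]: f for c, f in sorted(grid.class_fractions().items())
        },
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def read_grid(
    path: str | Path,
    fmt: str | None = None,
    nodata_override: int | None = None,
) -> LandCoverGrid:
    """Read a grid; pixel size comes from the file header/tags.

    ``nodata_override`` replaces the nodata code declared in the file, for
    deposited maps whose nodata convention is unrecorded.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "ascii_grid":
        values, pixel, nodata = _read_ascii(path)
    else:
        values, pixel, nodata = _read_geotiff(path)

    codebook: dict[int, str] | None = None
    crs = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        codebook = {int(k): v for k, v in meta.get("codebook", {}).items()}
        crs = meta.get("crs")
        if nodata is None:
            nodata = meta.get("nodata_code")
    if nodata_override is not None:
        nodata = nodata_override
    if nodata is None:
        nodata = -9999
    if codebook is None:
        codes = set(np.unique(values).tolist()) - {int(nodata)}
        codebook = {int(c): f"class_{int(c)}" for c in codes}
    return LandCoverGrid(
        values=values, pixel_size_m=pixel, codebook=codebook, nodata_code=int(nodata), crs=crs
    )


# ---------------------------------------------------------------------------
# ESRI ASCII grid


def _write_ascii(grid: LandCoverGrid, path: Path) -> None:
    rows, cols = grid.shape
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner 0.0\n"
        f"yllcorner 0.0\n"
        f"cellsize {grid.pixel_size_m:g}\n"
        f"NODATA_value {grid.nodata_code}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt="%d", delimiter=" ")


def _read_ascii(path: Path) -> tuple[np.ndarray, float, int | None]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        values = np.loadtxt(fh, ndmin=2)
    if "cellsize" not in header:
        raise ValueError(f"{path}: ESRI ASCII header missing 'cellsize'")
    if not np.all(values == np.round(values)):
        raise ValueError(f"{path}: raster holds non-integer values; class codes expected")
    values = values.astype(np.int64)
    rows, cols = values.shape
    if "nrows" in header and (rows, cols) != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: data block {rows}x{cols} disagrees with header "
            f"{int(header['nrows'])}x{int(header['ncols'])}"
        )
    nodata = header.get("nodata_value")
    return values, float(header["cellsize"]), None if nodata is None else int(nodata)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# GeoTIFF


def _write_geotiff(grid: LandCoverGrid, path: Path) -> None:
    px = float(grid.pixel_size_m)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (px, px, 0.0)),
        (_GDAL_NODATA, "s", 0, str(grid.nodata_code)),
    ]
    tifffile.imwrite(path, grid.values.astype(np.int32), extratags=extratags)


def _read_geotiff(path: Path) -> tuple[np.ndarray, float, int | None]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        scale = tags.get(_MODEL_PIXEL_SCALE)
        if scale is None:
            raise ValueError(f"{path}: GeoTIFF lacks ModelPixelScaleTag; pixel size unknown")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        if abs(sx - sy) > 1e-9 * max(sx, sy):
            raise ValueError(f"{path}: non-square pixels ({sx} x {sy} m) unsupported")
        nd_tag = tags.get(_GDAL_NODATA)
        nodata = int(float(str(nd_tag.value))) if nd_tag is not None else None
    if values.ndim != 2:
        raise ValueError(f"{path}: expected single-band raster, got shape {values.shape}")
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(values == np.round(values)):
            raise ValueError(f"{path}: float raster with non-integer values")
        values = values.astype(np.int64)
    return values.astype(np.int64), sx, nodata


# ---------------------------------------------------------------------------
# Harmonization maps


def load_harmonization_map(path: str | Path) -> HarmonizationMap:
    """Load a raw->harmonized class map from YAML or 2-column CSV.

    YAML schema::

        mapping: {raw_code_or_name: harmonized_name, ...}
        wetland_classes: [fen, bog, ...]   # optional
        lake_classes: [lake]               # optional

    A 2-column CSV (``raw,harmonized``, optional header) carries only the
    mapping; wetland/lake flags then fall back to conventional class names.
    """
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        doc = yaml.safe_load(path.read_text())
        mapping = {_coerce_key(k): str(v) for k, v in doc["mapping"].items()}
        if "wetland_classes" in doc or "lake_classes" in doc:
            return HarmonizationMap(
                mapping=mapping,
                wetland_classes=frozenset(doc.get("wetland_classes", [])),
                lake_classes=frozenset(doc.get("lake_classes", [])),
            )
        return HarmonizationMap.with_default_flags(mapping)

    mapping = {}
    for i, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 2:
            raise ValueError(f"{path}:{i + 1}: expected 2 columns, got {len(parts)}")
        if i == 0 and not _is_number(parts[0]) and parts[0].lower() in {"raw", "code", "class"}:
            continue
        mapping[_coerce_key(parts[0])] = parts[1]
    return HarmonizationMap.with_default_flags(mapping)


def _coerce_key(key) -> int | str:
    if isinstance(key, int):
        return key
    s = str(key)
    try:
        return int(s)
    except ValueError:
        return s
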