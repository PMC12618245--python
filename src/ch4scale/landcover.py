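"""Categorical land-cover grids: container, harmonization, alignment cropping.

A :class:`LandCoverGrid` is the in-memory form of a classified map: a 2-D
integer array of class codes (row-major, origin at the top-left), a square
pixel size in meters, a codebook mapping codes to harmonized class names, and
a nodata code. Pixel area is ``pixel_size_m ** 2`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "LandCoverGrid",
    "HarmonizationMap",
    "harmonize_classes",
    "crop_to_multiple",
    "DEFAULT_WETLAND_NAMES",
    "DEFAULT_LAKE_NAMES",
]

#: Class names treated as wetland when a harmonization map does not say.
DEFAULT_WETLAND_NAMES = frozenset(
    {"fen", "bog", "other_wetland", "wetland", "permafrost_bog", "permafrost_wetland"}
)
#: Class names treated as open water when a harmonization map does not say.
DEFAULT_LAKE_NAMES = frozenset({"lake", "water", "open_water"})


@dataclass
class LandCoverGrid:
    """A categorical raster with square pixels.

    Parameters
    ----------
    values : ndarray of int, shape (rows, cols)
        Class codes; ``nodata_code`` marks unmapped pixels.
    pixel_size_m : float
        Edge length of a (square) pixel in meters.
    codebook : mapping of int to str
        Class code -> harmonized class name. Every non-nodata value occurring
        in ``values`` must have an entry.
    nodata_code : int
        Code for missing pixels (never listed in the codebook).
    crs : str, optional
        Free-form CRS description; carried along, never interpreted.
    """

    values: np.ndarray
    pixel_size_m: float
    codebook: dict[int, str]
    nodata_code: int = -9999
    crs: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError(f"values must be 2-D with >=1 row/col, got shape {self.values.shape}")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError(f"values must be integer-typed, got {self.values.dtype}")
        if not self.pixel_size_m > 0:
            raise ValueError(f"pixel_size_m must be > 0, got {self.pixel_size_m}")
        self.codebook = {int(k): str(v) for k, v in self.codebook.items()}
        if self.nodata_code in self.codebook:
            raise ValueError("nodata_code must not appear in the codebook")
        present = set(np.unique(self.values).tolist()) - {self.nodata_code}
        missing = present - set(self.codebook)
        if missing:
            raise ValueError(f"values contain codes absent from codebook: {sorted(missing)}")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_m2(self) -> float:
        return float(self.pixel_size_m) ** 2

    @property
    def extent_m2(self) -> float:
        """Total mapped (non-nodata) area in m^2."""
        return int(np.sum(self.values != self.nodata_code)) * self.pixel_area_m2

    # -- class bookkeeping ----------------------------------------------
    def class_counts(self) -> dict[int, int]:
        """Pixel count per non-nodata class code (codes absent -> 0 omitted)."""
        codes, counts = np.unique(self.values, return_counts=True)
        return {
            int(c): int(n) for c, n in zip(codes, counts) if int(c) != self.nodata_code
        }

    def class_fractions(self) -> dict[int, float]:
        """Areal fraction per class code over the non-nodata extent."""
        counts = self.class_counts()
        total = sum(counts.values())
        if total == 0:
            raise ValueError("grid has no valid (non-nodata) pixels")
        return {c: n / total for c, n in counts.items()}

    def code_of(self, class_name: str) -> int:
        for code, name in self.codebook.items():
            if name == class_name:
                return code
        raise KeyError(f"class {class_name!r} not in codebook {self.codebook}")

    def with_values(self, values: np.ndarray, **changes) -> "LandCoverGrid":
        return replace(self, values=values, **changes)


@dataclass
class HarmonizationMap:
    """Raw class -> harmonized class mapping, plus wetland/lake flags.

    ``mapping`` keys may be raw integer codes or raw class names; values are
    harmonized class names. ``wetland_classes`` and ``lake_classes`` are
    disjoint subsets of the harmonized names.
    """

    mapping: dict[int | str, str]
    wetland_classes: frozenset[str] = field(default_factory=frozenset)
    lake_classes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.wetland_classes = frozenset(self.wetland_classes)
        self.lake_classes = frozenset(self.lake_classes)
        overlap = self.wetland_classes & self.lake_classes
        if overlap:
            raise ValueError(f"classes flagged both wetland and lake: {sorted(overlap)}")

    @classmethod
    def with_default_flags(cls, mapping: Mapping[int | str, str]) -> "HarmonizationMap":
        """Flag wetland/lake classes by their conventional names."""
        targets = set(mapping.values())
        return cls(
            mapping=dict(mapping),
            wetland_classes=frozenset(targets & set(DEFAULT_WETLAND_NAMES)),
            lake_classes=frozenset(targets & set(DEFAULT_LAKE_NAMES)),
        )

    def harmonized_name(self, raw_code: int, raw_name: str | None) -> str | None:
        if raw_code in self.mapping:
            return self.mapping[raw_code]
        if raw_name is not None and raw_name in self.mapping:
            return self.mapping[raw_name]
        return None


def harmonize_classes(grid: LandCoverGrid, hmap: HarmonizationMap) -> LandCoverGrid:
    """Relabel a raster's raw classes into harmonized classes.

    Pixel geometry is unchanged and areas are conserved: each raw class's
    pixels all move to exactly one harmonized class. Harmonized codes are
    assigned 1..K in sorted harmonized-name order, so the result is
    independent of the raw coding.

    Raises
    ------
    ValueError
        If any non-nodata code in the grid has no mapping entry.
    """
    raw_codes = sorted(set(np.unique(grid.values).tolist()) - {grid.nodata_code})
    target_by_raw: dict[int, str] = {}
    unmapped = []
    for code in raw_codes:
        name = hmap.harmonized_name(code, grid.codebook.get(code))
        if name is None:
            unmapped.append(code)
        else:
            target_by_raw[code] = name
    if unmapped:
        raise ValueError(f"unmapped raw codes: {unmapped}")

    harmonized_names = sorted(set(target_by_raw.values()))
    code_by_name = {name: i + 1 for i, name in enumerate(harmonized_names)}
    # nodata must stay distinct from the new 1..K codes
    nodata = grid.nodata_code if grid.nodata_code not in code_by_name.values() else -9999

    lut_src = np.array(raw_codes + [grid.nodata_code])
    lut_dst = np.array([code_by_name[target_by_raw[c]] for c in raw_codes] + [nodata])
    order = np.argsort(lut_src)
    idx = np.searchsorted(lut_src[order], grid.values)
    out = lut_dst[order][idx]

    return LandCoverGrid(
        values=out.astype(grid.values.dtype, copy=False),
        pixel_size_m=grid.pixel_size_m,
        codebook={c: n for n, c in code_by_name.items()},
        nodata_code=nodata,
        crs=grid.crs,
    )


def crop_to_multiple(grid: LandCoverGrid, target_pixel_m: float) -> LandCoverGrid:
    """Crop so both dimensions are exact multiples of the aggregation factor.

    The factor is ``target_pixel_m / grid.pixel_size_m`` and must be a whole
    number. Cropping is anchored at the top-left origin; the right/bottom
    remainder is discarded so no partial blocks remain at the map edges.
    """
    factor = _integer_factor(target_pixel_m, grid.pixel_size_m)
    rows, cols = grid.shape
    new_rows = (rows // factor) * factor
    new_cols = (cols // factor) * factor
    if new_rows == 0 or new_cols == 0:
        raise ValueError(
            f"grid {rows}x{cols} smaller than one {factor}x{factor} block "
            f"for target pixel {target_pixel_m} m"
        )
    if (new_rows, new_cols) == (rows, cols):
        return grid
    return grid.with_values(grid.values[:new_rows, :new_cols])


def _integer_factor(target_pixel_m: float, pixel_size_m: float) -> int:
    """Aggregation block edge in input pixels; errors on non-integer ratios."""
    ratio = target_pixel_m / pixel_size_m
    factor = round(ratio)
    if factor < 1 or abs(ratio - factor) > 1e-9 * max(1.0, abs(ratio)):
        raise ValueError(
            f"target pixel {target_pixel_m} m is not an integer multiple "
            f"of the grid pixel {pixel_size_m} m"
        )
    return int(factor)
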