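"""Majority (mode) block aggregation of categorical rasters.

Coarsening a classified map to a larger pixel size assigns each output pixel
the most frequent class within its block of input pixels — the rule most
moderate- and coarse-resolution land-cover products are built with. Every
ladder step is aggregated directly from the (cropped) reference map, never
from a previously coarsened step, so aggregation error does not cascade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .landcover import LandCoverGrid, crop_to_multiple, _integer_factor

__all__ = ["DEFAULT_LADDER_M", "ResolutionSeries", "mode_aggregate", "build_resolution_series"]

logger = logging.getLogger(__name__)

#: Coarsening ladder in meters applied on top of the nominal resolution.
DEFAULT_LADDER_M: tuple[float, ...] = (5, 10, 25, 50, 100, 250, 500, 1000, 1250, 5000)

_TIE_BREAKS = ("smallest_code", "largest_area")


@dataclass
class ResolutionSeries:
    """One landscape at each retained ladder step.

    ``grids[0]`` is the reference map at nominal resolution; each later grid
    is the mode-aggregated map at the matching entry of ``resolutions_m``.
    """

    resolutions_m: list[float]
    grids: list[LandCoverGrid]

    def __post_init__(self) -> None:
        if len(self.resolutions_m) != len(self.grids):
            raise ValueError("resolutions_m and grids must have equal length")
        if not self.grids:
            raise ValueError("empty resolution series")
        res = np.asarray(self.resolutions_m, dtype=float)
        if np.any(np.diff(res) <= 0):
            raise ValueError(f"resolutions must be strictly increasing, got {self.resolutions_m}")
        for r, g in zip(self.resolutions_m, self.grids):
            if abs(g.pixel_size_m - r) > 1e-9 * r:
                raise ValueError(f"grid pixel size {g.pixel_size_m} != ladder entry {r}")

    def __len__(self) -> int:
        return len(self.grids)

    def __iter__(self):
        return iter(zip(self.resolutions_m, self.grids))


def mode_aggregate(
    grid: LandCoverGrid,
    target_pixel_m: float,
    tie_break: str = "smallest_code",
) -> LandCoverGrid:
    """Coarsen a grid by per-block majority vote.

    Each output pixel takes the most frequent non-nodata class within its
    ``factor x factor`` block, ``factor = target_pixel_m / pixel_size_m``
    (must be a whole number, and the grid pre-cropped so both dimensions are
    multiples of it — see :func:`~ch4scale.landcover.crop_to_multiple`).

    Ties are broken deterministically: ``"smallest_code"`` (default) prefers
    the smaller integer class code; ``"largest_area"`` prefers the class
    covering more area in the input grid (then the smaller code). Nodata
    pixels never vote; an all-nodata block stays nodata.
    """
    if tie_break not in _TIE_BREAKS:
        raise ValueError(f"tie_break must be one of {_TIE_BREAKS}, got {tie_break!r}")
    factor = _integer_factor(target_pixel_m, grid.pixel_size_m)
    if factor == 1:
        return grid.with_values(grid.values.copy())
    rows, cols = grid.shape
    if rows % factor or cols % factor:
        raise ValueError(
            f"grid {rows}x{cols} not a multiple of factor {factor}; crop first"
        )

    counts = grid.class_counts()
    if tie_break == "smallest_code":
        order = sorted(counts)
    else:  # largest native-resolution area first, code as final tie-break
        order = sorted(counts, key=lambda c: (-counts[c], c))

    out_shape = (rows // factor, cols // factor)
    block_counts = np.empty((len(order),) + out_shape, dtype=np.int64)
    blocks = grid.values.reshape(out_shape[0], factor, out_shape[1], factor)
    for i, code in enumerate(order):
        block_counts[i] = (blocks == code).sum(axis=(1, 3))

    if block_counts.size == 0:  # all-nodata input
        out = np.full(out_shape, grid.nodata_code, dtype=grid.values.dtype)
        return grid.with_values(out, pixel_size_m=float(target_pixel_m))

    # argmax keeps the first maximum, i.e. the highest-priority class in `order`
    winner_idx = block_counts.argmax(axis=0)
    out = np.asarray(order, dtype=grid.values.dtype)[winner_idx]
    out[block_counts.sum(axis=0) == 0] = grid.nodata_code
    return grid.with_values(out, pixel_size_m=float(target_pixel_m))


def build_resolution_series(
    grid: LandCoverGrid,
    steps_m: Sequence[float] = DEFAULT_LADDER_M,
    tie_break: str = "smallest_code",
) -> ResolutionSeries:
    """Aggregate a reference map across a ladder of coarser pixel sizes.

    Each retained step is produced from the reference grid, cropped (top-left
    anchored) so no partial blocks remain at the map edges. Steps whose
    factor is not a whole number of reference pixels, or for which the map
    cannot hold a single block, are dropped with a logged warning.
    """
    steps = [float(s) for s in steps_m]
    if sorted(set(steps)) != steps:
        raise ValueError(f"steps must be strictly increasing, got {steps_m}")

    resolutions = [float(grid.pixel_size_m)]
    grids = [grid]
    for step in steps:
        if step <= grid.pixel_size_m:
            continue
        try:
            cropped = crop_to_multiple(grid, step)
        except ValueError as exc:
            logger.warning("dropping %g m step: %s", step, exc)
            continue
        grids.append(mode_aggregate(cropped, step, tie_break=tie_break))
        resolutions.append(step)
    if len(grids) == 1 and any(s > grid.pixel_size_m for s in steps):
        raise ValueError("no requested ladder step fits the grid; empty retained ladder")
    return ResolutionSeries(resolutions_m=resolutions, grids=grids)
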