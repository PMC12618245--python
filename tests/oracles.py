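"""Independent brute-force oracles, kept free of the package's vectorized code."""

from __future__ import annotations

import numpy as np


def brute_force_mode_aggregate(
    values: np.ndarray,
    factor: int,
    nodata: int,
    tie_break: str = "smallest_code",
    native_counts: dict[int, int] | None = None,
) -> np.ndarray:
    """Per-block histogram majority, one block at a time.

    ``tie_break``: 'smallest_code' prefers the smaller code among tied
    classes; 'largest_area' prefers the class with the larger count in
    ``native_counts`` (the full input grid by default), then smaller code.
    """
    rows, cols = values.shape
    assert rows % factor == 0 and cols % factor == 0
    if native_counts is None:
        codes, counts = np.unique(values[values != nodata], return_counts=True)
        native_counts = dict(zip(codes.tolist(), counts.tolist()))
    out = np.full((rows // factor, cols // factor), nodata, dtype=values.dtype)
    for i in range(rows // factor):
        for j in range(cols // factor):
            block = values[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
            hist: dict[int, int] = {}
            for v in block.ravel().tolist():
                if v != nodata:
                    hist[v] = hist.get(v, 0) + 1
            if not hist:
                continue
            best = max(hist)
            if tie_break == "smallest_code":
                key = lambda c: (hist[c], -c)  # noqa: E731
            else:
                key = lambda c: (hist[c], native_counts.get(c, 0), -c)  # noqa: E731
            best = max(hist, key=key)
            out[i, j] = best
    return out


def flood_fill_patches(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int]]]:
    """Connected components of a boolean mask by explicit stack-based flood fill."""
    assert connectivity in (4, 8)
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    rows, cols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    patches = []
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c] or seen[r, c]:
                continue
            stack = [(r, c)]
            seen[r, c] = True
            patch = set()
            while stack:
                y, x = stack.pop()
                patch.add((y, x))
                for dy, dx in offsets:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < rows and 0 <= nx < cols and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            patches.append(patch)
    return patches
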