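"""Synthetic categorical landscapes with controlled fractions and patchiness.

Arctic and boreal wetland mosaics are highly patterned: fens, bogs and other
wet classes occur as patches from a few meters to hundreds of meters across,
embedded in an upland/forest matrix. This module emulates that structure
with a neutral landscape model: one smooth Gaussian latent field per
landscape (white noise convolved with a Gaussian kernel whose scale,
``correlation_length_px``, sets the patch scale) thresholded into classes by
quantile bands sized to the target areal fractions. Quantile banding makes
realized fractions match their targets to within rounding by construction,
while the kernel scale tunes fragmentation: short correlation lengths give
many small scattered patches (division index near 1), long ones give a few
large blobs.

Class bands are ordered along the latent axis from wet to dry
(lake, fen, bog, other wetland, forest, upland, barren) so wet classes are
spatially adjacent, mimicking hydrological zonation down a moisture gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .landcover import LandCoverGrid
from .upscaling import BAWLD_MEDIUM_PEATLAND_LAKES, FluxTable

__all__ = [
    "CLASS_ORDER",
    "DEFAULT_CODES",
    "SyntheticConfig",
    "SiteSuiteSpec",
    "generate_landscape",
    "generate_site_suite",
    "site_class_fractions",
    "make_flux_table",
]

#: Order of class bands along the latent (moisture) axis, wet to dry.
CLASS_ORDER: tuple[str, ...] = (
    "lake",
    "fen",
    "bog",
    "other_wetland",
    "forest",
    "upland",
    "barren",
)

#: Integer codes for the harmonized classes.
DEFAULT_CODES: dict[str, int] = {name: i + 1 for i, name in enumerate(CLASS_ORDER)}

_NODATA = -9999


@dataclass
class SyntheticConfig:
    """Recipe for one synthetic landscape.

    Parameters
    ----------
    grid_size : int
        Pixels per side (square grid), >= 2.
    pixel_size_m : float
        Pixel edge in meters; 2.5 m matches very-high-resolution site maps.
    class_fractions : dict
        Target areal fraction per class name; nonnegative, summing to 1.
    correlation_length_px : float
        Gaussian kernel sigma in pixels; 0 gives uncorrelated (salt-and-
        pepper) classes, larger values give larger patches.
    seed : int
        RNG seed; identical config + seed reproduces the raster bit for bit.
    nodata_fraction : float
        Fraction of pixels masked as nodata by an independent random mask.
    class_order : sequence of str
        Band order along the latent axis; classes absent from
        ``class_fractions`` are ignored, unknown classes are appended.
    """

    grid_size: int
    class_fractions: dict[str, float]
    pixel_size_m: float = 2.5
    correlation_length_px: float = 8.0
    seed: int = 0
    nodata_fraction: float = 0.0
    class_order: Sequence[str] = CLASS_ORDER

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ValueError(f"grid_size must be >= 2, got {self.grid_size}")
        if self.correlation_length_px < 0:
            raise ValueError("correlation_length_px must be >= 0")
        if not 0.0 <= self.nodata_fraction < 1.0:
            raise ValueError("nodata_fraction must be in [0, 1)")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be nonnegative")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, expected 1")

    def ordered_classes(self) -> list[str]:
        """Classes with positive fraction, in latent-axis band order."""
        known = [c for c in self.class_order if self.class_fractions.get(c, 0) > 0]
        extra = sorted(c for c in self.class_fractions if c not in self.class_order
                       and self.class_fractions[c] > 0)
        return known + extra


@dataclass
class SiteSuiteSpec:
    """Recipe for a multi-site suite spanning wetland cover and patchiness.

    Sites get wetland fractions evenly spaced across
    ``wetland_fraction_range`` and correlation lengths cycled from
    ``fragmentation_gradient``; per-site seeds derive from
    ``base_config.seed``.
    """

    n_sites: int
    wetland_fraction_range: tuple[float, float]
    fragmentation_gradient: Sequence[float]
    base_config: SyntheticConfig = field(
        default_factory=lambda: SyntheticConfig(
            grid_size=512, class_fractions={"upland": 1.0}
        )
    )

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        low, high = self.wetland_fraction_range
        if not 0.0 <= low <= high <= 1.0:
            raise ValueError(f"invalid wetland fraction range ({low}, {high})")
        if len(self.fragmentation_gradient) == 0:
            raise ValueError("fragmentation_gradient must be non-empty")


def generate_landscape(config: SyntheticConfig) -> LandCoverGrid:
    """Draw one landscape from the latent-field model.

    A single standard-normal field is smoothed with a Gaussian kernel of
    sigma ``correlation_length_px`` and cut into quantile bands whose widths
    equal the target class fractions, assigning bands wet-to-dry along the
    latent axis. Nodata pixels, if requested, are masked independently.
    """
    rng = np.random.default_rng(config.seed)
    n = config.grid_size
    latent = rng.standard_normal((n, n))
    if config.correlation_length_px > 0:
        latent = ndimage.gaussian_filter(latent, sigma=config.correlation_length_px)

    classes = config.ordered_classes()
    fractions = np.array([config.class_fractions[c] for c in classes])
    cut_points = np.cumsum(fractions)[:-1]
    thresholds = np.quantile(latent, cut_points) if len(cut_points) else np.array([])
    band = np.searchsorted(thresholds, latent, side="right")

    codes = np.array([DEFAULT_CODES.get(c, 100 + i) for i, c in enumerate(classes)])
    values = codes[band].astype(np.int32)

    if config.nodata_fraction > 0:
        mask = rng.random((n, n)) < config.nodata_fraction
        values[mask] = _NODATA

    codebook = {int(codes[i]): classes[i] for i in range(len(classes))}
    return LandCoverGrid(
        values=values,
        pixel_size_m=config.pixel_size_m,
        codebook=codebook,
        nodata_code=_NODATA,
    )


def site_class_fractions(wetland_fraction: float, include_lakes: bool = True) -> dict[str, float]:
    """Split a target wetland fraction into a realistic class composition.

    The wetland share goes 45% bog, 40% fen, 15% other wetland (bogs
    slightly exceeding fens, as in mixed peatland mosaics); the dry
    remainder is 52% upland, 30% forest, 15% barren and 3% lake (lakes a
    few percent of the landscape). Fractions sum to 1 exactly.
    """
    w = float(wetland_fraction)
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"wetland fraction {w} outside [0, 1]")
    dry = 1.0 - w
    dry_split = {"upland": 0.52, "forest": 0.30, "barren": 0.15, "lake": 0.03}
    if not include_lakes:
        dry_split.pop("lake")
        norm = sum(dry_split.values())
        dry_split = {k: v / norm for k, v in dry_split.items()}
    fractions = {"bog": 0.45 * w, "fen": 0.40 * w, "other_wetland": 0.15 * w}
    fractions.update({k: v * dry for k, v in dry_split.items()})
    fractions = {k: v for k, v in fractions.items() if v > 0}
    total = sum(fractions.values())
    return {k: v / total for k, v in fractions.items()}


def generate_site_suite(spec: SiteSuiteSpec) -> list[LandCoverGrid]:
    """One landscape per site, wetland cover spanning the requested range.

    Wetland fractions are evenly spaced from low to high; fragmentation
    (correlation length) cycles through the gradient; site i uses seed
    ``base.seed + i`` so the suite is deterministic yet sites differ.
    """
    low, high = spec.wetland_fraction_range
    wet_fracs = np.linspace(low, high, spec.n_sites)
    grids = []
    for i, w in enumerate(wet_fracs):
        corr = spec.fragmentation_gradient[i % len(spec.fragmentation_gradient)]
        config = replace(
            spec.base_config,
            class_fractions=site_class_fractions(float(w)),
            correlation_length_px=float(corr),
            seed=spec.base_config.seed + i,
        )
        grids.append(generate_landscape(config))
    return grids


def make_flux_table(seed: int = 0) -> FluxTable:
    """Plausible per-class CH4 fluxes (g C-CH4 ha^-1 h^-1) for a site.

    Wet classes emit (fens > bogs > other wetlands > 0), dry classes are
    weak sinks (<= 0), and lakes carry the converted BAWLD medium peatland
    lake median. Means are jittered +-10% around field-plausible magnitudes,
    standard errors sit near 40% of the mean magnitude (chamber campaigns
    commonly report relative SEs of that order), and plot counts span the
    range seen in site syntheses. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    base = {
        "fen": 30.0,
        "bog": 12.0,
        "other_wetland": 6.0,
        "forest": -0.3,
        "upland": -0.5,
        "barren": -0.1,
    }
    mean_flux, se_flux, n_plots = {}, {}, {}
    for cls in sorted(base):
        jitter = 1.0 + rng.uniform(-0.10, 0.10)
        mean = base[cls] * jitter
        mean_flux[cls] = mean
        se_flux[cls] = abs(mean) * (0.4 + rng.uniform(-0.1, 0.1))
        n_plots[cls] = int(rng.integers(12, 280))
    lake = BAWLD_MEDIUM_PEATLAND_LAKES
    mean_flux["lake"] = lake.as_g_c_ha_h("median")
    se_flux["lake"] = 0.5 * (lake.as_g_c_ha_h("q75") - lake.as_g_c_ha_h("q25"))
    n_plots["lake"] = 0  # no in-situ plots; literature constant
    return FluxTable(mean_flux=mean_flux, se_flux=se_flux, n_plots=n_plots)
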