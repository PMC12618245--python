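"""Area-weighted regional CH4 flux upscaling from a classified map.

The regional flux is the class-area-weighted mean of per-class plot fluxes,

    FCH4_region = sum_i (A_i * FCH4_i) / A_region,

with A_i the mapped area of class i, FCH4_i its mean measured flux in
g C-CH4 ha^-1 h^-1 (negative = uptake, positive = emission), and A_region
the total mapped (non-nodata) area. The standard error treats class means as
independent and areas as error-free: SE = sqrt(sum_i f_i^2 * SE_i^2) with
f_i the areal fraction of class i.

Open-water classes usually lack chamber measurements; their flux defaults to
the BAWLD-CH4 medium-sized peatland lake median (63.5 mg CH4 m^-2 d^-1,
diffusion 18.4 + ebullition 45.1), converted to g C-CH4 ha^-1 h^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .landcover import (
    DEFAULT_LAKE_NAMES,
    DEFAULT_WETLAND_NAMES,
    HarmonizationMap,
    LandCoverGrid,
)

__all__ = [
    "FluxTable",
    "RegionalFlux",
    "LakeFluxConstants",
    "BAWLD_MEDIUM_PEATLAND_LAKES",
    "MG_CH4_M2_D_TO_G_C_HA_H",
    "convert_lake_flux",
    "regional_flux",
    "propagate_se",
    "wetland_fraction",
]

#: Molar mass of carbon over methane: CH4 mass -> C mass.
_C_PER_CH4 = 12.011 / 16.043

#: mg CH4 m^-2 d^-1 -> g C-CH4 ha^-1 h^-1:
#: mg->g (1e-3) * m^-2 -> ha^-1 (1e4) * d^-1 -> h^-1 (1/24) * CH4 -> C.
MG_CH4_M2_D_TO_G_C_HA_H = _C_PER_CH4 * 1e-3 * 1e4 / 24.0


def convert_lake_flux(value_mg_ch4_m2_d: float) -> float:
    """Convert a lake flux from mg CH4 m^-2 d^-1 to g C-CH4 ha^-1 h^-1."""
    return float(value_mg_ch4_m2_d) * MG_CH4_M2_D_TO_G_C_HA_H


@dataclass(frozen=True)
class LakeFluxConstants:
    """Median and quartile lake CH4 fluxes, split by transport pathway.

    All values in mg CH4 m^-2 d^-1; each total must equal its diffusive plus
    ebullitive component exactly, and quartiles must bracket the median.
    """

    median_total: float
    median_diffusion: float
    median_ebullition: float
    q25_total: float
    q25_diffusion: float
    q25_ebullition: float
    q75_total: float
    q75_diffusion: float
    q75_ebullition: float

    def __post_init__(self) -> None:
        for label in ("median", "q25", "q75"):
            total = getattr(self, f"{label}_total")
            parts = getattr(self, f"{label}_diffusion") + getattr(self, f"{label}_ebullition")
            if total != parts:
                raise ValueError(
                    f"{label}: total {total} != diffusion + ebullition {parts}"
                )
        if not (self.q25_total <= self.median_total <= self.q75_total):
            raise ValueError("quartile totals must bracket the median")

    def as_g_c_ha_h(self, which: str = "median") -> float:
        """Total flux for 'q25' | 'median' | 'q75', in g C-CH4 ha^-1 h^-1."""
        return convert_lake_flux(getattr(self, f"{which}_total"))


#: BAWLD-CH4 "medium-sized peatland lakes" medians and quartiles.
BAWLD_MEDIUM_PEATLAND_LAKES = LakeFluxConstants(
    median_total=63.5,
    median_diffusion=18.4,
    median_ebullition=45.1,
    q25_total=31.8,
    q25_diffusion=11.0,
    q25_ebullition=20.8,
    q75_total=122.5,
    q75_diffusion=42.0,
    q75_ebullition=80.5,
)


@dataclass
class FluxTable:
    """Per-class mean CH4 flux with standard error and plot count.

    ``mean_flux`` and ``se_flux`` are in g C-CH4 ha^-1 h^-1, keyed by
    harmonized class name.
    """

    mean_flux: dict[str, float]
    se_flux: dict[str, float]
    n_plots: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = set(self.se_flux) - set(self.mean_flux)
        if extra:
            raise ValueError(f"se_flux for classes without a mean: {sorted(extra)}")
        for cls, se in self.se_flux.items():
            if se < 0:
                raise ValueError(f"negative se_flux for {cls!r}: {se}")

    @property
    def classes(self) -> set[str]:
        return set(self.mean_flux)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": cls,
                "mean_flux": self.mean_flux[cls],
                "se_flux": self.se_flux.get(cls, 0.0),
                "n": self.n_plots.get(cls, 0),
            }
            for cls in sorted(self.mean_flux)
        ]
        return pd.DataFrame(rows, columns=["class", "mean_flux", "se_flux", "n"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FluxTable":
        df = pd.read_csv(path)
        required = {"class", "mean_flux", "se_flux"}
        if not required <= set(df.columns):
            raise ValueError(f"flux table needs columns {sorted(required)}, got {list(df.columns)}")
        return cls(
            mean_flux=dict(zip(df["class"], df["mean_flux"].astype(float))),
            se_flux=dict(zip(df["class"], df["se_flux"].astype(float))),
            n_plots=dict(zip(df["class"], df["n"].astype(int))) if "n" in df else {},
        )


@dataclass
class RegionalFlux:
    """Upscaled regional flux with its per-class decomposition."""

    value: float  # g C-CH4 ha^-1 h^-1
    se: float
    per_class_contribution: dict[str, tuple[float, float]]  # class -> (fraction, contribution)
    resolution_m: float

    def __post_init__(self) -> None:
        fracs = sum(f for f, _ in self.per_class_contribution.values())
        contribs = sum(c for _, c in self.per_class_contribution.values())
        if abs(fracs - 1.0) > 1e-9:
            raise ValueError(f"area fractions sum to {fracs}, expected 1")
        if abs(contribs - self.value) > 1e-9 * max(1.0, abs(self.value)):
            raise ValueError(f"contributions sum to {contribs}, expected value {self.value}")


def propagate_se(area_fractions: Sequence[float], se_by_class: Sequence[float]) -> float:
    """SE of the area-weighted mean, independent class means, fixed areas."""
    f = np.asarray(area_fractions, dtype=float)
    s = np.asarray(se_by_class, dtype=float)
    if f.shape != s.shape:
        raise ValueError("area_fractions and se_by_class must align")
    if np.any(s < 0):
        raise ValueError("negative standard errors")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"area fractions sum to {f.sum()}, expected 1")
    return float(np.sqrt(np.sum(f**2 * s**2)))


def regional_flux(
    grid: LandCoverGrid,
    table: FluxTable,
    include_lakes: bool = True,
    lake_classes: Iterable[str] | None = None,
    lake_constants: LakeFluxConstants = BAWLD_MEDIUM_PEATLAND_LAKES,
    lake_quantile: str = "median",
) -> RegionalFlux:
    """Area-weighted regional FCH4 (+- SE) for one grid and flux table.

    Lake classes missing from the flux table fall back to the converted
    BAWLD lake constant (``lake_quantile`` in {'q25','median','q75'}). With
    ``include_lakes=False`` lake pixels are excluded from the mapped area
    entirely, mirroring analyses that omit open water.

    Raises
    ------
    ValueError
        If a non-lake grid class lacks a flux entry, or no valid area remains.
    """
    lakes = set(lake_classes) if lake_classes is not None else set(DEFAULT_LAKE_NAMES)
    counts = grid.class_counts()
    names = {code: grid.codebook[code] for code in counts}

    kept = {
        code: n
        for code, n in counts.items()
        if include_lakes or names[code] not in lakes
    }
    total = sum(kept.values())
    if total == 0:
        raise ValueError("no valid (non-nodata) area to upscale over")

    missing = [
        names[code]
        for code in kept
        if names[code] not in table.mean_flux and names[code] not in lakes
    ]
    if missing:
        raise ValueError(f"flux table lacks entries for classes: {sorted(set(missing))}")

    lake_default = lake_constants.as_g_c_ha_h(lake_quantile)
    fractions, ses, contributions = [], [], {}
    value = 0.0
    for code in sorted(kept):
        name = names[code]
        frac = kept[code] / total
        flux = table.mean_flux.get(name, lake_default if name in lakes else math.nan)
        se = table.se_flux.get(name, 0.0)
        contrib = frac * flux
        value += contrib
        fractions.append(frac)
        ses.append(se)
        contributions[name] = (frac, contrib)

    return RegionalFlux(
        value=value,
        se=propagate_se(fractions, ses),
        per_class_contribution=contributions,
        resolution_m=float(grid.pixel_size_m),
    )


def wetland_fraction(grid: LandCoverGrid, hmap: HarmonizationMap | None = None) -> float:
    """Percent of the non-nodata area covered by wetland classes.

    Wetland membership comes from ``hmap.wetland_classes`` when given,
    otherwise from conventional wetland class names.
    """
    wetlands = set(hmap.wetland_classes) if hmap is not None else set(DEFAULT_WETLAND_NAMES)
    if not wetlands:
        raise ValueError("wetland class set is empty")
    counts = grid.class_counts()
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no valid (non-nodata) pixels")
    wet = sum(n for code, n in counts.items() if grid.codebook[code] in wetlands)
    return 100.0 * wet / total
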