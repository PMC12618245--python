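"""Resolution-sensitivity statistics built on per-resolution regional fluxes.

For each site, the regional flux at every ladder step is compared with the
flux at the nominal (reference) resolution as a percent deviation,

    deviation_k = 100 * |F_ref - F_k| / |F_ref|,

which is nonnegative by construction even for net-sink reference sites. The
area under a site's deviation curve, integrated by the trapezoidal rule over
log-transformed resolution (so each doubling of pixel size counts equally),
summarizes how sensitive the site's flux estimate is to coarsening; sites
are ranked 1 (most sensitive) to n (least). A site whose regional flux
changes sign at some step — e.g. an apparent switch from net CH4 source to
net sink once small emitting patches are aggregated away — is flagged with
the first resolution at which the flip occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import DEFAULT_LADDER_M, ResolutionSeries, build_resolution_series
from .landcover import LandCoverGrid
from .metrics import PatchStats, patch_area_stats, pooled_patch_stats
from .upscaling import FluxTable, RegionalFlux, regional_flux, wetland_fraction

__all__ = [
    "DeviationCurve",
    "SensitivityScore",
    "CrossSiteSummary",
    "SiteResult",
    "ExperimentReport",
    "deviation_curve",
    "auc_log_trapezoid",
    "rank_sites",
    "detect_sign_transition",
    "cross_site_summary",
    "run_experiment",
]

@dataclass
class DeviationCurve:
    """Percent deviation from the reference flux at each ladder step."""

    resolutions_m: list[float]
    deviation_pct: list[float]
    reference_flux: RegionalFlux

    def __post_init__(self) -> None:
        if len(self.resolutions_m) != len(self.deviation_pct):
            raise ValueError("resolutions and deviations must align")
        if abs(self.deviation_pct[0]) > 1e-9:
            raise ValueError("deviation at the nominal resolution must be 0")
        if any(d < 0 for d in self.deviation_pct):
            raise ValueError("percent deviations must be nonnegative")


@dataclass(frozen=True)
class SensitivityScore:
    """AUC of a site's deviation curve and its cross-site rank (1 = most sensitive)."""

    site: str
    auc: float
    rank: int


def _sorted_fluxes(
    fluxes_by_resolution: Mapping[float, RegionalFlux] | Sequence[RegionalFlux],
) -> list[RegionalFlux]:
    if isinstance(fluxes_by_resolution, Mapping):
        fluxes = [fluxes_by_resolution[r] for r in sorted(fluxes_by_resolution)]
    else:
        fluxes = sorted(fluxes_by_resolution, key=lambda f: f.resolution_m)
    if not fluxes:
        raise ValueError("no fluxes given")
    return fluxes


def deviation_curve(
    fluxes_by_resolution: Mapping[float, RegionalFlux] | Sequence[RegionalFlux],
) -> DeviationCurve:
    """Percent deviation of each step's flux from the nominal-resolution flux.

    The finest resolution present is the reference; its flux must be nonzero
    (the relative deviation is undefined otherwise).
    """
    fluxes = _sorted_fluxes(fluxes_by_resolution)
    ref = fluxes[0]
    if ref.value == 0:
        raise ValueError("reference flux is exactly 0; percent deviation undefined")
    deviations = [100.0 * abs(ref.value - f.value) / abs(ref.value) for f in fluxes]
    deviations[0] = 0.0
    return DeviationCurve(
        resolutions_m=[f.resolution_m for f in fluxes],
        deviation_pct=deviations,
        reference_flux=ref,
    )


def auc_log_trapezoid(curve: DeviationCurve | tuple[Sequence[float], Sequence[float]]) -> float:
    """Area under the deviation curve over log-transformed resolution.

    Trapezoidal rule on (ln r, deviation); natural log. Using log spacing
    normalizes the distance between ladder steps so a 5->10 m step carries
    the same weight as 2500->5000 m.
    """
    if isinstance(curve, DeviationCurve):
        r, d = curve.resolutions_m, curve.deviation_pct
    else:
        r, d = curve
    r = np.asarray(r, dtype=float)
    d = np.asarray(d, dtype=float)
    if r.size < 2:
        raise ValueError("AUC needs at least two resolution steps")
    if np.any(r <= 0) or np.any(np.diff(r) <= 0):
        raise ValueError("resolutions must be positive and strictly increasing")
    return float(np.trapezoid(d, np.log(r)))


def rank_sites(aucs: Mapping[str, float]) -> dict[str, int]:
    """Rank sites by descending AUC, 1 = most sensitive; ties by site label."""
    if not aucs:
        raise ValueError("no sites to rank")
    order = sorted(aucs, key=lambda site: (-aucs[site], site))
    return {site: i + 1 for i, site in enumerate(order)}


def detect_sign_transition(
    fluxes_by_resolution: Mapping[float, RegionalFlux] | Sequence[RegionalFlux],
) -> float | None:
    """First resolution whose flux sign is opposite to the reference flux.

    Exact zero is not a flip. Returns None if the sign never flips.
    """
    fluxes = _sorted_fluxes(fluxes_by_resolution)
    ref_sign = np.sign(fluxes[0].value)
    if ref_sign == 0:
        raise ValueError("reference flux is exactly 0; transition undefined")
    for f in fluxes[1:]:
        if np.sign(f.value) == -ref_sign:
            return f.resolution_m
    return None


@dataclass
class CrossSiteSummary:
    """Per-resolution cross-site means and wetland-type contributions.

    ``per_resolution`` columns: resolution_m, mean_deviation_pct,
    se_deviation_pct (sample sd / sqrt(n); 0 when n = 1), median
    wetland_fraction_pct, n_sites, and the bog/fen proportions of the summed
    positive emissions across sites.
    """

    per_resolution: pd.DataFrame
    single_site: bool = False

    def __post_init__(self) -> None:
        if (self.per_resolution["se_deviation_pct"] < 0).any():
            raise ValueError("negative SE")


def cross_site_summary(
    curves: Mapping[str, DeviationCurve],
    series_by_site: Mapping[str, ResolutionSeries],
    flux_tables: Mapping[str, FluxTable],
    include_lakes: bool = True,
) -> CrossSiteSummary:
    """Aggregate deviation curves and wetland statistics across sites.

    Ladders may differ between sites: each resolution row reports the mean
    deviation and SE over the sites that retain that step (n tracked per
    resolution). Bog/fen proportions divide each type's summed positive
    emission (contribution rate x site mapped area, summed over sites) by
    the total positive emission of all classes at that resolution.
    """
    if not curves:
        raise ValueError("no sites")
    records: dict[float, dict] = {}
    dev_by_res: dict[float, list[float]] = {}
    wetfrac_by_res: dict[float, list[float]] = {}
    emissions_by_res: dict[float, dict[str, float]] = {}

    for site, curve in curves.items():
        for r, d in zip(curve.resolutions_m, curve.deviation_pct):
            dev_by_res.setdefault(r, []).append(d)
    for site, series in series_by_site.items():
        table = flux_tables[site]
        for r, grid in series:
            wetfrac_by_res.setdefault(r, []).append(wetland_fraction(grid))
            rf = regional_flux(grid, table, include_lakes=include_lakes)
            pool = emissions_by_res.setdefault(r, {})
            for cls, (_, contrib) in rf.per_class_contribution.items():
                if contrib > 0:
                    pool[cls] = pool.get(cls, 0.0) + contrib * grid.extent_m2

    for r in sorted(dev_by_res):
        devs = np.asarray(dev_by_res[r], dtype=float)
        n = devs.size
        se = float(devs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        pool = emissions_by_res.get(r, {})
        total_pos = sum(pool.values())
        records[r] = {
            "resolution_m": r,
            "mean_deviation_pct": float(devs.mean()),
            "se_deviation_pct": se,
            "median_wetland_fraction_pct": float(np.median(wetfrac_by_res.get(r, [np.nan]))),
            "n_sites": int(n),
            "bog_proportion": pool.get("bog", 0.0) / total_pos if total_pos > 0 else np.nan,
            "fen_proportion": pool.get("fen", 0.0) / total_pos if total_pos > 0 else np.nan,
        }
    df = pd.DataFrame([records[r] for r in sorted(records)]).reset_index(drop=True)
    return CrossSiteSummary(per_resolution=df, single_site=len(curves) == 1)


@dataclass
class SiteResult:
    """Everything computed for one site."""

    site: str
    series: ResolutionSeries
    fluxes: list[RegionalFlux]
    curve: DeviationCurve
    score: SensitivityScore
    transition_m: float | None
    wetland_patches: PatchStats


@dataclass
class ExperimentReport:
    """Full multi-site resolution-sensitivity experiment output."""

    sites: dict[str, SiteResult]
    summary: CrossSiteSummary
    pooled_patches: dict[str, PatchStats] = field(default_factory=dict)

    def deviation_frame(self) -> pd.DataFrame:
        rows = []
        for site, res in sorted(self.sites.items()):
            for r, d, f in zip(
                res.curve.resolutions_m, res.curve.deviation_pct, res.fluxes
            ):
                rows.append(
                    {
                        "site": site,
                        "resolution_m": r,
                        "flux_gc_ha_h": f.value,
                        "flux_se": f.se,
                        "deviation_pct": d,
                        "wetland_fraction_pct": wetland_fraction(
                            self.sites[site].series.grids[
                                res.curve.resolutions_m.index(r)
                            ]
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def ranks_frame(self) -> pd.DataFrame:
        rows = [
            {
                "site": site,
                "auc": res.score.auc,
                "rank": res.score.rank,
                "transition_m": res.transition_m,
                "wetland_mean_patch_area_m2": res.wetland_patches.mean_area_m2,
                "wetland_sd_patch_area_m2": res.wetland_patches.sd_area_m2,
                "wetland_division_index": res.wetland_patches.division_index,
            }
            for site, res in sorted(self.sites.items())
        ]
        return pd.DataFrame(rows)

    def write_tables(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.deviation_frame().to_csv(outdir / "deviation_curves.csv", index=False)
        self.ranks_frame().to_csv(outdir / "sensitivity_ranks.csv", index=False)
        self.summary.per_resolution.to_csv(outdir / "cross_site_summary.csv", index=False)
        transitions = pd.DataFrame(
            [
                {"site": site, "transition_m": res.transition_m}
                for site, res in sorted(self.sites.items())
            ]
        )
        transitions.to_csv(outdir / "transitions.csv", index=False)


def run_experiment(
    grids: Mapping[str, LandCoverGrid],
    flux_tables: Mapping[str, FluxTable] | FluxTable,
    ladder_m: Sequence[float] = DEFAULT_LADDER_M,
    connectivity: int = 8,
    tie_break: str = "smallest_code",
    include_lakes: bool = True,
    wetland_classes: Sequence[str] = ("fen", "bog", "other_wetland"),
    output_dir: str | Path | None = None,
) -> ExperimentReport:
    """Run the full pipeline: aggregate, upscale, deviate, rank, summarize.

    Parameters
    ----------
    grids : mapping of site name -> reference LandCoverGrid
    flux_tables : one FluxTable for all sites, or a per-site mapping
    ladder_m : coarsening ladder; steps that do not fit a site are dropped
        per site and the per-resolution site count is tracked.
    """
    if isinstance(flux_tables, FluxTable):
        flux_tables = {site: flux_tables for site in grids}

    series_by_site: dict[str, ResolutionSeries] = {}
    curves: dict[str, DeviationCurve] = {}
    fluxes_by_site: dict[str, list[RegionalFlux]] = {}
    aucs: dict[str, float] = {}
    transitions: dict[str, float | None] = {}
    patches: dict[str, PatchStats] = {}

    for site, grid in grids.items():
        series = build_resolution_series(grid, ladder_m, tie_break=tie_break)
        fluxes = [
            regional_flux(g, flux_tables[site], include_lakes=include_lakes)
            for _, g in series
        ]
        curve = deviation_curve(fluxes)
        series_by_site[site] = series
        fluxes_by_site[site] = fluxes
        curves[site] = curve
        aucs[site] = auc_log_trapezoid(curve)
        transitions[site] = detect_sign_transition(fluxes)
        present = [c for c in wetland_classes if c in grid.codebook.values()]
        patches[site] = patch_area_stats(grid, present, connectivity=connectivity)

    ranks = rank_sites(aucs)
    summary = cross_site_summary(
        curves, series_by_site, flux_tables, include_lakes=include_lakes
    )
    pooled = {
        cls: pooled_patch_stats(list(grids.values()), cls, connectivity=connectivity)
        for cls in ("bog", "fen")
        if any(cls in g.codebook.values() for g in grids.values())
    }
    report = ExperimentReport(
        sites={
            site: SiteResult(
                site=site,
                series=series_by_site[site],
                fluxes=fluxes_by_site[site],
                curve=curves[site],
                score=SensitivityScore(site=site, auc=aucs[site], rank=ranks[site]),
                transition_m=transitions[site],
                wetland_patches=patches[site],
            )
            for site in grids
        },
        summary=summary,
        pooled_patches=pooled,
    )
    if output_dir is not None:
        report.write_tables(output_dir)
    return report
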