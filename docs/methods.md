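# Methods

## The model

`ch4scale` treats a regional CH₄ budget as a deterministic function of a
categorical land-cover map and a per-class flux table:

```
FCH4_region = Σᵢ (Aᵢ × FCH4ᵢ) / A_region
```

with `Aᵢ` the area of harmonized class *i* (pixel count × pixel area),
`FCH4ᵢ` its mean plot-scale flux in g C-CH₄ ha⁻¹ h⁻¹ (negative = uptake) and
`A_region` the total non-nodata area. The approach assumes each class has one
representative flux; within-class hydrological or microtopographic
heterogeneity and temporal dynamics are deliberately outside the model.

Resolution sensitivity is probed by recomputing the regional flux on
mode-aggregated versions of the same map and summarizing the drift as

```
deviation_k = 100 × |F_ref − F_k| / |F_ref|           [%]
AUC        = Σ_k ½ (d_k + d_{k+1}) (ln r_{k+1} − ln r_k)
```

The absolute value in the denominator keeps deviation curves nonnegative for
net-sink reference sites. Natural-log spacing makes each multiplicative step
of the ladder count equally in the AUC, so a site's sensitivity score is not
dominated by the huge metric distance between 1250 and 5000 m. Sites are
ranked by descending AUC (1 = most sensitive), ties broken lexicographically
by site label so ranks are always a permutation.

## Aggregation conventions

* Mode (majority) aggregation votes within non-overlapping `f×f` blocks,
  `f = target / native pixel size`, which must be a whole number. Every
  ladder step is aggregated directly from the reference map, never cascaded
  from the previous step.
* Before each step the map is cropped to a multiple of `f`, anchored at the
  top-left origin, so no partial blocks remain at the edges. Ladder steps the
  map cannot hold (less than one block, or a non-integer factor) are dropped
  per site with a logged warning, and cross-site statistics track the number
  of sites present at each resolution.
* Tie-break: the default prefers the smaller integer class code; the
  alternative `largest_area` prefers the class covering more of the native
  map. Whether real products resolve ties deterministically is generally
  undocumented, so the rule is explicit and configurable here. Note that at
  the finest ladder step (factor 2) patches only one or two blocks wide make
  ties common, so the chosen rule imposes a small systematic push — toward
  wet classes under `smallest_code` (wet classes carry low codes), toward the
  dominant dry matrix under `largest_area`. Deviation curves for very
  fragmented landscapes therefore show a deterministic wiggle at the 5 m step
  before the patch-loss regime takes over; monotone-growth checks start at
  the second ladder step for this reason.
* Nodata pixels never vote; a block with at least one valid pixel gets a
  valid class, an all-nodata block stays nodata.

## Flux table and uncertainty

Standard error of the regional flux assumes independent class means and
error-free areas: `SE = sqrt(Σᵢ fᵢ² SEᵢ²)` with `fᵢ` areal fractions. No
areal uncertainty is propagated — the point of the analysis is precisely that
the areas are biased, not noisy.

Open-water classes default to the BAWLD-CH₄ "medium-sized peatland lakes"
constants (median total 63.5 mg CH₄ m⁻² d⁻¹ = 18.4 diffusive + 45.1
ebullitive; quartiles 31.8 and 122.5). Conversion to the class-flux unit
multiplies by `(12.011/16.043) × 10 / 24` (CH₄→C by molar mass, mg m⁻² →
g ha⁻¹, day → hour), giving 19.81 g C-CH₄ ha⁻¹ h⁻¹ for the median. Because
flux syntheses disagree on whether open water belongs in a wetland budget at
all, `include_lakes=False` removes lake pixels from `A_region` entirely
instead of zeroing their flux.

Bog/fen contributions per resolution divide each type's summed positive
emission (contribution rate × site mapped area, summed over sites) by the
summed positive emissions of **all** classes, so uptake classes never deflate
the denominator. With this convention bog + fen proportions only sum to 1
when bogs and fens are the sole emitters (e.g. lake-free synthetic suites);
with emitting lakes present they sum to slightly less.

## Fragmentation metrics

Patches are connected components of same-class pixels; the default
8-neighbor rule matches the common class-metric convention, with 4-neighbor
available. Reported per class: patch count, mean patch area, **population**
standard deviation of patch area (m²), and the division index
`D = 1 − Σⱼ (aⱼ/A)²` where `A` is the total non-nodata landscape area (not
the class area) — `D` is the probability two random points fall in different
patches of the class. Pooled cross-site statistics concatenate patch lists
and use the summed landscape area.

## Synthetic landscapes

The generator is a neutral landscape model: one standard-normal field per
landscape, smoothed by a Gaussian kernel of sigma `correlation_length_px`,
then cut into quantile bands whose widths equal the target class fractions.
Properties that follow by construction: realized fractions match targets to
within pixel rounding; identical config + seed reproduces the raster bit for
bit; larger correlation lengths yield larger patches and lower division
indices. Bands are ordered wet→dry (lake, fen, bog, other wetland, forest,
upland, barren) so wet classes adjoin each other, mimicking zonation down a
moisture gradient.

Defaults emulate high-latitude study conditions: 2.5 m pixels, site extents
of a few km², 5–7 harmonized classes, wetland cover spanning 4–50% across a
suite (median near a third), wetland area split 45% bog / 40% fen / 15%
other wetland, lakes a few percent of the dry remainder. The bundled flux
table generator draws per-seed tables with fens (≈30 g C-CH₄ ha⁻¹ h⁻¹)
above bogs (≈12) above other wetlands (≈6) above zero, weak uptake
(−0.1…−0.5) for barren/forest/upland, ±10% jitter, relative SEs near 40%,
and the converted BAWLD constant for lakes.

What the generator does **not** emulate: anisotropic or curvilinear features
(channels, polygon networks, shorelines), class-dependent patch geometry,
classification error, and spatial autocorrelation structure beyond a single
isotropic scale. Passing tests therefore demonstrate correctness of the
pipeline and the direction/magnitude class of resolution effects on
plausible mosaics, not site-specific numbers for any real landscape.

## Experiment sizes

The default experiment in `scripts/acceptance.py` uses seven 2000×2000
landscapes at 2.5 m (5 km × 5 km each, supporting the full ladder to 5000 m
exactly) with a fragmentation gradient of correlation lengths 1–64 px paired
low-wetland→fragmented, high-wetland→aggregated, and per-site flux tables.
Test-suite experiments use 64–512 px grids, which retain ladder steps up to
their extent. All randomness flows through explicit integer seeds.

## Known limitations

* Percent deviation is undefined for a reference flux of exactly zero; such
  sites raise an error rather than report a curve.
* The top-left crop anchor means very coarse steps can sample an
  unrepresentative corner of a map whose extent is not an exact ladder
  multiple; this mirrors real regridding artifacts but makes the coarsest
  one-block steps sensitive to map layout.
* Reported patch-area SDs are population SDs in m²; comparisons against
  conventions that use sample SD or hectares need rescaling.
* GeoTIFF support covers single-band integer rasters with square pixels; no
  reprojection or CRS interpretation is attempted.
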