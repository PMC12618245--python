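# ch4scale

**How much does the spatial resolution of a land-cover map bias an upscaled
wetland methane budget?**

Bottom-up regional CH₄ budgets for Arctic and boreal landscapes are usually
built by "paint-by-numbers" upscaling: classify the landscape into land-cover
classes, measure a mean chamber flux per class, and take the area-weighted
mean,

```
FCH4_region = Σᵢ (Aᵢ × FCH4ᵢ) / A_region        [g C-CH₄ ha⁻¹ h⁻¹]
```

where `Aᵢ` is the mapped area of class *i* and `FCH4ᵢ` its mean flux
(negative = uptake, positive = emission). The weak link is `Aᵢ`: high-latitude
wetlands are mosaics of fens, bogs and ponds only meters across, while most
available land-cover products have pixels of 30 m to several km. `ch4scale`
quantifies the resulting bias for ecosystem scientists and remote-sensing
practitioners:

- **mode aggregation** — coarsen a categorical raster across a resolution
  ladder (default 5, 10, 25, 50, 100, 250, 500, 1000, 1250, 5000 m) by
  per-block majority vote, the rule coarse land-cover products are built with;
- **flux upscaling** — area-weighted regional FCH₄ ± SE per resolution, with
  lake classes defaulting to the BAWLD-CH₄ medium peatland lake median
  (63.5 mg CH₄ m⁻² d⁻¹ = 18.4 diffusive + 45.1 ebullitive, converted to
  19.81 g C-CH₄ ha⁻¹ h⁻¹);
- **deviation curves and sensitivity ranks** — percent deviation from the
  nominal-resolution flux, `100·|F_ref − F_k|/|F_ref|`, integrated by the
  trapezoidal rule over log-resolution into an AUC score that ranks sites
  from most to least resolution-sensitive, plus detection of spurious
  source→sink transitions;
- **fragmentation metrics** — per-class patch labeling (4- or 8-neighbor),
  landscape division index `D = 1 − Σⱼ(aⱼ/A)²`, and mean/SD of patch area,
  the structural covariates that explain the sensitivity ranks;
- **synthetic landscapes** — a neutral landscape model (smoothed Gaussian
  latent field cut into quantile bands) generating multi-class maps with
  controlled class fractions and patch scale, so the whole pipeline is
  testable without any proprietary site map.

## Worked example

```python
import ch4scale as cs

# a 512² landscape at 2.5 m: 30% wetland in small scattered patches
cfg = cs.SyntheticConfig(
    grid_size=512,
    class_fractions=cs.site_class_fractions(0.30),
    correlation_length_px=2,
    seed=0,
)
grid = cs.generate_landscape(cfg)
table = cs.make_flux_table(seed=0)

series = cs.build_resolution_series(grid)          # 2.5 m … 1250 m
fluxes = [cs.regional_flux(g, table) for _, g in series]
curve = cs.deviation_curve(fluxes)

print([round(f.value, 2) for f in fluxes])
print([round(d, 1) for d in curve.deviation_pct])
print(cs.detect_sign_transition(fluxes))
```

prints

```
[5.82, 6.56, 6.58, 4.37, 1.09, -0.45, -0.45, -0.45, -0.45, -0.45]
[0.0, 12.7, 13.0, 24.9, 81.3, 107.8, 107.8, 107.8, 107.8, 107.8]
100.0
```

The reference flux of 5.82 g C-CH₄ ha⁻¹ h⁻¹ erodes as coarsening swallows the
small emitting patches, deviates by ~80% already at 50 m, and at 100 m the
region flips from net CH₄ source to apparent net sink (the dry classes'
uptake of −0.45 is all that remains once the wetland pixels are voted away).

The same analysis is scriptable from the shell:

```
ch4scale simulate --grid-size 512 --wetland-fraction 0.3 --seed 0 site.asc
ch4scale aggregate --steps 5,10,25,50 site.asc coarse/
ch4scale metrics site.asc
ch4scale run-all --config run.yaml out/
```

`run-all` writes `deviation_curves.csv`, `sensitivity_ranks.csv`,
`cross_site_summary.csv` and `transitions.csv`.

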