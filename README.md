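# mbd — mammographic breast density quantification and spatial analysis

`mbd` measures how much radiodense fibroglandular tissue a mammogram shows
and how that tissue is arranged. It is written for researchers studying
percent density (PD) as a breast-cancer risk factor who need a tested,
reproducible version of the classic thresholding-plus-grid workflow:

1. **ROI** — rasterize breast-contour / pectoral-muscle polygons to a
   breast mask (`mbd.preprocess`), optionally with a linear contrast
   stretch for outlining the skin border.
2. **Segmentation** — split the in-breast grey-level histogram at the
   maximum-entropy (Kapur) threshold `t* = argmax_t [H_low(t) + H_high(t)]`
   and call pixels above it radiodense;
   overall PD = 100 × dense / breast pixels (`mbd.segmentation`).
3. **Regional & zonal PD** — tile the breast bounding box into an 8×6 grid
   of 48 equal sub-regions; zonal PD averages the regional PDs over the
   posterior / middle / anterior column bands (`mbd.regional`).
4. **Spatial pattern** — Moran's I over the 48 regional PDs,

   I = N/ΣΣw_ij · ΣΣ w_ij (x_i−x̄)(x_j−x̄) / Σ(x_i−x̄)²,  w_ij = 1/d_ij²,

   with d the tile-midpoint distance; I > 0 ⇒ clustered, I = 0 ⇒ random,
   I < 0 ⇒ scattered (`mbd.spatial`; rook/queen contiguity schemes
   available).
5. **Cohort statistics** — Pearson age–PD correlation, chi-square
   pattern-by-group tables, Kruskal–Wallis / Friedman / Mann–Whitney zonal
   comparisons, mean regional-PD heatmaps (`mbd.cohort`).

Since clinical archives cannot be bundled, `mbd.phantom` generates
MLO-like synthetic mammograms (curved contour, pectoral cut-out, adipose
background, dense blobs with a controlled total fraction and zonal or
checkerboard placement, Gaussian noise) with exported ground-truth masks,
and whole cohorts with planted age-density and clustering effects — so the
entire pipeline is testable against known truth. See `docs/methods.md` for
the model details and assumptions.

## Worked example

```python
from mbd import PhantomSpec, generate_phantom, analyze_image

spec = PhantomSpec(dense_fraction=0.25, placement="middle", seed=7)
ph = generate_phantom(spec)                      # image + ground-truth masks
a = analyze_image(ph.image, ph.breast_mask)      # full per-image pipeline

print(f"planted dense fraction : {ph.true_dense_fraction:.4f}")
print(f"threshold (Kapur)      : {a.threshold}")
print(f"overall PD             : {a.overall_pd:.2f}%")
print(f"zonal PD (P/M/A)       : {a.zonal.posterior:.2f} / "
      f"{a.zonal.middle:.2f} / {a.zonal.anterior:.2f}")
print(f"Moran's I              : {a.moran.I:.4f} -> {a.moran.pattern}")
```

prints

```
planted dense fraction : 0.2508
threshold (Kapur)      : 97
overall PD             : 27.94%
zonal PD (P/M/A)       : 8.85 / 44.52 / 9.00
Moran's I              : 0.3623 -> clustered
```

The phantom planted 25.1% dense tissue concentrated in the middle zone. The
entropy threshold (97) falls between the adipose (80) and dense (200)
intensity levels; the measured overall PD (27.9%) sits within noise of the
planted fraction, the middle zonal PD (44.5%) dominates the posterior and
anterior zones as planted, and the positive Moran's I classifies the breast
as spatially clustered.

The same workflow is scriptable from the shell: `mbd phantom`,
`mbd preprocess`, `mbd segment`, `mbd grid`, `mbd moran`, `mbd cohort`,
`mbd run --config cfg.json` (see `--help` on each).

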