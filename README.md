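# wellquant

Quantitative image analysis for micropatterned stem-cell differentiation
cultures.

Adherent pancreatic differentiation protocols show spontaneous local
clustering of cells with elevated nuclear PDX1 and NKX6.1 — the earliest
markers of pancreatic and beta-cell commitment.  Confining posterior-foregut
cells on circular cell-adhesive microwells (150–500 µm diameter) directs
this clustering, and the resulting colonies are read out by fluorescence
microscopy: a DAPI nuclear counterstain, a phalloidin F-actin stain, and
two transcription-factor channels.  `wellquant` implements the measurements
such experiments need, for imaging scientists and stem-cell bioengineers:

- **Equal-area concentric zoning.**  A well of radius *R* is split into *K*
  annuli of identical area with boundaries *r·k = R·√(k/K)*; nuclei are
  enumerated per zone and densities reported in cells/mm², so radial cell
  redistribution (clustering toward the centre) is quantified directly.
- **Nuclear and N:C intensity metrics.**  Per-nucleus mean transcription-
  factor intensity over automatically segmented nuclear ROIs (Otsu +
  distance-transform watershed, with profile-aware ROI expansion), the
  nuclear:cytoplasmic ratio N:C = mean nuclear / mean cytoplasmic intensity
  (cytoplasm = actin tissue mask minus nuclear ROIs), and normalisation of
  well nuclear intensities to the surrounding unconfined control monolayer.
  All intensity metrics are computed on background-subtracted channels and
  are invariant under global gain.
- **Radial actin-architecture classification.**  The average intensity
  profile along 8 diameters through the well centre, classified as
  *uniform*, *peripheral* (edge-peaked ring) or *central* (centre-peaked
  cap) by explicit contrast criteria — the signature of the purse-string
  contraction that accompanies colony compaction.
- **High-cell cluster detection.**  Threshold rules for PDX1-high cells and
  single-linkage spatial clustering of their centroids, with convex-hull
  diameter and circularity per cluster.
- **Group statistics.**  One-way ANOVA with Tukey HSD across well
  diameters, Student's t-test for two-group comparisons, star tiers
  (n.s./*/**/***/****), and a confocal-vs-widefield modality-consistency
  control (constant per-cell intensity ratio).
- **A fully ground-truthed synthetic image generator.**  Multi-channel
  microwell colonies and unconfined monolayer fields with known nucleus
  positions, N:C ratios, actin archetypes and cluster memberships, so every
  stage of the pipeline is validated by parameter recovery without any
  external data.

## Worked example

```python
import wellquant as wq

# render a 150 µm microwell colony with a known ground truth
spec = wq.SyntheticWellSpec(well_diameter=150, seed=1, noise_sd=5.0,
                            tf_nc_ratio=(2.0, 1.6), actin_class="central")
image, truth = wq.render_microwell_image(spec)

# run the full measurement path
result = wq.quantify_well(image, truth.well)
print("nuclei in well:", result.n_in_well)
print("zone counts:   ", list(result.zone_summary["count"]))
print("zone densities:", [round(d) for d in
                          result.zone_summary["density_cells_per_mm2"]])
print("PDX1 N:C:      ", round(result.colony_nc["tf1"], 3))
print("normalised:    ", round(result.normalized["tf1"], 3))
print("actin class:   ", result.actin_class.label)
```

Output:

```
nuclei in well: 48
zone counts:    [16, 17, 9, 6]
zone densities: [3622, 3848, 2037, 1358]
PDX1 N:C:       1.983
normalised:     0.996
actin class:    central
```

The nuclei concentrate in the inner zones (equal areas, so counts are
proportional to density — the generator seeded 53 cells and the default
packing lets close neighbours merge into 48 resolved ROIs); the measured
PDX1 nuclear:cytoplasmic ratio recovers the generator's true value of 2.0
within ~1%; the colony's actin is correctly read as centre-concentrated;
and the well's mean nuclear intensity equals the surrounding unconfined
control (ratio ≈ 1), as built.

A cohort run from a single config, with CSV outputs and a manifest:

```sh
wellquant quantify --config configs/demo.yaml
wellquant validate --config configs/demo.yaml   # ground-truth recovery
```

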