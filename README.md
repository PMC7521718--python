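# zonerecon

Spatial reconstruction of liver zonation from single-cell RNA-seq, and the
question of what sequencing design recovers it best.

Hepatocyte gene expression varies continuously along the lobule axis from the
central vein (pericentral) to the portal triad (periportal). Single-cell
RNA-seq protocols differ enormously in how they sample this gradient: a
full-length plate protocol reads few cells very deeply, while droplet/UMI
protocols read many cells shallowly. `zonerecon` implements the complete
comparison pipeline for this setting:

- **Wave-Crest ordering** — reconstructs the 1-D pericentral→periportal axis
  from a panel of known marker genes. Markers are standardized to mean 0 /
  variance 1; cells are placed by an *extended nearest insertion* that puts
  each cell at the gap minimizing the objective
  `sum_g MSE_g(order)`, the total mean squared residual of OLS fits of each
  marker on position 1..n; a 2-opt pass over adjacent exchanges refines the
  order, and the flip freedom is fixed so pericentral markers decrease along
  the axis (position 1 = pericentral).
- **Nine-zone profiles** — ordered cells are split into 9 equally sized
  groups; per-gene group summaries (mean, median, or posterior-weighted
  `Z_ij = Σ_c P(c∈j)x_ic / Σ_c P(c∈j)`) are scaled to [0,1] per gene so
  protocols with different dynamic ranges can be compared by Pearson
  correlation. Zonation calls use a per-gene slope t-test with
  Benjamini–Hochberg adjustment (direction: positive slope = periportal), or
  Kruskal–Wallis across zones.
- **Protocol sensitivity** — per-gene `log2(mean_A⁺/mean_B⁺)` (means over
  nonzero values) regressed on the difference in gene detection fractions;
  the intercept is the experiment-wide log2 sensitivity gain and
  `2^intercept` the fold-sensitivity (an intercept of 3.1 ≈ 9-fold).
- **Cells-vs-depth trade-off** — subsample cells, or thin each cell's counts
  to `round(X·N_c)` by a multinomial with probabilities `counts/N_c`, rebuild
  the scaled profiles, and score
  `MSE = Σ_i Σ_j (Z_ij − Ẑ_ij)² / n_genes` over 500 randomly sampled genes,
  25 replicates per scenario (minimum over the flipped axis when the order is
  recomputed).
- **Synthetic zonated data** — cells with latent positions z ∈ [0,1], genes
  with monotone/peaked/flat mean profiles, log-normal per-cell depths,
  multinomial counts with optional gamma overdispersion, and ERCC-style
  spike-ins, so the whole pipeline is testable end to end with known truth.
  QC filters (≥20% spike-in fraction removal; 200–3,000 genes detected) and
  library-size normalization are included as plumbing.

## Worked example

The numbered drivers under `analysis/` run the full study on simulated
regimes ("deep": 66 cells at mean depth 1e5; "shallow": 606 cells at 5e3,
20-fold less) and print, for example:

```
$ python analysis/01_simulate_protocols.py
deep: 66 cells, median depth 96925, 997 genes detected per cell on average
shallow: 606 cells, median depth 5028, 818 genes detected per cell on average

$ python analysis/02_detection_sensitivity.py
deep: mean cell detection fraction 0.997
shallow: mean cell detection fraction 0.818
sensitivity regression: intercept 4.35 -> 20.4-fold gain over 1000 genes

$ python analysis/03_order_cells.py
deep: Spearman rho vs latent positions = 0.958

$ python analysis/04_zonation_profiles.py
median profile correlation over 83 strongly zonated genes: 0.905
414 genes significantly zonated in all regimes (adj p < .1)
```

The regression intercept of 4.35 recovers the nominal log2 depth ratio
log2(20) ≈ 4.32 — deeper sequencing shows up as a uniform log2 expression
shift at equal detection. The deep regime's reconstructed axis correlates at
ρ ≈ 0.96 with the simulated truth, and the scaled zonation profiles of the
strongly zonated genes agree across the two independently sampled protocols
(median r ≈ 0.9). `analysis/05_tradeoff.py` reproduces the trade-off curves:
profile error grows roughly linearly as cells are dropped at fixed depth, and
sharply as depth falls below ~25% in the shallow regime.

A `zonerecon` console command exposes the same steps
(`simulate`, `qc`, `normalize`, `order`, `profiles`, `compare`,
`sensitivity`, `tradeoff`); run `zonerecon --help`.

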