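# retina-atlas

Statistics for a dual-omic (snRNA + snATAC) atlas of the developing human
retina. The package re-implements, as a tested and reusable pipeline, the
bespoke analyses such an atlas calls for:

* **Maturation scoring** — for each major cell class, each (location, PCW
  group) of developmental cells is scored by the Pearson correlation between
  its mean top-50 principal-component embedding and the adult reference's
  mean embedding, computed on the pooled developmental + adult matrix.
* **Birth-rate curves** — per class (or per inferred progenitor fate), a
  Gaussian fitted by method of moments to member cells' ages, scaled so the
  curve's integral equals the class's cell proportion:
  `curve(t) = p_c · N(t; μ_c, σ_c)` with `Σ_c p_c = 1` per location.
* **Fate-absorption inference** — a cell–cell transition kernel
  `T = 0.8·T_vel + 0.2·T_conn`, where `T_vel` puts softmax(cos(v_i, x_j −
  x_i)/τ) mass on each cell's k nearest neighbors and `T_conn` is the
  row-normalized symmetrized kNN graph; terminal fates are absorbing cell
  sets and per-cell fate probabilities solve `B = (I − Q)⁻¹R` on the
  absorbing Markov chain. Cluster fates are threshold-gated argmaxes.
* **TF fate-specification prediction** — a transcription factor is
  predicted to specify the class whose fated neurogenic progenitors express
  it most; predictions are validated against a curated literature table
  (matched / unmatched / unknown).
* **Latent-time gene modules** — genes correlated with latent time
  (Pearson, BH FDR < 0.05), grouped by average-linkage clustering of the
  gene–gene correlation matrix, with per-cell module scores from a
  single-component PCA of the smoothed module submatrix, and
  expression-weighted gene timing in days.
* **Spatial differential expression** — class markers by the
  overestimated-variance t-test, and a two-stage macula-vs-periphery
  procedure: NB regression (Location; Wald, q < 0.01, |effect| > 1,
  detected in > 2,000 cells) intersected with an NB likelihood-ratio test
  (Location + Age vs Age, q < 0.01).
* **Chromatin procedures** — one-sided Wilcoxon DARs (FDR < 0.01, log2FC >
  1), adult-overlap classification at the inclusive 20% base-coverage rule,
  peak-to-gene linkage (≤ 250 kb from the TSS, Pearson r ≥ 0.45 across
  pseudobulk units), and four-phase chromatin–expression segmentation
  (primed / coupled-on / coupled-off / decoupled) over gene-time grids.

Every stage is driven by a **synthetic atlas generator**
(`retina_atlas.synthetic`) that plants the structure the stages assume —
Gaussian birth ages with a configurable macula lead, NB counts with class
markers, three latent-time modules, fate-biased TFs, location DEGs, linked
peaks, and chromatin trajectories that lead expression — so the whole
pipeline is testable with no download.

## Worked example

```python
import numpy as np
from retina_atlas import (AtlasConfig, generate_atlas, normalize, NormState,
                          estimate_birth_curves, table1_fixture,
                          validate_tf_predictions)

atlas = generate_atlas(AtlasConfig(n_cells=20000, macula_lag_days=14.0, seed=17))
macula = {c.group: c for c in estimate_birth_curves(atlas.cells, location="macula", seed=0)}
periph = {c.group: c for c in estimate_birth_curves(atlas.cells, location="periphery", seed=0)}
for cls in ("RGC", "Cone", "Rod", "MG"):
    print(cls, round(periph[cls].mu - macula[cls].mu, 1))

table = table1_fixture()
print(validate_tf_predictions(dict(zip(table["tf"], table["predicted_class"])), table))
```

prints

```
RGC 13.8
Cone 13.6
Rod 14.4
MG 14.3
{'n_matched': 22, 'n_unmatched': 10, 'n_unknown': 63, 'match_rate': 0.6875}
```

The per-class birth-mean differences recover the planted 14-day macula lead
to within sampling error, and re-deriving the TF validation statuses from
the literature annotation reproduces the 22/32 (68.75%) match rate.

A command-line surface mirrors the library: `retina-atlas simulate`,
`maturation`, `birthrate`, `fate`, `tfpredict`, `modules`, `deg-location`,
`deg-class`, `dars`, `adult-overlap`, `link`, `phases`, `report` (see
`retina-atlas --help`).

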