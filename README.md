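# gliaxis

Analysis toolkit for the glioma–neuron–immune axis: how functional
connectivity between a glioblastoma and surrounding brain relates to regional
immunosuppression. The package provides tested, reusable implementations of
the computational stages such a study chains together, plus seeded synthetic
data generators so every stage can be exercised end-to-end without patient
data.

It is aimed at computational biologists working with single-cell and spatial
(Visium-style) transcriptomics of brain tumors, and with calcium-imaging /
patch-clamp readouts of tumor-adjacent neuronal activity.

## What it computes

**Gene-signature scoring** (`gliaxis.signatures`) — four per-observation
scores for a gene set *S* in a genes × observations matrix *X*:

- *module score*: mean(X[S]) − mean(X[ctrl]), with controls drawn from
  expression-matched bins (24 bins, 100 controls per set gene);
- *AUC*: area under the recovery curve of *S* within the top 5% of each
  observation's expression ranking, scaled to [0, 1];
- *ssGSEA*: Σ over ranks of (weighted in-set ECDF − out-of-set ECDF), with
  in-set weights |rank|^α, α = 0.25;
- *JASMINE*: mean of a min–max-scaled dropout-aware mean-rank component and
  an expression odds-ratio component.

**TAM classification and composition** (`gliaxis.immune`) — a myeloid cell is
Mg-TAM (microglia-derived) or Mo-TAM (monocyte-derived) when the matching
signature score is > 0 *and* strictly higher than the alternative; ties and
double-negatives are undetermined. Regional composition tables are compared
with a two-sided Fisher's exact test (exact for 2×2, fixed-margin Monte Carlo
for 2×K).

**Expression-inferred CNV and spatial gating** (`gliaxis.cnv_spatial`) —
per-chromosome relative copy number from reference-centered, genomically
ordered log expression smoothed by a 51-gene moving average; the CNA index
Σ_chrom |CN − 1| as per-spot burden; tumor-bed masks (polygon or CNA
threshold); and "glioma-neuronal infiltration areas": tumor-bed spots in the
upper 10–30 percentile band of the mesenchymal score and the lower 10–30
percentile band of the neuronal score, with region-restricted
Pearson/Spearman correlations.

**Enrichment** (`gliaxis.enrichment`) — preranked GSEA with the classic
running-sum ES, gene-set permutation null (1000 permutations), NES,
one-sided permutation p with Benjamini–Hochberg correction and leading-edge
extraction; ranked lists from log2 fold changes on CPM; and a simplified
two-part (hurdle) differential-expression analog: binomial LRT on detection
rate + Gaussian LRT on log-expression among detected cells.

**Physiology** (`gliaxis.physiology`) — ΔF/F with a trailing
lower-half-of-10-s-window baseline; template-matching calcium event detection
(difference-of-exponentials library; events require template correlation
> 0.85 and ΔF/F > 0.1); pooled inter-event-interval (IEI) statistics with the
two-sided two-sample Kolmogorov–Smirnov test and Welch's t-test.

**Synthetic data** (`gliaxis.synthetic`) — negative-binomial single-cell
matrices with HFC/LFC region structure, marker panels and sparse TSP1
(THBS1); Visium-like lattices with implanted chromosome-level CNVs (+7/−10
by default) and a rim where synaptic and inflammatory program activations are
anticorrelated (ρ = −0.5 by default); calcium traces; exponential event
trains (group mean IEIs 0.29 s vs 0.51 s by default).

## Worked example

Simulate a spatial dataset, infer copy number, gate the infiltration area and
measure the synaptic/inflammatory anticorrelation inside it:

```python
import numpy as np
from gliaxis.synthetic import SpatialSimConfig, simulate_spatial
from gliaxis.signatures import module_score
from gliaxis.cnv_spatial import (cna_index, infer_cnv, infiltration_gate,
                                 region_correlation, select_reference_spots,
                                 tumor_bed_mask)

ds, annotation, truth = simulate_spatial(SpatialSimConfig(seed=1))
scores = module_score(ds.matrix, truth.programs, seed=0)
reference = select_reference_spots(ds.matrix, annotation)
index = cna_index(infer_cnv(ds.matrix, annotation, reference_obs=reference))
bed = tumor_bed_mask(ds.spots, cna=index, cna_cutoff=float(np.percentile(index, 65)))
gate = infiltration_gate(scores["mes"], scores["synaptic"], bed)
corr = region_correlation(scores["synaptic"], scores["inflammatory"], gate)
print(f"spots: {ds.matrix.n_obs}, infiltration spots: {(gate == 'infiltration').sum()}")
print(f"mean CNA index (core/rim/normal): "
      + "/".join(f"{index[truth.spots.region == r].mean():.2f}"
                 for r in ("core", "rim", "normal")))
print(f"synaptic vs inflammatory in infiltration area: "
      f"r = {corr.r:.3f}, p = {corr.pval:.2e}, n = {corr.n}")
```

prints

```
spots: 2500, infiltration spots: 411
mean CNA index (core/rim/normal): 1.48/1.09/0.64
synaptic vs inflammatory in infiltration area: r = -0.472, p = 3.79e-24, n = 411
```

The tumor core carries the implanted copy-number burden (CNA index 1.48 vs
0.64 in normal tissue), 411 of the 500 true rim spots pass the percentile
gate, and the recovered anticorrelation (−0.47) estimates the simulated
latent ρ = −0.5, slightly attenuated by counting noise in the scores.

A command-line interface mirrors the library
(`gliaxis simulate-spatial | score | cnv | regions | correlate | gsea |
composition | calcium-detect | iei | run`); `gliaxis run --out DIR` executes
the full synthetic pipeline and writes a manifest with every stage's
parameters and outputs.

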