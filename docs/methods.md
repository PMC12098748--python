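# Methods

This note documents the statistical procedures implemented in `gliaxis`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Signature scoring

All four scorers consume a genes × observations `ExpressionMatrix`.
Normalization, where applied, is counts-per-10k followed by log1p.

**Module score.** Genes are binned into `n_bins = 24` equal-occupancy bins by
average expression; for each set gene, `n_ctrl = 100` control genes are
sampled without replacement (seeded) from its bin, *excluding the set's own
genes*; the score is mean(set) − mean(controls). Excluding set genes from the
control pool is a deliberate deviation from the common implementation (which
does not exclude them): it makes the score an exact contrast against
non-signature genes and has negligible numerical effect when bins are well
populated. A set with no genes in the matrix scores NaN with a warning. The
score is invariant to adding a constant to every value.

**AUC score.** Genes are ranked per observation by decreasing expression with
stable (input-order) tie breaking; the score is the area under the
set-recovery step curve within the top `ceil(0.05 · G)` ranks, divided by the
maximal achievable area, hence in [0, 1] and invariant to any within-
observation monotone transform.

**ssGSEA.** Per observation, walking down the decreasing expression ordering,
the score is Σ_positions (P_in − P_out) where P_in weights in-set genes by
(average rank)^α with α = 0.25 and P_out is the uniform ECDF of out-of-set
genes. Ties get average ranks. A set covering every gene scores 0 by
convention (the out-of-set ECDF is undefined).

**JASMINE.** "Expressed" means count > 0. Component A is the mean ascending
rank of expressed set genes among all expressed genes divided by the number
of expressed genes (0 when no set gene is expressed); component B is the
set-vs-rest expression odds ratio with 0.5 added to every cell when any cell
is zero. Both components are min–max scaled across observations (a
degenerate scale maps to 0) and averaged, so scores lie in [0, 1].

**Pseudo-bulk** sums raw counts per group label (e.g., cell type × region ×
patient), giving bulk-like columns scoreable with ssGSEA; `znorm`
standardizes each signature across observations with the sample standard
deviation (a zero-variance signature maps to 0). The AMPA-receptor score is
ssGSEA on the fixed four-gene set Gria1–Gria4.

## TAM classification and compositional tests

The ontogeny rule is intentionally literal: Mg-TAM if score_Mg > 0 and
score_Mg > score_Mo; symmetrically Mo-TAM; everything else — including exact
ties — is undetermined, because the rule requires a *strictly* higher score.
Cluster polarization labeling automates manual curation: per cluster and
marker panel, mean log-normalized panel expression over member cells is
z-scored across clusters; the argmax panel wins when its z exceeds the
runner-up by ≥ 0.25, else the cluster is undetermined. Clustering itself is
upstream and out of scope; labels are supplied.

Fisher's exact test is two-sided by probability ordering. 2×2 tables are
exact (hypergeometric enumeration); 2×K tables use 100,000 seeded
fixed-margin Monte Carlo draws (Patefield sampler) with the Monte Carlo
standard error reported, an unbiased and simple alternative to the network
algorithm.

## Expression-inferred CNV and spatial gating

Copy number is inferred at chromosome level only: per gene, log-normalized
expression is centered by the reference-spot mean; genes are ordered
genomically (declared chromosome order, then start; BED 0-based half-open
intervals); a centered 51-gene moving average smooths each chromosome; the
chromosome's relative CN is 1 + clip(mean smoothed deviation, ±0.5). This is
a deliberate simplification of full segmental CNV callers: downstream use is
a scalar burden index and tumor delineation, so chromosome-level recovery is
the tested contract. The CNA index is Σ_chrom |CN − 1|; it is 0 iff every
chromosome is neutral, and carries a positive noise floor of roughly
Σ_chrom E|mean noise| on real-sized panels — it is a ranking statistic, not a
calibrated ploidy estimate.

When no normal reference is annotated, `select_reference_spots` runs a
two-pass rule: infer CNV against the all-spot average, keep the 30% of spots
with the lowest burden as the diploid reference for the second pass. This
mirrors how expression-CNV tools are anchored in practice.

Tumor-bed masks come either from a polygon in pixel coordinates (validity
checked; boundary points count as inside — a deterministic tie rule) or from
thresholding the CNA index. Infiltration gating selects tumor-bed spots whose
mesenchymal-score percentile rank lies in [70, 90) and whose neuronal-score
percentile rank lies in [10, 30). "Upper 10–30 percentiles" is read as the
stratum *between* the 70th and 90th percentile: the extreme top decile is
tumor core, and the intent of the gate is the rim between core and normal
tissue. Percentile ranks use the midpoint formula 100·(rank − 0.5)/n with
average ranks on ties, computed over all spots; band endpoints and the
all-spots-vs-bed-only convention are configurable since either reading is
defensible. The gate depends only on score orderings, hence is invariant to
monotone transforms.

Region-restricted correlations report Pearson or Spearman r with the
analytic two-sided p, plus an optional seeded permutation p.

## Enrichment and differential expression

Ranked lists order genes by decreasing statistic with stable ties; log2 fold
changes are computed on CPM with a 1-CPM pseudocount. The enrichment score is
the classic running sum (hits add |stat|^p / Σ_set |stat|^p with p = 1,
misses subtract 1/(G − |S|)); the ES is the extremum of maximal absolute
deviation and the leading edge the set genes at or before (positive ES) / at
or after (negative ES) it.

The null is gene-set permutation — `n_perm = 1000` random same-size sets
drawn without replacement — because a preranked input has no phenotype to
permute. The one-sided p is (1 + #{null same sign, at least as extreme}) /
(1 + #{null same sign}); its floor is ≈ 1/(1 + n_perm). This is the simple
permutation estimate rather than an adaptive multilevel sampler; the two
differ only below the floor, where the adaptive scheme keeps resolving and
this implementation saturates. NES = ES / mean |same-sign null ES|.
Benjamini–Hochberg correction runs across all tested sets; size-filtered
sets are reported with a status flag, never silently dropped.

The differential-expression test is a covariate-free two-part analog of the
scRNA-seq hurdle model, and its output labels it as such: part 1 is a 1-df
binomial likelihood-ratio test on the detection rate (degenerate when the
gene is detected in all or no cells); part 2 is a 1-df Gaussian
likelihood-ratio test on log-normalized expression among detected cells
(requires ≥ 2 detected cells per group); the combined statistic is
chi-square with df = number of testable parts. Genes never detected are
flagged untestable. The chi-square reference assumes approximately Gaussian
log-expression among detected cells and is mildly anticonservative at
moderate sample sizes (measured type-I ≈ 0.05–0.07 at α = 0.05 under the
model's own null); it is a screening statistic, not a calibrated replacement
for the full hurdle regression with covariates.

## Calcium events and IEI statistics

ΔF/F at sample t uses the baseline B(t) = mean of the lowest half of the raw
fluorescence in the 10 s strictly *before* t (a transient never pollutes its
own baseline). During warm-up an expanding window of all previous samples is
used; the first sample uses itself (ΔF/F(0) = 0). A non-positive baseline is
treated as invalid input.

The template library holds difference-of-exponentials transients
exp(−t/τ_d) − exp(−t/τ_r) with τ_r ∈ {1, 2} s, τ_d ∈ {2, 4, 8} s (pairs with
τ_d ≤ τ_r excluded), 10 s long, unit peak. Each waveform is additionally
sampled at four sub-sample onset phases (0, ¼, ½, ¾ of the sampling
interval): at 1 Hz the rising edge is undersampled, and a matched filter
without phase diversity rejects well-formed transients whose onset falls
mid-sample. The library is self-defined and replaceable; the contract is the
thresholds, not the exact waveforms.

Detection slides every template along the ΔF/F trace and takes a
time-varying correlation after projecting the constant + linear component
out of both window and template (robust to a preceding transient's decay
tail under the window). Candidates are correlation local maxima > 0.85; the
event peak is the ΔF/F maximum near the matched template's own peak
position, kept when > 0.1; truncated templates (≥ half length) cover onsets
in the final window. Because a transient 3–10 s after another rides on its
neighbour and degrades the match, detection runs two matching-pursuit
passes: fitted templates of accepted events are subtracted and the residual
re-scanned. Events closer than 2 samples are merged keeping the higher
correlation. Rise time is 20→80% of peak amplitude and fall time
peak→50%, linearly interpolated — conventional definitions, exposed as
parameters. Residual misses under the fixed 0.85/0.1 thresholds are bursts
of ≥ 3 closely spaced events and transients starting in the last ~3 s of a
recording.

IEIs are successive event-time differences within each cell, pooled across
cells per group (cells with < 2 events contribute nothing); per-cell mean
IEIs are kept separately for the cell-level comparison. The two-sample K-S
test computes D = sup |ECDF difference| and takes p from the Kolmogorov
distribution at the effective sample size n_a·n_b/(n_a + n_b) (Smirnov's
asymptotic formula). At the sample sizes of interest the exact and
asymptotic p differ only far below any reporting threshold; an underflowing
p is clamped to the smallest positive float rather than reported as 0.
Welch's t-test uses Satterthwaite degrees of freedom.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of their config (same seed, same bytes)
and return a truth bundle sufficient to score every downstream stage.
Counts are negative binomial in the mean/dispersion parameterization, the
standard overdispersion model for UMI data.

**Single cell.** Two label axes per cell — inflammatory polarization
(pro/anti/undetermined) and ontogeny (Mg/Mo/undetermined) — are assigned
independently per region by deterministic largest-remainder apportionment.
Default regional fractions mirror the reported myeloid composition
(pro-inflammatory 41.4% in HFC vs 53.1% in LFC; anti-inflammatory 37.7% vs
22.1%; Mo-TAM 73.4% vs 52.3%; Mg-TAM 20.9% vs 37.6%) at roughly the reported
total cell count (~3,800). A cell expresses the marker panel of each label it
carries at mean 20 vs 0.2 elsewhere: canonical ontogeny markers are
near-binary between the populations they define, and this contrast is what
lets the score-threshold rule recover composition within a couple of
percentage points. Background genes span a log-spaced expression spectrum
(0.05–20), so that module-score control bins are populated by non-marker
genes as in a real transcriptome — with a flat background all marker panels
share the top bins and become each other's controls, which destroys the
score contrast. TSP1 (THBS1) is zero-inflated with a per-polarization
positivity rate. Not emulated: batch effects, doublets, ambient RNA,
continuous polarization gradients.

**Spatial.** A 50×50 square lattice (hex offsets add no tested behavior)
with a circular pure-tumor core (radius 9 ≈ 10% of spots), a flat 50/50
tumor/normal rim annulus (width 6.5 ≈ 20% of spots), and normal tissue. The
tumor archetype expresses the mesenchymal program (8×) and carries the
implanted CNVs as multiplicative mean shifts (defaults chr7 ×1.4, chr10
×0.6, chr1 ×1.25 — the canonical glioblastoma +7/−10 pattern); the normal
archetype expresses the synaptic program (8×). Within the rim, latent
synaptic and inflammatory activations are bivariate standard normal with
correlation ρ (default −0.5), entering gene means as exp(0.5·a); the flat
rim mixture makes within-rim score variation purely latent, so the
region-restricted correlation estimates ρ without a radial-gradient
confound. The geometry places the rim in the upper 10–30 percentile stratum
of the mesenchymal score, which is exactly the regime the percentile gate
assumes. Recovered r is attenuated a few percent below |ρ| by counting noise
in the scores. Programs are spread evenly across chromosomes so archetype
expression differences dilute into the 60-gene chromosome windows rather
than mimicking focal CNVs. Not emulated: spatial spillover, H&E images,
sub-clonal CNV heterogeneity, within-region archetype gradients.

A note on evaluating CNA rank recovery: truth tumor fraction takes only
three values (1, 0.5, 0) and ~70% of spots are normal, so the tied-rank
ceiling caps the all-spot Spearman near 0.81 even under perfect separation.
Rank recovery is therefore evaluated on a class-balanced subsample of ~500
spots (ceiling ≈ 0.94; measured ≈ 0.86).

**Calcium.** Traces are baseline × (1 + slow sinusoidal drift + Σ events +
Gaussian noise), with difference-of-exponentials kernels (τ_r = 1 s,
τ_d = 4 s), Poisson event times (default 0.02 Hz), log-normal amplitudes
(median 0.5 ΔF/F), 5-min recordings at 1 Hz. Event detection is measured
against exact truth peak times. Not emulated: photobleaching, movement
artifacts, overlapping ROIs, non-stationary firing.

**Event trains.** Per-cell exponential inter-event intervals with group
means 0.29 s and 0.51 s by default (the reported group means), event counts
Poisson-consistent with the recording duration.

## Problem sizes and numerical conventions

The acceptance script and test suite run at the study-default condition
sizes: 100 lattices for correlation recovery, 10 seeds for gating overlap
and event detection, 500 replicates for null calibration, 100 simulations
for the K-S power check at the published event counts (2938 vs 1315), each
completing in seconds to tens of seconds on one CPU. Tie-breaks are
deterministic everywhere (stable sorts, average ranks, documented boundary
rules); every stochastic routine takes an explicit seed; percentile-band
endpoints, detection thresholds, window sizes and clip limits are exposed as
parameters with the defaults stated above.

## Known limitations

- CNV inference is chromosome-level only and its index has a noise floor;
  arm-level or segmental events are out of scope.
- The hurdle analog fits no covariates (e.g., cellular detection rate) and
  is mildly anticonservative; use it for ranking and screening.
- The GSEA p saturates at the permutation floor 1/(1 + n_perm).
- Passing recovery tests on synthetic data shows the implementations are
  faithful to their definitions under the generators' assumptions; real
  tissue adds structure (spillover, continuous mixtures, batch effects) that
  the generators deliberately omit.
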