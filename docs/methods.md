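# Methods

`medsift` implements the statistical pipeline used to analyze a pooled
CRISPR knockout screen read out by a *Spry4* transcriptional reporter, and to
characterize how a *Med12*-mutant mESC line differs from wild type in its
transcriptional response to differentiation. This note describes each model
and procedure, its assumptions, the tunable parameters that matter, and the
numerical choices made where the design was open.

## Screen scoring (alpha-RRA)

**Model.** Guides are ranked by log2 enrichment of a sorted gate over the
unsorted library. If a gene's guides behave like random draws from the
library, their percentile ranks are i.i.d. uniform. The gene score is

    rho = min_{k : u_(k) <= alpha}  P( Beta(k, n-k+1) <= u_(k) ),

the tail probability that the k-th order statistic of n uniforms falls at or
below the observed k-th guide percentile. Only guides with percentile at or
below `alpha` participate; a gene with no participating guide scores 1.

**Parameters.**

- `alpha` (default 0.25): the participation cutoff. Permissive enough that a
  4-guide gene with one weak guide keeps power; sweeping alpha in the unit
  tests confirms the truncated and untruncated scores agree on the worked
  order-statistic cases.
- `pseudocount` (default 1, both columns): symmetric stabilization of the
  log2 fold change at low counts.
- `n_perm` (default 1000, floor 100): permutation p-values use the
  (1 + #{null <= obs}) / (1 + n_perm) estimator so no p-value is zero. Null
  scores resample guide percentiles without replacement from the full
  observed pool (controls included), one null distribution per distinct
  guide count.

Normalization rescales every sample column to the mean of the original
column totals ("total" normalization). Ranks break ties by row order, which
makes reruns byte-identical. Gene-level fold change is the mean over guides
passing alpha, falling back to the mean over all of the gene's guides when
none pass.

**Hit rule.** A gene is a hit if its BH-adjusted permutation FDR is <= 0.05
in at least one condition, or <= 0.2 in at least two of the four conditions
(two gate fractions x two sort days per direction). Genes absent from a
condition count as FDR 1 there.

## Differential expression contract and single-cell rules

Downstream statistics consume only (log2fc, padj) per gene, so the DE stage
is deliberately minimal: mean log2(x+1) difference, Welch's t-test, BH
adjustment. It is antisymmetric under contrast swap and is not intended to
reproduce a count-model DE method's p-values.

Single-cell QC follows strict removal semantics: barcodes with <= 2500
detected genes or >= 15% mitochondrial counts are removed (boundaries
removed, not kept). Normalization is counts / cell total x 10,000, then
log1p; marker testing is a rank-sum test restricted to genes whose group
mean log1p difference is at least 0.5, BH-adjusted over exactly the tested
genes. Mitochondrial fraction is computed from counts (whether the original
analysis used reads or UMIs is not determinable; counts are the container's
native unit here).

## Signaling footprints

A pathway footprint is a 50-gene target set together with the expression
delta (knockout - wild type after 24 h of differentiation, log2 scale) of
the knockout that defines the pathway. For a query mutant delta vector:

- activity `a_P` = sum of query deltas over the footprint genes / sum of
  defining deltas. Linear in the query; exactly 1 for the defining knockout
  itself. The denominator must be bounded away from zero — a coherent
  directional footprint guarantees this; a zero-sum footprint is rejected as
  degenerate.
- correlation `rho_P` = Spearman correlation between query and defining
  deltas (average ranks on ties; undefined for constant vectors, reported
  missing).

Batch correction subtracts the batch's wild-type delta from the query before
scoring — the minimal interpretation of using wild-type conditions for batch
correction, and the one the tests pin down ("expression fold changes" is
read as log-scale change, consistent with the rest of the pipeline).

## Differentiation delay

The expression change of a naive marker panel (Prdm14, Tfcp2l1, Klf4, Tbx3,
Nanog, Zfp42, Esrrb) between pluripotency (2i) and 24 h of differentiation
is compared with the change-to-time-t of a reference differentiation time
course. "Normalized Euclidean distance" is realized as: linear interpolation
of the reference onto a 0.1 h grid; per-marker standardization by the
standard deviation of that marker's reference change course; Euclidean norm
divided by sqrt(#markers); min-max rescaling of the curve to [0, 1] for
plotting. Each ingredient is a monotone transform, so the argmin — the only
thing the estimate uses — is unaffected. The signed delay is
`delta = t* - 24 h`; a sample that has progressed less far than nominal
yields a negative delta (a mutant planted to lag by 6 h reads the reference
at 18 h and recovers delta = -6 h). Ties take the earliest grid point; flat
reference markers are dropped with a warning.

## Slopes of regulation and ratio modes

Slopes are `s_g = (mutant log2 change) / (wild-type log2 change)` over
differentiation, for the marker panel or the 100 genes with the strongest
negative/positive wild-type fold change. Orientation is mutant over wild
type so that a globally attenuated mutant response gives slopes below one.
Genes with |wild-type change| <= 0.1 log2 units are excluded (ratio
unstable) and reported.

Fold-change ratios for the stimulation experiment are computed on the linear
scale, `r_g = 2^(log2fc_mut - log2fc_wt)`, over a signed target set
(|log2fc| > 1, padj < 0.05 in the wild type). The mode is the argmax of a
Gaussian KDE with Silverman bandwidth on a 512-point grid spanning the ratio
range; this orientation and scale make an attenuated mutant concentrate
above 1 for downregulated and below 1 for upregulated targets.

## Fate prediction and genotype gating

Induction traces (one frame per 10 min) are smoothed with a centered 7-frame
rolling average; edges use shrinking windows rather than padding. The
default scalar feature is the smoothed-trace maximum (the natural summary of
a rise-and-fall induction trace); the end-of-induction value is available as
an alternative. ROC analysis scans all distinct feature values as
thresholds with the rule "positive when feature > threshold"; AUC is the
trapezoidal area (identical to the rank-sum statistic U/(n1 n2), asserted in
tests), and the operating point maximizes Youden's J = sensitivity +
specificity - 1, taking the lowest threshold on ties.

Genotype gating fits a two-component Gaussian mixture to log10 fluorescence
intensity (intensities are multiplicative, hence the log) by EM: means
initialized at the 25th/75th percentiles, variances at the pooled variance,
weights at 1/2; convergence tolerance 1e-8 on the mean log-likelihood, at
most 500 iterations; vanishing variance raises with diagnostics. The EM is
deterministic from this initialization. A cell is assigned to its
max-posterior component only if that posterior reaches 0.85; cells between
the populations stay unassigned.

## Colony counting and cell classification

Colony counting: Gaussian high-pass background subtraction at a scale of
10x the largest accepted colony radius (capped at a quarter of the image's
short side so boundary artifacts of the big blur stay out of the interior),
Gaussian blur (`blur_sigma`, default 2 px), Otsu threshold, 8-connected
components, then area and circularity filters. Circularity is 4*pi*A/P^2
with the Crofton perimeter estimate, clamped at 1 (the estimator slightly
overshoots on smooth rasterized shapes). Because Otsu always returns a
split, the foreground is accepted only when the split explains at least 75%
of the image variance (between-class over total); colony-free noise fields
sit near 0.6, real wells above 0.8. Size/circularity cutoffs are
configuration, not claimed defaults. Counts are normalized to the mean of a
control condition.

Cell classification drops nuclei under 40 square microns, thresholds each
channel, and maps the signature to Epi (NANOG+ SOX17-), PrE (NANOG- SOX17+)
or other; proportions are reported per replicate with mean +/- s.e.m. An
automatic threshold suggester locates the deepest KDE density minimum
between the two strongest modes (modes below 10% of the peak density are
ignored as tail wiggles) and falls back to Otsu, flagged, on unimodal input.

## Synthetic data: what it emulates and what it does not

All inputs can be generated with planted ground truth:

- **Screen**: each cell's reporter log-intensity is a single Gaussian,
  `Normal(effect_g * sd, sd)`; a gate keeps the population tail fraction, so
  per-guide selection probabilities have closed form and tail sorting has an
  analytic enrichment oracle. Library skew is lognormal
  (`library_dispersion`, default 0.3); counts are multinomial at the stated
  depth (default 1e6). Defaults of 4 guides/gene and 1000 non-targeting
  controls are library conventions. Not emulated: read-level errors, UMI
  chemistry, guide-efficiency heterogeneity, fitness effects of knockouts.
- **Reference time course**: per-marker monotone sigmoidal decay
  `L0 / (1 + (r t)^2)` — flat shoulder at t = 0, half-decline at t = 1/r, so
  doubling the rate halves the half-time (used as an analytic test oracle).
- **Bulk expression**: log2-scale construction in which the mutant's fold
  change over differentiation is `attenuation x` the wild type's, naive
  markers read the reference course at `24 - delay_h` for the mutant, and
  pathway footprint genes are offset by `activity x` the defining delta.
  The generator's fold-change tables are computed from replicate means of
  log2 expression *without* a pseudocount, so at noise_sd = 0 every
  downstream estimator (delay, slope, activity) recovers its planted value
  to machine precision — the central testability invariant. Defining deltas
  are drawn `Normal(1.0, 1.5)` per gene: coherent directional shifts, which
  keeps the activity denominator away from zero. Not emulated: count noise,
  library-size effects, batch structure beyond a single wild-type baseline.
- **Traces**: Gaussian-bump rise-and-fall intensities; fate is PrE iff the
  noise-free peak strictly exceeds the threshold (a peak exactly at the
  threshold is non-PrE by convention).
- **Mixtures**: two lognormal intensity components with retained labels.
- **Colony images**: non-overlapping disks or ellipses (rejection-sampled
  placement; overlap would make the truth count ill-defined) on a noisy
  background with optional linear gradient; ellipse circularity uses
  Ramanujan's perimeter approximation as the truth value.

Passing tests on these generators demonstrates correctness of the
estimators under their stated models, not robustness to everything real
data does (overdispersion, segmentation errors, tracking mistakes,
batch effects).

## Problem sizes and seeds

The test suite and the acceptance script use: screens of 500 genes x 4
guides + 1000 controls at depth 1e6 with 1000 permutations (3 seeds);
bulk datasets with 3 replicates and 400-2000 background genes; 150-cell
trace sets; 3000-cells-per-component mixtures; 20 colony images. These
sizes keep every recovery property measurable (binomial standard errors
small enough for 3-sigma checks) while a full run completes in well under
a minute per stage. Every stochastic step takes an explicit seed, and all
generators are bit-reproducible under it.

## Known limitations

- The permutation null resamples from the observed percentile pool, which
  includes truly enriched guides; with many strong hits the null is slightly
  conservative.
- The DE contract's Welch test on log2(x+1) is a stand-in sufficient for
  the downstream (log2fc, padj) consumers; it is not a count model.
- The sum-ratio pathway activity is unstable for footprints whose defining
  deltas nearly cancel; such footprints are rejected rather than scored.
- The KDE mode estimator's grid spans the observed ratio range; with fewer
  than ~10 genes the mode is unstable and the function refuses to estimate.
- EM for the two-component mixture is deterministic from percentile
  initialization; heavily overlapping components (< ~1.5 sd separation) can
  converge to a single-component-like solution, surfaced by the degeneracy
  diagnostics.
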