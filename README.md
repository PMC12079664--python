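# medsift

Statistics for a pooled CRISPR screen read out by a *Spry4* (Sprouty4)
transcriptional reporter, and for characterizing how a *Med12*-mutant mouse
embryonic stem cell line differs from wild type as it exits naive
pluripotency.

## Who this is for

Groups analyzing FACS-sorted pooled CRISPR screens (guide counts from sorted
tails vs an unsorted reference) and bulk/single-cell RNA-seq of
differentiation time courses, who need the screen's gene-level scoring, the
mutant-characterization statistics, and the imaging quantifications in one
tested, scriptable package. Every input can also be simulated with planted
ground truth, so the full pipeline is testable without any external data.

## What it computes

- **Screen scoring** (`medsift.screen_scoring`). Total-count normalization;
  per-guide log2 fold change of a sorted gate over the unsorted reference;
  alpha-RRA gene scores — for a gene whose n guides have library-wide
  percentiles u₍₁₎ ≤ … ≤ u₍ₙ₎,

      ρ = min over {k : u₍ₖ₎ ≤ α} of  P( Beta(k, n−k+1) ≤ u₍ₖ₎ ),

  the probability that the k-th order statistic of n uniforms is at most the
  observed percentile; permutation p-values with Benjamini–Hochberg FDR; and
  the compound hit rule *FDR ≤ 0.05 in ≥ 1 condition, or FDR ≤ 0.2 in ≥ 2
  conditions*.
- **Expression statistics** (`medsift.expression_stats`). A minimal
  differential-expression contract (Welch test on log2(x+1), BH), signed
  target-set definition (|log2FC| > 1, padj < 0.05), and the single-cell QC
  rules: remove barcodes with ≤ 2500 detected genes or ≥ 15% mitochondrial
  counts, normalize to 10,000 counts per cell, log1p, and rank-sum marker
  tests gated on a minimum log1p difference of 0.5.
- **Signaling footprints** (`medsift.footprint`). Pathway activity
  a_P = Σ Δ_query / Σ Δ_defining over a 50-gene footprint set, and the
  Spearman correlation of the query against the pathway-defining knockout,
  with wild-type-based batch correction.
- **Differentiation dynamics** (`medsift.dynamics`). Delay estimation: the
  naive-marker change vector (Prdm14, Tfcp2l1, Klf4, Tbx3, Nanog, Zfp42,
  Esrrb) is matched against a reference time course by normalized Euclidean
  distance on a 0.1 h grid, giving a signed delay δ = t* − 24 h. Slopes of
  regulation s_g = Δ_mut/Δ_wt for the top-100 regulated genes, and the KDE
  mode of linear-scale fold-change ratios r_g = 2^(log2FC_mut − log2FC_wt).
- **Fate prediction** (`medsift.fate_prediction`). 7-frame rolling-average
  trace smoothing, peak features, ROC with the Youden-J optimal threshold
  (AUC ≡ rank-sum U/(n₁n₂)), and two-component Gaussian-mixture genotype
  gating on log10 intensity with a ≥ 0.85 posterior assignment rule.
- **Image quantification** (`medsift.image_quant`). Colony counting
  (background subtraction → blur → Otsu → connected components → area and
  4πA/P² circularity filters, normalized to control), and intensity-threshold
  cell classification with a 40 µm² nuclear-area floor.
- **Synthetic data** (`medsift.synthetic_data`). Generators for all of the
  above with planted ground truth and closed-form oracles (Gaussian tail
  enrichment, sigmoid half-times, mixture overlap integrals, Ramanujan
  ellipse circularity).

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Score a small simulated screen with two planted negative regulators
(reporter effect −2 sd among 100 genes), then estimate a mutant's
differentiation delay and regulation slopes:

```python
import numpy as np
from medsift import synthetic_data as sd, screen_scoring as ss, dynamics as dyn

truth = sd.ScreenTruth(n_genes=100, n_controls=200, depth=500_000,
                       effect={"gene0000": -2.0, "gene0001": -2.0}, seed=1)
ds = sd.simulate_screen(truth)
fdr = {}
for i, gate in enumerate(ds.gate_columns):
    scored = ss.score_condition(ds.counts, gate, n_perm=1000, seed=10 + i)
    fdr[gate] = scored["fdr"]
hits = ss.select_hits(fdr)
print(hits[hits["is_hit"]].round(4))

markers = {m: l for m, l in zip(dyn.NAIVE_MARKERS, [8, 7.5, 9, 6.5, 8.5, 7, 8.2])}
rates = {m: r for m, r in zip(dyn.NAIVE_MARKERS, [0.05, 0.07, 0.09, 0.11, 0.13, 0.15, 0.17])}
ref = sd.simulate_reference_timecourse(markers, 36, 2, rates)
bulk = sd.simulate_bulk_expression(
    sd.ExpressionTruth(attenuation=0.5, delay_h=6.0, noise_sd=0.05, seed=2), ref)
change = dyn.marker_change(bulk.mut, bulk.metadata.loc[bulk.mut.columns], "2i", "N2B27_24h")
est = dyn.estimate_delay(change, ref)
print(f"delay delta = {est.delta_h:+.1f} h (t* = {est.t_star:.1f} h)")
slopes = dyn.regulation_slopes(bulk.wt_fc, bulk.mut_fc, "top_down")
print(f"slope median = {slopes.median:.3f} over {len(slopes.slopes)} genes")
```

Output:

```
          low_0.01_6  low_0.05_6  low_0.01_9  low_0.05_9  is_hit
gene
gene0000        0.05        0.05        0.05        0.05    True
gene0001        0.05        0.05        0.05        0.05    True
delay delta = -6.1 h (t* = 17.9 h)
slope median = 0.504 over 100 genes
```

Exactly the two planted regulators are recovered as hits (FDR 0.05 in every
gate), the mutant planted to lag differentiation by 6 h matches the
reference time course best at t* ≈ 18 h (δ ≈ −6 h), and a mutant whose
responses are globally attenuated to half strength shows a slope
distribution centered at 0.5.

A command-line surface wraps the same stages
(`medsift simulate|screen|footprint|dynamics|fate|colonies|classify`); each
run writes its outputs together with a manifest recording inputs, parameters
and seed.

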