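# Methods

## Pathway activity model

The scorer implements knowledge-based pathway activity inference: each
pathway is represented by a two-layer Bayesian network whose hidden binary
root is the state of the pathway's transcription complex and whose leaves
are binary "target up / not up" nodes, one per direct transcription-factor
target gene, conditionally independent given the root. Measured log2
expression enters as virtual (soft) evidence on the leaf nodes. With this
structure, exact posterior inference factorizes into a sum of per-gene
log2 likelihood ratios, i.e. weighted naive-Bayes log-odds; the test suite
verifies the factorized computation against brute-force joint enumeration
over all hidden-state configurations (networks up to 8 targets, agreement
to 1e-9).

Assumptions worth stating explicitly:

- **Conditional independence of targets given pathway state.** Real target
  genes share co-regulation beyond the pathway; the model ignores it, as
  naive-Bayes scorers do.
- **Soft evidence via a logistic transform.** `p_g = σ(d_g (e_g − θ_g) /
  s_g)`. The transform is monotone in direction-adjusted expression, hits
  0.5 exactly at the midpoint and saturates smoothly; the discretization
  scale is a modelling choice, not a measured quantity.
- **Evidence weights** `w_g > 0` multiply a gene's log-likelihood-ratio
  contribution. Setting `w_g = 0` is exactly equivalent to removing the
  gene (tested). Weights other than 1 break the strict probabilistic
  semantics (they act as tempered likelihoods); the default is 1.
- **Prior odds 1:1** (`L_prior = 0`) unless configured otherwise.

### Calibration

Calibration uses ground-truth samples with known high/low pathway state
(at least 2 per class; in practice 50/50 in all shipped configurations):

- midpoint `θ_g` = midpoint of the two class means;
- scale `s_g` = pooled within-class SD / 2, floored at 0.05 log2 units so
  that near-degenerate training data cannot produce a step function;
- `a_g`, `b_g` = Laplace-smoothed (pseudocount α = 1) fractions of
  active/inactive samples falling on the active side of the midpoint;
- genes calibrating to `a_g ≤ b_g` are retained but **neutralized**
  (contribution identically 0) rather than direction-flipped: directions
  are literature priors, and silently flipping one would mask label or
  annotation errors.

### Normalization

Scores are `100 (L − L_min) / (L_max − L_min)` clipped to [0, 100], with
`L_min`/`L_max` the model's analytically attainable log-odds extremes
(all-evidence-0 / all-evidence-1 over informative targets). Anchoring to
the attainable extremes, rather than to an observed calibration range,
makes 0 and 100 reachable (a saturated input scores exactly 100, tested
bit-exactly) and keeps scores comparable across datasets scored by the
same model. Cross-dataset comparability of *data* is never assumed; it is
checked empirically with the reference-pathway test (below).

### PI3K interpretation

FOXO transcription-factor activity is an inverse readout of PI3K
signalling, confounded by oxidative stress, which activates FOXO
independently. Per sample: FOXO counts as high when its score exceeds the
control-group median by τ_foxo (default 5 score units); SOD2 counts as
high when its log2 expression exceeds the control median by τ_sod2
(default 0.5). High FOXO + high SOD2 → `UNINTERPRETABLE_OXIDATIVE_STRESS`;
high FOXO + low SOD2 → `PI3K_INACTIVE`; low FOXO → `PI3K_ACTIVE`. The two
thresholds are package defaults (no published cutoffs exist for "high")
and are configurable.

## Deconvolution

Bulk mRNA mixes additively on the linear intensity scale, so fractions are
estimated on anti-logged data (`2^x − 1`, the inverse of the reader's
`log2(x+1)` option) by non-negative least squares on a system augmented
with a sum-to-one penalty row of weight λ (default 100 × the mean column
norm of the signature — effectively a hard constraint on a well-scaled
problem). Numerical choices:

- the bulk is first normalized by its unconstrained-NNLS mass, which makes
  the estimate exactly invariant to positive rescaling of the input
  (tested); the reported residual norm is computed on the original,
  unaugmented system at the full-mass solution;
- NNLS components below 1e-12 of the maximum are snapped to exact zero
  before the final renormalization, so pure samples recover fractions of
  exactly 1 and 0;
- rank-deficient signatures are rejected with the collinear columns named;
  condition numbers above 1e4 are flagged.

Top-level lineages default to {epithelial, fibroblast, immune}; immune
subsets to {granulocyte, monocyte_macrophage, T_cell, B_cell, NK}, with
subset estimates scaled by the top-level immune fraction. Both levels are
set entirely by the supplied signature matrices, and the bundled marker
lists are synthetic defaults, not curated biology.

## Microarray QC

QC runs on plain probe-level tables (probe id, probeset, chip x/y, 5′→3′
position, intensity, control class), not on vendor binaries. Metrics:
overall mean intensity; counts of negative and >65535 (16-bit saturated)
intensities; strict concentration-order checks of the poly-A (lys < phe <
thr < dap) and hybridization (bioB < bioC < bioD < cre) spike-in families;
GAPDH and ACTB 3′/5′ mean-intensity ratios; Cmoff — the intensity-weighted
centroid of the negative-control probes, reported as distance from chip
center over half the chip diagonal (0 = perfectly centered, 1 = corner),
our concrete reading of "equal spatial distribution of negative controls";
positive-vs-negative border control separation; and an RNA degradation
slope, the OLS slope of mean intensity against probe position over all
non-control probesets (shift-invariant, linearly scaling — a simpler
statistic than the standardized shift/scale some reference tools report,
with the same fault sensitivity).

Published parameter lists give no numeric cutoffs, so the defaults are
package conventions, all configurable: mean intensity in [50, 20000];
no negative or saturated values; strict spike-in order; GAPDH 3′/5′ ≤
1.25, ACTB ≤ 3.0; Cmoff ≤ 0.15; border positives above border-negative
mean + 3 SD; degradation slope |slope| ≤ 5 (single-sample mode) or > 3
MAD from the cohort median (cohort mode). Any criterion can be waived per
dataset with a mandatory non-empty reason, recorded in the report — the
mechanism for keeping an otherwise valuable dataset that reproducibly
fails one spatial criterion, with the waiver auditable downstream.

## Statistics

- **Mann–Whitney U** (unpaired) and **Wilcoxon signed-rank** (paired),
  both two-sided with midrank tie handling. Exact p-values are computed
  whenever the enumeration budget permits (C(n+m, n) ≤ 2×10⁶ for the U
  test; n ≤ 25 informative pairs for the signed-rank test) via a
  generating-function dynamic program over integer-doubled midranks —
  mathematically identical to full enumeration of group assignments /
  sign patterns, and verified against itertools enumeration oracles in the
  tests. Beyond the budget, the tie- and continuity-corrected normal
  approximation is used and labelled as such.
- Zero paired differences are dropped (signed-rank convention) with the
  count logged; an all-zero input is an error.
- **Correlations** are Spearman (Pearson on midranks) or Pearson with
  t-approximation p-values, delegated to scipy.
- **Comparison tables** apply the flat per-test convention: significant at
  p ≤ 0.01, annotated at p ≤ 0.05, no multiple-testing correction across
  the twelve pathways; an optional Holm adjustment flag exists and is off
  by default.
- **Reference-pathway comparability**: two datasets are directly
  comparable when a disease-stable reference pathway (estrogen receptor by
  default) shows Mann–Whitney p > 0.05 and |median difference| < 5 score
  units between them. The pipeline annotates, never blocks, cross-dataset
  comparisons that fail the check.
- **Ranked paired tables** sort pairs by descending tumor score of the
  ranking pathway; ties break stably by pair id (a package convention —
  the worked example contains no ties).

## Synthetic data

The generators are the package's validation instrument, emulating the
structure of mixed-composition Affymetrix cohorts:

- per-compartment log2 profiles with pathway-driven target shifts
  (tumor epithelium: MAPK, STAT3, Wnt, Notch, TGFβ; fibroblasts: TGFβ,
  HH, NFκB; immune: NFκB, interferon-driven STAT1/2 — qualitative
  assumptions, not measurements);
- compositions from Dirichlet priors (default (4, 5, 1) over epithelial /
  fibroblast / immune, matching reported PDAC ranges of roughly 33–45%
  epithelium, 45–60% fibroblast, 5–10% immune), paired designs sharing
  correlated compositions, cell lines exactly (1, 0, 0);
- linear-scale mixing, `log2(x+1)` transform, i.i.d. Gaussian log2 noise
  (σ = 0.3 default);
- MKI67 coupled to the tumor-epithelial MAPK signal (κ = 0.8) and a latent
  per-sample oxidative-stress Bernoulli (p = 0.3 in tissue, 0 in cell
  lines) jointly shifting FOXO targets and SOD2 — reproducing the
  confound that motivates the PI3K interpretation rule;
- probe-level chips (11 probes per probeset, exponential 5′ decay, 1.5×
  spike-in steps, mirrored negative-control pairs centred on the chip)
  with five targeted fault injectors, each constructed to flip exactly one
  QC criterion.

What the generator does **not** emulate: probe-sequence effects, batch
effects between datasets, real GPL570 annotation, correlated gene-gene
noise, or realistic marker biology. Passing recovery tests therefore
demonstrates internal consistency of the pipeline under its own generative
assumptions, not performance on real tumor data.

Default problem sizes in the shipped tests: 25 targets per pathway,
calibration at 50/50 samples with shift 2σ, cohorts of 16 tumor/adjacent
pairs over ~1500 genes, 200-sample deconvolution noise sweeps, 1000 null
permutations for the type-I check, and 100 seeded replicates of the
end-to-end calibrate → score → compare chain.

## Pipeline

One flat YAML config drives read → QC → calibrate/score → PI3K
interpretation → deconvolution → comparisons/correlations → report.
Unknown config keys are fail-fast errors. Samples failing QC without a
waiver are excluded before scoring and listed in `summary.json`. Bundles
are written to a temporary sibling directory and moved into place
atomically; with an identical config the bundle is byte-identical across
runs (the run log records steps, not wall-clock times, for this reason).
`summary.json` carries the config hash, seed, package version and a
sha256 per output file.

## Known limitations

- Conditional probabilities, target lists and weights of validated
  commercial pathway models are proprietary; this package provides the
  framework and calibrates on user-supplied or synthetic ground truth, so
  absolute scores are not comparable to any commercial implementation.
- Gene-level input only; probeset collapse (`max_mean` or `mean`) is
  provided but the choice of summarization upstream is the user's.
- The deconvolution is marker-based and RNA-level; RNA fractions need not
  equal cell-count or protein-level fractions.
- Exact-test p-values are conditional on the observed tie pattern, the
  standard convention for rank tests with midranks.
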