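# Methods

`mirmod` implements an integrated mRNA–miRNA analysis for case/control
cohorts profiled on expression arrays (genes) and by small RNA-seq (miRNA
counts): weighted coexpression modules with eigengenes, module preservation
between cohorts, a permutation screen for miRNAs negatively coupled to
disease modules, seed-based target prediction with inverse-correlation
filtering, and eigengene-based prediction of therapy response. Because the
pipeline's statistical behaviour is the object of interest, everything is
exercised on synthetic cohorts with planted ground truth.

## Synthetic cohorts

The generator (`mirmod.simulate`) uses a latent-factor model. Each module
`m` has an i.i.d. standard-normal per-sample factor `f_m(s)`; a disease
module's factor mean is shifted by `factor_shift` (in factor SD units) in
cases. A gene `g` in module `m` is

```
x_gs = a_g · f_m(s) + ε_gs,   a_g ~ U(loading_range),  ε ~ N(0, noise_sd²),
```

plus a per-gene baseline that no correlation statistic sees. Background
genes are independent unit-normal noise. The implied intra-module
correlation for loadings `a` and noise SD `σ` is `a²/(a² + σ²)` — with the
defaults (loadings 0.7–0.9, σ = 0.6) about 0.64, a strongly coexpressed
module; this closed form is what the generator tests check against.

miRNA counts are negative binomial (gamma–Poisson, one shared dispersion,
default 0.1) with mean `cpm_i/1e6 · L_s` for library size `L_s` drawn
uniformly from 8.5–11 million reads (emulating ~10M-read miRNA libraries).
Relative abundances are log-uniform between 0.05 and 5000 (then rescaled so
cpm sums to 1e6), giving a realistic spread from sub-cpm species to
highly-abundant ones. A planted regulator multiplies its mean by
`exp(coupling · f_m(s))` with `coupling < 0` (default −0.8), so its
normalized abundance falls as module activity rises — this is the effect
the permutation screen must find. Real miRomes are more extremely skewed
(a few species dominate; a very steep tail below 1 cpm); consequences are
noted under Limitations.

3′UTRs are random DNA at the configured GC content. Every true target's
UTR carries exactly one canonical site of the configured type for its
regulator, and every other UTR is guaranteed site-free for every regulator,
by rejection sampling (capped; the error advises longer UTRs or another
seed). This makes target-recovery precision well defined: any predicted
pair outside the planted set is a genuine false positive.

Responder labels are drawn for cases from a logistic model on the first
disease module's factor, `P(nonresponder) = sigmoid(β·(f − f̄))` (default
β = 2), encoding the observation that high inflammatory-module activity
predicts failure of anti-TNF therapy.

All randomness flows from one seed through four named substreams (genes,
mirs, utrs, response). `gene_param_seed` optionally pins gene-level
loadings separately from subject-level draws, so two runs with the same
`gene_param_seed` but different seeds are replicate cohorts of the same
underlying network — exactly what a preservation analysis needs.

Defaults (46 cases / 20 controls; three 50-gene modules in a 500-gene
background; one disease module shifted 2 SD; one regulator at coupling
−0.8 with 20 targets; 400 miRNAs) describe a deliberately desk-scale
cohort: large enough for every statistic to behave, small enough that the
whole test battery runs in seconds.

## Preprocessing

* Quantile normalization maps each sample column onto the vector of row
  means of the column-sorted matrix, then log2; tied values share the mean
  of their quantile values.
* miRNA counts become cpm (`count/library·1e6`); log values use
  `log2(cpm + 0.5)` with the 0.5 offset fixed throughout.
* A miRNA is *expressed* if it reaches 2 cpm in at least half the samples
  of at least one group. The per-library call is lifted to cohort level so
  a single analysis set exists; cutoff and fraction are parameters.
* Depth stability: a single library is subsampled without replacement
  (multivariate hypergeometric — reads are physical objects, so the
  multinomial approximation is rejected) to 0.6–5M reads in triplicate;
  the report counts expressed miRNAs per cutoff and the R² of log-cpm
  against the full library over its expressed miRNAs.
* Differential expression is Welch's t per feature on log2 values (arrays)
  or log2 cpm (miRNA counts), with log2FC = case − control and
  Benjamini–Hochberg q-values. A negative-binomial count model is out of
  scope by design: DE acts purely as a screen feeding the integration
  step, and the Welch stand-in preserves that contract (per-feature p and
  q) while being exactly testable. Features with zero variance in both
  groups get p = 1 and a flag.

## Coexpression network and modules

Pearson correlations (two-sided p via the t transform) are soft-thresholded
into adjacency — unsigned `A = |r|^β` by default, signed available — with
the power chosen as the smallest candidate whose signed scale-free fit R²
(log10 frequency vs log10 binned connectivity, negated for positive slopes)
reaches 0.8, else the best-fitting power. Topological overlap is

```
TOM_ij = (Σ_u A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 − A_ij),  TOM_ii = 1.
```

Genes are clustered by average linkage on `1 − TOM`. The tree is cut
statically at the smallest height that maximizes the number of clusters
with ≥ 30 genes (the minimum module size); clusters below the minimum are
unassigned. Modules whose eigengenes correlate above 0.75 are merged
iteratively. Because a static cut at a low height can strand members of a
true module in sub-threshold clusters, a final membership pass assigns any
unassigned gene with kME > 0.5 to its best module; background genes, whose
null kME is ~N(0, 1/√n), are untouched. Module labels are deterministic
(M1, M2, … by decreasing size; ties by first gene position).

The module eigengene is the first right singular vector (unit norm over
samples) of the gene-standardized module submatrix, sign-aligned to the
module's mean standardized profile, with the variance explained reported.
Module membership kME is the gene–eigengene Pearson correlation.
Module–trait correlations (point-biserial for 0/1 traits) are BH-adjusted
over the module × trait grid; modules at q < 0.05 versus disease are
flagged disease-associated. Hub genes are the intersection of DE p < 0.05
and kME > 0.5 (both strict).

Preservation between a reference and a test cohort uses two observed
statistics per module in the test network: intramodular density (mean
off-diagonal adjacency) and connectivity-pattern preservation (Pearson r
between intramodular connectivity in reference vs test). Nulls come from
200 random same-size gene sets; `Z = (obs − null mean)/null SD` and
`Zsummary = (Z_density + Z_connectivity)/2`, read against the conventional
bounds (< 2 no evidence, > 10 strong evidence). This is a deliberate
two-statistic simplification of the published composite (which medians
over seven or more statistics); the Z construction and the interpretation
bounds are retained.

## Integration

Step 1 — screen. For each (DE miRNA, disease module) pair, the mean
Pearson correlation between the miRNA and all module genes is compared
with a null built by permuting the miRNA's sample order B = 10,000 times
against the fixed gene matrix. The empirical p is lower-tailed with the
plus-one correction, `p = (1 + #{bg ≤ obs})/(B + 1)` — lower-tailed
because the screen seeks negative coupling (a two-sided option exists);
the minimum attainable p is 1/(B+1) and p never equals 0. Permutations are
sampled in a canonical sample frame (samples sorted by the module profile)
so the p-value is exactly invariant under joint relabeling of the inputs.
q-values are BH over all pairs jointly, and a pair is selected when
p < 0.05 and q < 0.25.

Step 2 — targets. Canonical seed sites (8mer, 7mer-m8, 7mer-A1, 6mer —
reverse complements of miRNA positions 2–7/2–8, optionally followed by an
A opposite position 1) are scanned on the UTR sense strand; each 6mer-core
occurrence is reported once with its highest-priority type, 0-based
half-open coordinates, U/T equivalent. An external prediction table can be
ingested and combined by union (default) or intersection. Predicted pairs
are kept when miRNA and gene are negatively correlated (r < 0, p < 0.05)
in the patient subset only; miRNAs are then ranked by retained-target
count, ties broken lexicographically.

Context scores, free-energy hybridization, conservation and non-canonical
sites are out of scope; the scanner covers the canonical seed match only.

## Evaluation

ROC/AUC uses the Mann–Whitney identity with half credit for ties and a
threshold sweep over unique scores (curve from (0,0) to (1,1)). The
positive class is the nonresponder; the orientation flag records whether a
higher eigengene scores the positive class. Recovery metrics compare
pipeline output to planted truth: adjusted Rand index for modules,
sensitivity/specificity of the screen over (miRNA, module) pairs,
sensitivity/precision of retained targets, and the planted regulator's
rank.

## Numerical choices and problem sizes

* BH-FDR is statsmodels' `fdr_bh`; hierarchical clustering is scipy;
  subsampling uses numpy's multivariate hypergeometric ("marginals"
  method); ARI is scikit-learn. Each is cross-checked against a
  brute-force oracle in the tests (step-up FDR, pair counting, triple-loop
  TOM, substring seed scan, pairwise AUC, exhaustive 120-ordering
  permutation p at n = 5).
* Test batteries use desk-scale sizes chosen once: 50 end-to-end
  replicates at n = 60 with B = 10,000 for regulator recovery; 500 null
  miR–module tests at B = 1,000 for screen calibration; two 50-sample
  replicate cohorts with a 60-gene module over 400 background genes
  (loadings 0.7–1.3, σ = 1, mean intra-module r ≈ 0.5) and 200
  permutations for preservation.
* Degenerate inputs: zero-variance genes abort correlation (named), are
  dropped from eigengenes (warned), and flag undefined kME; a constant
  trait or miRNA vector is an error; zero null SD in preservation is an
  error suggesting more permutations or genes.

## Limitations

* The Welch screen is not a count-model DE test; at very low counts its
  p-values are approximate. It is used only to gate the screen.
* The preservation Zsummary uses two statistics, not the published ≥7;
  absolute values are not comparable to WGCNA's, only the < 2 / > 10
  reading is.
* The generator's log-uniform miRNA abundance model under-represents the
  very steep sub-1-cpm tail of real miRomes. One visible consequence: the
  greater depth-stability of the 2-cpm expressed call relative to 1 cpm —
  a strong effect in real libraries — is only weakly and
  seed-dependently reproduced here. Passing the threshold-stability checks
  shows the machinery is correct, not that 2 cpm is optimal for a given
  real library.
* Synthetic UTRs are i.i.d. DNA with planted sites; real UTRs have
  composition, length and repeat structure that make seed matching
  noisier. Perfect target precision on synthetic data is by construction
  and should not be read as a field error rate.
* No batch effects, probe-level artifacts or read-level data are
  simulated; single-split AUC only (no cross-validation or DeLong
  intervals).
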