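# mirmod — integrated mRNA–miRNA coexpression module analysis

In chronic inflammatory disease, monocyte gene expression reorganises into
modules of tightly coexpressed genes, and reduced microRNAs can sit
upstream of whole modules rather than single transcripts. `mirmod`
implements that analysis end to end for paired case/control cohorts (gene
expression arrays plus small RNA-seq miRNA counts):

1. **Coexpression modules** — WGCNA-style: soft-thresholded correlation
   network (`A = |r|^β`), topological overlap, average-linkage clustering
   with a minimum module size of 30, module eigengenes (first principal
   component, `ME`), module membership (`kME`), module–trait correlation
   with disease modules flagged at FDR < 0.05, and permutation `Zsummary`
   preservation between cohorts (< 2 none, > 10 strong).
2. **Small RNA-seq preprocessing** — cpm normalization, the 2-cpm
   expressed-miRNA threshold with its subsampling depth-stability
   analysis, and a Welch-t differential-expression screen with
   Benjamini–Hochberg FDR.
3. **Two-step integration** — (i) each down-regulated DE miRNA is tested
   against each disease module by comparing its mean correlation with all
   module genes to 10,000 sample-permutation nulls (empirical p, selected
   at p < 0.05 and FDR < 0.25); (ii) targets inside the module are
   predicted by canonical seed matching (8mer/7mer-m8/7mer-A1/6mer,
   optionally combined with an external prediction table) and kept when
   inversely correlated with the miRNA in patients (r < 0, p < 0.05),
   then miRNAs are ranked by retained-target count.
4. **Response prediction** — the disease-module eigengene before therapy
   as a classifier score for subsequent anti-TNF nonresponse,
   summarised by the Mann–Whitney AUC.

Everything runs on synthetic cohorts with planted ground truth
(`mirmod.simulate`): latent-factor gene modules, negative-binomial miRNA
counts with a regulator negatively coupled to a disease module, 3′UTRs
carrying exactly one planted seed site per true target, and
responder labels tied to module activity — so module recovery, screen
calibration and target precision are all measurable.

It is aimed at computational biologists who want a tested, reproducible
reference implementation of this integration strategy, or a harness for
benchmarking variants of it.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
cohort (46 cases, 20 controls, three 50-gene modules, one disease module,
one planted regulator miRNA among 400):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_run_pipeline.py
```

`02_run_pipeline.py` prints (abridged):

```
modules detected: {'M1': 50, 'M2': 50, 'M3': 50}
expressed miRNAs (2 cpm rule): 332; DE at FDR<0.05: 1
disease-associated modules (FDR<0.05): ['M1']
permutation screen: 1/1 miR-module pairs selected
  mir_id module  actual_r  pvalue  qvalue
miR-0001     M1 -0.828861  0.0001  0.0001
integrated (predicted + inversely correlated) targets: 20
miRNAs by integrated-target count:
  mir_id  n_targets
miR-0001         20
response prediction: module M1 eigengene AUC = 0.792 (22 nonresponders vs 24 responders)
```

Reading this: the three planted modules are recovered exactly; the planted
regulator miR-0001 is the one down-regulated DE miRNA, its mean
correlation with the disease module (−0.83) beats all 10,000 permutation
nulls (p = 1/10001), and all 20 planted targets — and nothing else — pass
the seed-match + inverse-correlation filter. The disease-module eigengene
predicts nonresponse with AUC 0.79. `analysis/05_recovery_metrics.py`
scores the same run against ground truth (module ARI 1.0, screen and
target sensitivity/precision 1.0).

`analysis/03_module_preservation.py` and
`analysis/04_threshold_stability.py` run the two supporting studies:
preservation of a planted module between replicate cohorts
(Zsummary ≈ 35, versus ≈ −3 for a random pseudo-module) and the
subsampling analysis behind the 2-cpm expressed threshold (log-cpm R²
0.98–1.00 between subsampled and full libraries).

All outputs are plain TSV/JSON under `results/`, with a manifest of
content checksums; two runs with the same config and seed are
byte-identical.

## Layout

```
src/mirmod/        library: simulate, preprocess, coexpression, seeds,
                   integration, evaluation, io, pipeline, studies
analysis/          numbered drivers reproducing the study on synthetic data
tests/             pytest suite incl. oracle and calibration tests
scripts/           acceptance.py (benchmark reproduction)
docs/methods.md    model, assumptions, parameters, limitations
```
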