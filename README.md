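# vaemarker

Biomarker discovery from tumor/normal bulk RNA-seq read counts. The package
implements an end-to-end framework for finding genes that separate tumor from
normal tissue *consistently across samples* — the property that distinguishes
a usable diagnostic marker from a gene that is merely differential in a
subset of heterogeneous tumors — plus the downstream gene-signature risk
stratification step.

## Who it is for

Computational biologists with a gene × sample count matrix and binary
normal/tumor labels (optionally with overall-survival follow-up) who want a
reproducible, seed-deterministic candidate-marker list and a quantitative
consistency score per gene. Everything is exercisable on synthetic cohorts
with planted ground truth, so every stage can be validated before touching
real data.

## The method

1. **Stability-selected differential expression.** Tumor samples are
   repeatedly subsampled at a fixed tumor:normal ratio (default 1:6, 1000
   draws; every normal sample enters every draw). Each draw gets a
   negative-binomial conditional exact test per gene (two groups of NB counts
   with common dispersion φ, `var = μ + φμ²`; the group-A total given the
   grand total has a computable conditional law, and the two-sided p doubles
   the smaller tail). A gene counts as significant at |log2FC| > 1 and
   p < 0.05; genes are kept by their significance *frequency* (defaults: ever
   significant, ≥950/1000, ≥750/1000).

2. **Joint VAE + MLP classifier.** A variational autoencoder (encoder
   1024–1024–512–128, Gaussian latent of dimension 128 via the
   reparameterization z = μ + σε, mirrored Bernoulli decoder) is coupled with
   a 128–64–2 softmax classifier head on the latent code. Losses:

       L_VAE   = BCE(x, x′) + D_KL( N(μ, σ) ‖ N(0, 1) )
       L_MLP   = CE(y, y′)
       L_joint = λ·L_VAE + L_MLP          (λ = 0.001)

   trained in three phases over 250 epochs: 50 VAE-only, 50 MLP-only with the
   autoencoder frozen, 150 joint.

3. **Per-sample, per-gene attribution.** Expected gradients (integrated
   gradients averaged over training-set references) decompose the tumor
   logit of each sample into additive per-gene contributions
   `f(x) = base + Σ_j attr_j(x)`; positive values push toward the tumor
   class.

4. **Biomarker potential score.** With per-sample contribution shares
   thresholded at ±5%/±1%/±0.5%, each gene g gets
   `P_tumor = C_P/N_tumor` (tumor samples with a significant positive
   contribution) and `P_normal = C_N/N_normal` (normal samples with a
   significant negative one), and

       Score(g) = 2 · P_tumor · P_normal / (P_tumor + P_normal)

   — the harmonic mean, 0 when either proportion vanishes. Genes in the top
   quartile of scores survive; candidates are intersected across the three
   threshold groups, across resampled training runs, and across feature
   configurations. The survivors are the final biomarkers.

5. **Prognostic step.** A linear risk score
   `RiskScore = Σ_i Coef_i · Expr_i` (Cox coefficients via lifelines) is
   median-split into High/Low groups and compared with the log-rank test.

## Worked example

```python
import vaemarker as vm

# synthetic cohort: 2000 genes, 10 normal / 60 tumor, 200 differential
# genes of which 20 are fully penetrant biomarkers
counts, labels, truth = vm.simulate_counts(vm.SimulationConfig(seed=1))

cfg = vm.DiscoveryConfig(n_iterations=5, freq_thresholds=(5, 4),
                         n_sample_sets=5, seed=1)
result = vm.run_discovery(counts, labels, cfg)
recovered = set(result.gene_ids) & set(truth.biomarker_gene_ids)
print(len(result.gene_ids), "final genes,",
      len(recovered), "of", len(truth.biomarker_gene_ids),
      "planted biomarkers, run AUCs:",
      sorted({r["metrics"]["auc"] for r in result.provenance["runs"]}))
```

prints

```
10 final genes, 10 of 20 planted biomarkers, run AUCs: [1.0]
```

i.e. every trained classifier separates the held-out samples perfectly
(AUC 1.0), and every gene in the final intersected list is a planted
fully-penetrant biomarker — no null or low-penetrance gene survives the
intersection. The recovered count varies with the seed (between roughly a
third and four fifths of the planted set); the absence of false positives
is stable.

The same pipeline is available from the shell:

```bash
vaemarker simulate --seed 1 --outdir cohort/
vaemarker discover --counts cohort/counts.tsv --labels cohort/labels.tsv \
    --seed 1 --outdir run/
cat run/final_biomarkers.txt
```

## Layout

- `src/vaemarker/data_model.py` — count/label/survival containers and I/O
- `src/vaemarker/synthetic_data.py` — NB cohort generator with planted truth
- `src/vaemarker/diffexp_stability.py` — resampling plan, NB exact test,
  frequency selection
- `src/vaemarker/vaejmlp.py` (+ `_nn.py`) — the joint model and its training
- `src/vaemarker/attribution.py` — expected-gradients contributions
- `src/vaemarker/biomarker_scoring.py` — thresholds, harmonic-mean score,
  quartile filter, intersection, `run_discovery`
- `src/vaemarker/prognostic.py` — risk score, median split, log-rank, Cox
- `src/vaemarker/pipeline.py`, `cli.py` — configuration, manifest, CLI

See `docs/methods.md` for the modeling choices and their rationale.
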