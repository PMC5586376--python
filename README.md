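# mutdet

Gene-level analysis of what drives point-mutation rates in the human
germline and soma: negative-binomial regression of per-gene mutation
counts on genomic and epigenomic covariates, and strand-resolved
mutation-spectrum analysis of transcription-coupled repair signatures.

## The problem

De novo germline mutations (from trio exome studies) and pre-neoplastic
somatic mutations (from tumour/normal exome pairs) are both shaped by
expression level, replication timing, chromatin state and base
composition — but apparently in different ways.  Comparing them fairly
requires one unit of analysis (the coding exons of a gene), one
statistical model, and exposures that account for how many sites in each
gene could actually produce each kind of mutation.  This package
implements that pipeline, together with a synthetic-data generator that
reproduces the statistical structure of the real inputs so every stage
can be exercised and validated without any external downloads.

## The model

For gene *i*, the count of mutations of a given class is modelled as
overdispersed-Poisson (negative binomial, NB2):

```
y_i ~ NB(mu_i, theta),    log(mu_i) = beta0 + sum_j beta_j * X_ij + log(L_i)
```

* `X_1..X_5` — expression (log(RPKM + half the smallest nonzero RPKM)),
  replication timing (higher = earlier), H3K9me3, H3K27me3, exonic GC
  fraction; each z-scored so the `beta_j` are comparable.  Average CpG
  methylation can be added as `X_6`.
* `L_i` — the mutational opportunity, entered as a fixed offset: the
  number of exonic CpG-dinucleotide nucleotides outside CpG islands for
  CpG transitions, all exonic nucleotides for other classes, or the
  per-strand A count for strand-resolved A>G / A>T fits.
* `theta` — the NB size parameter, estimated jointly with `beta` by
  alternating IRLS and profile-likelihood Newton steps (the `glm.nb`
  scheme); `Var(y) = mu + mu^2/theta`.

Two-group contrasts (tissue vs. tissue, or CpG-Ti vs. other) are fitted
by stacking the groups with a 0/1 variable `C` interacting with every
predictor, so `C:X_j` estimates the difference in effect size and its
Wald p-value tests it.

Strand asymmetry: every exonic SNV is collapsed to one of six
purine-reference types (A>C, A>G, A>T, G>A, G>C, G>T) and assigned to
the non-transcribed (coding, NTS) or transcribed (template, TS) strand of
its gene.  Per-type per-strand rates are counts over strand-specific
opportunities; the asymmetry ratio `rate_NTS / rate_TS` exceeds 1 when
transcription-coupled repair spares the template strand.  95% CIs come
from bootstrap resampling of mutation records (B = 100 by default);
within- and across-dataset tests use chi-squared statistics with
opportunity-proportional expectations.

## Worked example

Everything below is synthetic and deterministic under the seed.  The
generator is configured with a germline-like A>G NTS/TS odds of 1.66 and
a positive expression effect on the targeted mutation processes:

```python
from mutdet import *

cfg = SimulationConfig(seed=42, n_genes=2000, ag_rate=4e-3,
                       expression_rate_slope=0.2, dataset="germline")
genome, genes, islands = simulate_reference(cfg)
retained = [g for g in genes if not g.dual_strand_flag]
opp = opportunity_table(retained, genome, islands)

cov = simulate_covariates(cfg, genes)
fm = build_feature_matrix(cov, opp, mutation_class="other",
                          predictors=["expression", "replication_timing",
                                      "H3K9me3", "H3K27me3", "gc_content"])
muts = simulate_strand_mutations(cfg, genes, genome,
                                 expression_z=fm.X["expression"])
kept, qc = filter_hypermutators(muts)
classified, report = classify_mutations(kept, genes, genome, islands)

spectrum, asym = compute_strand_spectrum(classified, opp, B=100, seed=1)
counts = count_by_gene(classified, fm.gene_ids, "other")
res = fit_nb_glm(counts, fm, ModelSpec(mutation_class="other",
                                       predictors=list(fm.X.columns)))
```

Output:

```
10847 mutations kept; 10698 assigned to genes; 2 hypermutator samples removed
A>G NTS/TS ratio: 1.65 (95% CI 1.58-1.72, chi2 p = 1.4e-122)
              term  estimate     se         z      p
         intercept   -5.9239 0.0170 -347.7820 0.0000
        expression    0.1516 0.0183    8.2633 0.0000
replication_timing    0.0153 0.0179    0.8516 0.3944
           H3K9me3   -0.0093 0.0175   -0.5282 0.5974
          H3K27me3   -0.0180 0.0181   -0.9915 0.3214
        gc_content   -0.0551 0.0204   -2.6952 0.0070
theta = 2.98, converged = True
```

Reading it: the recovered strand-asymmetry ratio (1.65, CI 1.58–1.72)
matches the configured 1.66, and the chi-squared test rejects strand
symmetry.  The regression recovers a positive expression coefficient
(0.15 per SD of log expression — attenuated from the planted 0.2 because
the symmetric background process carries no expression effect); the
other covariates, which carry no planted effect, stay near zero.
`exp(beta_j)` is the per-site rate ratio per SD of covariate *j*.

The same analysis is available from a shell via the `mutdet` CLI
(`simulate`, `features`, `classify`, `fit`, `asymmetry`, `all`), driven
by a YAML config; outputs are TSV/JSON and bit-identical under a fixed
seed.

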