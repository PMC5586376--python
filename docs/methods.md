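# Methods

## Units, coordinates and gene models

The unit of analysis is a protein-coding gene, represented as the union
of the exons of all of its transcripts on one strand of one chromosome.
All coordinates are 0-based half-open internally (BED convention);
1-based inputs (MAF-like tables, VCF) are converted at parse time.
Transcript records that disagree on strand mark the gene as
*dual-strand*; such loci are excluded from all strand-resolved analyses
(they are kept in the plain count models).  Overlapping genes are both
credited with a mutation that falls in both exon unions, and every site
is counted in every overlapping gene's opportunity — consistent with
treating genes as independent Bernoulli-trial sequences; the QC report
exposes assignment multiplicities so this can be audited.

## Opportunity counting

For each gene the package counts, over exonic positions with an
unambiguous reference base:

* `L_all` — all such positions (exposure for non-CpG-Ti classes);
* `L_cpg` — positions that are the C **or** the G of a CG dinucleotide
  on the reference + strand.  Both nucleotides count (a CpG transition
  can strike the cytosine on either strand), both members of the pair
  must be exonic and unambiguous, and positions inside CpG islands are
  removed (island CpGs are largely unmethylated, so they do not share
  the deamination-driven transition process).  The dinucleotide context
  is read from genomic, not spliced, sequence.
* strand-resolved base counts — the number of A, C, G, T residues on
  the coding (non-transcribed) strand and on the template strand; the
  A counts are the exposures of the strand-resolved A>G and A>T models.
* `gc_fraction` — (G+C) / `L_all`.

Counting nucleotides rather than dinucleotides for `L_cpg` scales the
CpG-Ti rate by 2 but leaves every regression coefficient except the
intercept unchanged.

## Covariates and the design matrix

Track covariates (replication timing, histone marks, methylation) are
averaged per gene as the *unweighted mean of all track windows
overlapping the gene's start-to-end span* (introns included, windows not
length-weighted).  Exon-weighted averaging was considered and rejected
in favour of the simpler span rule; with 1–10 kb windows the difference
is marginal.  Genes with no overlapping window get a missing value and
are dropped from fits, with the reason recorded.

Expression enters as `log(RPKM + m/2)` where `m` is the smallest nonzero
RPKM in the dataset; the pseudocount keeps unexpressed genes while
preserving the ordering of low expressers.  After dropping genes with
any missing covariate or zero exposure for the requested class, every
predictor column is z-scored (population SD); standardization happens
*after* filtering, and the means/SDs are recorded for reuse.  A
zero-variance column is an error naming the column.

## The negative-binomial model

Counts are NB2: `Var(y) = mu + mu^2/theta`, with log link and the log
exposure as offset.  The additive error term sometimes written in the
linear predictor of such models is not separately identifiable in a
count GLM; it is absorbed by the NB overdispersion, which is the
interpretation implemented here.

Fitting alternates (a) IRLS for `beta` at fixed `theta` (weights
`mu/(1+mu/theta)`, relative coefficient tolerance 1e-10) and (b) Newton
steps on the profile log-likelihood in `log(theta)` (digamma/trigamma
score and curvature, damped and clamped steps), until the joint
log-likelihood is stationary; a final IRLS polish at the last `theta`
precedes the diagnostics.  This is the same scheme R's `glm.nb` uses.
Standard errors for `beta` come from the information matrix at the
optimum conditional on `theta` (observed and expected information
coincide in expectation for this family and are numerically
indistinguishable at the gene counts used here); the `theta` SE from the
profile curvature.  Wald z and two-sided p-values are reported, matching
the coefficient-CI presentation of the figures this package reproduces;
likelihood-ratio comparisons can be formed from the reported
log-likelihoods.  Underdispersed data drive `theta` to a cap (1e8) and
the fit is flagged as the Poisson limit rather than failing.  A
rank-deficient design raises an error naming the collinear columns; a
fit whose score norm is not small is flagged `converged = False` and
warned about, never silently returned.

Combined two-group fits stack the groups with a 0/1 contrast interacting
with every predictor.  Each group keeps its own covariate
standardization (as the separate models imply); pooled standardization
can be had by building both groups' feature matrices from a pooled
table.  With all interactions included and a shared fixed `theta` the
likelihood factorizes, so group-specific effects equal separate
per-group fits — a property the tests exploit as an oracle.

## Hypermutator screening

Samples with outlying total mutation counts are removed before
modelling.  The default rule is Tukey's upper fence: count > Q3 +
1.5·IQR (linear-interpolation quartiles).  No standard single-outlier
test on counts matches a "P < 0.05" description exactly, so a
generalized-ESD alternative (upper tail, alpha = 0.05) is provided
behind `method="esd"`.  Fewer than four samples disables the screen with
a warning.  Under a clean null the fence still flags ~0.5–1% of samples
(it is an exploratory fence, not a calibrated test); the packaged
no-outlier control therefore uses 12 samples with ~50–80 mutations each,
chosen by an error analysis done at design time so that the expected
number of false removals is well below one.

## Classification and strand assignment

Each SNV is collapsed to a purine-reference type: if the base on the
coding strand is A or G the type is read off the coding strand and the
mutation is NTS; otherwise both alleles are complemented and the
mutation is TS.  `cpg_ti` is true for G>A-collapsed changes in a CG
genomic context outside islands.  In-island CpG transitions stay in the
"other" class (whose exposure is all nucleotides) and carry an
`in_island` flag.  Records whose stated reference base disagrees with
the genome are dropped and counted; the report enforces the
conservation identity `parsed = mismatch + assigned + unassigned`.

## Spectrum, bootstrap and tests

Rates are pooled over genes: total count over total opportunity per
(type, strand).  Bootstrap CIs (percentile 2.5/97.5, B = 100 by
default) resample individual mutation records with replacement while
opportunities stay fixed — the most literal reading of resampling "the
original sample"; since the statistics depend on records only through
their category, the resample is drawn as a multinomial over categories,
which is distributionally identical and fast.  Gene-level resampling
(counts and opportunities together) is available via `unit="gene"`.
Percentile rather than BCa intervals are used to match the simple
resampling description being reproduced.

Within-dataset asymmetry per type is a 1-df chi-squared of the observed
NTS/TS counts against opportunity-proportional expectations.  The
cross-dataset homogeneity test builds expected counts from pooled
per-strand rates scaled by each dataset's own opportunities (k−1 df);
with equal opportunities it reduces exactly to the textbook Pearson
statistic on the k×2 table.  Expected cells below 5 trigger a warning
and an optional Monte-Carlo p-value.

Expression-quantile analysis ranks genes by expression (ties broken by
gene id for determinism) and splits them into k near-equal bins, earlier
bins at most one gene larger; per-bin ratios and pooled rates carry
bootstrap CIs.

## The synthetic-data generator

`simulate_reference` lays genes end to end on one chromosome
(iid bases at 41% GC; 2–20 exons of 60–300 bp; introns 100–400 bp;
intergenic gaps 200–800 bp), embeds Poisson-placed CpG-rich island
segments (9/Mb, 400–1500 bp, 65% GC with explicitly planted CG pairs)
that are also recorded as the island BED, and flags 1.7% of genes as
dual-strand — the fraction reported for real annotation.  Defaults of
19,000 genes, NB dispersion theta = 2 and an A>G NTS/TS odds of 1.66
mirror the germline study conditions; smaller gene counts are used in
tests and examples purely as problem sizes, stated where used.

`simulate_covariates` draws latent gene scores from a multivariate
normal with a configurable correlation matrix (defaults: expressed genes
replicate earlier and carry fewer repressive marks, |r| ≤ 0.3) and maps
them to plausible scales — RPKM by exponentiation with a point mass at
zero for the lowest latent quantile (default 20%), timing to mean 50/SD
15, marks to log-normal enrichments.  Correlations are exact on the
latent scale; the zero point-mass attenuates raw-scale correlations
slightly.

`simulate_counts` is the generative twin of the regression: NB draws
(Gamma–Poisson mixture, exact for any real theta) with mean
`L·exp(beta0 + X·beta)` applied to the *standardized* feature matrix, so
configured coefficients are recovered on the fitted scale without
attenuation.

`simulate_strand_mutations` draws per-gene A>G (and A>T) totals as NB
with mean proportional to the gene's two-strand A opportunity (optionally
scaled by `exp(slope·x)` in standardized expression), then places each
mutation on the NTS with odds `rho(x) = rho0 + rho1·x` weighted by the
per-strand opportunities — totals stay NB, and the pooled NTS/TS rate
ratio estimates `rho`.  Positions are uniform over the eligible A sites
of the appropriate strand.  A uniform background process covers the
eight strand-types *not* governed by the targeted process (at A/T sites
only the A>C-collapsed change), so the A>G and A>T classes are not
diluted toward symmetry.  Sample ids are assigned with configurable
planted hypermutators receiving a multiplier-fold share.  Emitted
FASTA/refFlat/BED/bedGraph/TSV files are read back by the pipeline's own
readers (a round-trip the tests enforce).

What the generator does **not** emulate: real chromosome organisation,
trinucleotide signature structure beyond the CpG/other split,
annotation-version disagreements, mapping artefacts, or selection.
Passing tests demonstrate the statistical machinery is correct and
calibrated under the assumed generative model, not that real data meet
those assumptions.

## Numerical and determinism choices

Quantiles use linear interpolation (numpy default).  Ratios with a zero
TS rate are reported as +inf with a flag; zero opportunities give
missing rates.  All stage outputs are TSV with fixed float formatting
(`%.10g`) and stable column and row order, so identical config + seed
reproduce byte-identical files.  Generator stages derive independent
streams from `(seed, stage_id)` so adding a stage never perturbs another
stage's draws.

## Known limitations

* The expression covariate is a tissue-level proxy; nothing in the
  package corrects for proxy error.
* The per-gene models ignore spatial correlation along the genome and
  shared samples across genes; SEs are conditional on independence.
* The Tukey fence is not a calibrated outlier test (see above); its
  removal fraction on heavy-tailed real cohorts can be several percent.
* Bootstrap CIs are percentile-based and can undercover for very small
  counts; the tests quantify coverage only at the simulated scales.
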