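# Methods

This note documents the models, conventions and design choices behind
`hypoxiscore`: a pipeline that quantifies a 45-gene hypoxia-response panel
from qPCR threshold-cycle (Ct) data, profiles fold induction across
clinicopathological groups, clusters patients, and builds a 6-gene
indicator-sum relapse risk score with survival-optimized expression
cut-points.

## Relative quantification (comparative ddCt)

qPCR reports Ct, the cycle at which amplification crosses a fixed
fluorescence threshold; one cycle is one doubling, so Ct is −log2 of input
transcript abundance plus a per-sample offset (cDNA input, efficiency of
the run).  The pipeline assumes the pure exponential model with
amplification efficiency 1 (no efficiency correction):

* **Detection cutoff.**  Ct ≥ 35 cycles is treated as non-expressed and the
  well is masked.  The boundary is inclusive — a Ct of exactly 35 is
  non-expressed — with a documented flag (`inclusive=False`) to flip.
  Masked-by-cutoff wells are distinct from instrument "Undetermined" wells
  only until the cutoff is applied; afterwards both are missing values,
  excluded pairwise from every downstream mean and test (no imputation,
  except mean imputation inside clustering, which cannot tolerate holes).
* **Normalization.**  dCt(g, s) = Ct(g, s) − R(s), where R(s) is the
  arithmetic mean Ct of the reference set in sample s (arithmetic mean of
  Ct = geometric mean of linear quantities, the standard convention).
  Three reference strategies: the two endogenous controls (*RPL32*, *18S*);
  the top-k genes of the model-based stability ranking below; or the
  per-sample mean of all measured genes ("global mean").  Per-sample
  additive offsets cancel exactly in dCt under every strategy.
* **Calibration.**  ddCt(g, s) = dCt(g, s) − C(g).  The calibrator C is the
  cohort-mean dCt of gene g by default, making RQ = 2^(−ddCt) a fold
  expression versus the cohort average with unit geometric mean per gene;
  a named calibrator sample is also supported (its RQ is exactly 1).  Which
  convention the original analysis used is not recoverable from the
  quantities it reports; the cohort mean is the choice that makes group
  ratio profiles self-contained.

## Reference-gene stability ranking

The stability value follows the model-based (NormFinder-style)
decomposition.  Log-scale expression is column-centered (removing the
per-sample level), then, per candidate gene and patient group, split into
an inter-group bias d (deviation of the group mean from the gene's overall
mean) and an intra-group sampling variance u = s²/n.  The bias is shrunken
toward zero by the empirical-Bayes factor γ²/(γ² + u), with γ² the
between-gene variance of the biases in excess of their average sampling
variance; the stability value is the absolute shrunken bias plus the
residual sampling standard error, averaged over groups.  Lower is more
stable; ties break on the gene symbol.  With no groups the value reduces to
the standard deviation of centered log expression.  The original
publication's additional small-sample corrections for the correlation
induced by column-centering are omitted; with 47 genes the induced
correlation is below 1/47 per pair and does not reorder rankings in
practice.

## Fold induction and per-gene tests

For a case/control dichotomy (stage 2–3 vs 1, mSBR grade 4–5 vs 1–3, HER2+
vs −, recurrent vs non-recurrent) the ratio r of mean RQ (case over
control) is reported as a signed fold: f = r − 1 for r ≥ 1, −(1/r − 1)
otherwise, so +1 means 2-fold up and −1 means 2-fold down, and
f(r) = −f(1/r).  Significance per gene uses Welch's t-test on dCt (the log
scale, where the simulation model — and qPCR noise generally — is normal)
when Shapiro-Wilk at 0.05 does not reject normality in either group,
otherwise Kruskal-Wallis on RQ ranks; both p-values are always emitted so
either column can be inspected.  Raw p-values are the primary readout (no
multiplicity correction, by design); a Benjamini-Hochberg column is
attached as a clearly-marked extra.  "Average overexpression" of a group is
100 × mean over genes of (r − 1); the mean signed fold is emitted
alongside.

## Clustering

Patients are clustered on raw dCt profiles (no per-gene standardization by
default; a z-score flag exists) with Euclidean distances and Ward's
minimum-variance linkage in the barycenter formulation — equivalent to
ward.D2 on Euclidean distances — via `scipy.cluster.hierarchy`.  Default
cuts: k = 2 on the full 45-gene panel, k = 3 on the 6-gene signature.
Cluster membership is tested against relapse with a Pearson chi-square
(no continuity correction); clusters may be pooled before testing; a
small-expected-count warning and a Fisher exact extra accompany 2×2
tables.  For display, each gene row is median-centered and sign-flipped so
that above-median expression is positive.

## Survival

Relapse-free survival is time from diagnosis to local or distant
recurrence; anything else (including death without documented recurrence)
is censoring, with a documented flag at the data layer.  The Kaplan-Meier
product-limit estimator uses the standard tie convention (events before
censorings at equal times).  The two-group Mantel-Haenszel (log-rank) test
accumulates observed-minus-expected events and hypergeometric variances
over the risk sets at each distinct event time, referred to chi-square on
1 df without continuity correction.  The O/E-based hazard-ratio summary
(O₁/E₁)/(O₀/E₀) is reported, flagged degenerate when a group with positive
expectation has zero observed events.

## The relapse risk score

1. **Signature selection.**  Genes with p < 0.05 and positive fold in the
   recurrent-vs-non-recurrent comparison.
2. **Per-gene cut-point.**  Exhaustive search over all midpoints between
   consecutive sorted distinct RQ values ("iterative search" made
   exhaustive and scale-independent); patients with RQ > τ form the high
   group; the τ maximizing the log-rank statistic wins.  Cuts leaving
   fewer than ceil(0.1·n) patients on either side are inadmissible
   (configurable).  Ties within 1e−9 break toward the more balanced split,
   then the smaller τ.  Masked wells are excluded pairwise per gene.
3. **Scoring.**  One point per gene with RQ strictly above its threshold
   (equality scores 0); the score is the sum, 0..k.
4. **Score cut.**  Every s with score ≤ s vs ≥ s+1 is profiled by log-rank;
   the smallest maximizing s is chosen (most conservative high-risk
   group).
5. **Evaluation.**  Per-group KM curves, cumulative incidence at 60 and
   120 months, O/E hazard ratio, and Cronbach's alpha of the signature
   items, computed on standardized log2 RQ by default (alpha is then
   invariant to per-item affine rescaling; a raw-RQ option exists).

A fixed published six-gene threshold table (EPO 7.10, ETS1 1.81, ENO1
1.00, PGK1 1.37, LDHA 1.20, TPI 1.14) can be loaded in place of the search
for scoring external cohorts.

**Optimism.**  Steps 2 and 4 optimize the same outcomes they are tested
against, so the in-sample log-rank p of the final grouping is
anticonservative — under a zero-effect simulation the nominal-0.05 test
rejects well over half the time.  All outputs label this p as in-sample,
and `permutation_p_extra` offers a corrected p that re-runs the entire
optimization on outcome-permuted data (default 500 permutations).

## Synthetic cohorts

The generator emulates the statistical shape of a small retrospective
low-density-array study so every stage is testable without patient data:

* 47 assays (45 targets + *RPL32*, *18S*), 32 patients by default, clinical
  covariates drawn to match the reference cohort's marginal counts exactly
  (largest-remainder apportionment, randomly assigned): age <50/≥50 = 8/24,
  ER 1/31, PR 8/24, nodes 20/12, stage 7/24/1, mSBR grade low/high = 25/7,
  HER2 27/5.
* Ct ~ Normal(baseline − shifts, sd) per gene: biological sd 1.5 cycles for
  targets, 0.2 for references; abundant transcripts near Ct 22, scarce ones
  (EPO, LEP, CA9, CXCR4) near the detection limit so realistic Ct > 35
  dropouts occur and are reported numerically, as instruments do.
* A latent per-patient hypoxia activity loads on every target (1.0 cycle/sd
  on the six signature genes, 0.5 elsewhere, 0 on references), reproducing
  the coordinated co-expression of hypoxia-responsive transcripts; this is
  what makes the 6-gene scale internally consistent (alpha ≈ 0.75 at the
  defaults) rather than a collection of independent items.
* Relapse times are exponential proportional hazards on the signature:
  either 0.4 log-hazard per log2 unit of centered expression per gene
  (default, "proportional" mode) or a planted step of 0.8 per
  above-threshold indicator ("threshold" mode, default planted cutoff
  RQ = 2); baseline 0.003 events/month, independent exponential censoring
  at 0.003/month, administrative horizon 180 months.  These defaults give
  roughly 40% observed relapse over follow-up, matching an early-stage
  cohort followed for 10–15 years.
* Optional group effects shift chosen genes by a fixed cycle count in the
  case level of a clinical dichotomy.

What the generator does **not** emulate: amplification-efficiency
differences between assays, plate/batch effects, confounding between
clinical covariates and expression (unless configured via group effects),
richer co-expression than a single factor, and non-proportional or
time-varying hazards.  Passing tests therefore demonstrate correctness of
the algorithms under the stated generative model, not clinical validity on
real tumors.

## Test problem sizes

Oracle-equivalence tests run the cut-point search against exhaustive
enumeration on 200 random instances (n ≤ 50) and the log-rank statistic
against explicit risk-table enumeration on 100 instances (agreement to
1e−10); null calibration of the log-rank test uses 2 000 replicates at
n = 100.  Recovery studies use the strong-effect threshold-mode condition
(n = 300, 2.0 log-hazard per indicator, baseline 0.005/month, 50 seeded
replicates): the selection step recovers ≥ 5 of the 6 planted genes and
the cut-point search lands within ±0.4 of the planted RQ = 2.0 in
essentially all replicates; these sizes were chosen to make the recovery
probabilities near-deterministic while keeping the suite fast.

## Known limitations

* The score and its thresholds are in-sample constructs; without external
  validation the reported survival separation overstates real performance
  (see Optimism above).
* Stability ranking omits the original small-sample centering corrections.
* The chi-square on 32 patients routinely has expected counts below 5; the
  Fisher extra should be preferred there.
* With a single-gene signature, Cronbach's alpha is undefined and reported
  as null.
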