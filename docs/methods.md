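# Methods

## The stratified-discovery procedure

`prstrat` targets cohorts in which the case phenotype is a mixture of a
majority genetic architecture (common variants, large aggregate effect) and
a minority architecture (rarer variants, diluted in pooled analyses).  The
procedure trains a polygenic risk score (PRS) for the majority architecture
on one cohort half, uses it to carve out the test half's *low-PRS* stratum —
cases that the majority architecture does not explain — and re-runs the
case-control association scan inside that stratum against low-PRS controls.

### Association engine

Per-variant association is additive-dosage logistic regression,

    logit Pr(case) = b0 + b·G + γ'·(sex, PC1..PCk),

fit by Newton scoring (IRLS) with convergence tolerance 1e-8 and at most 25
iterations, and tested by the Wald statistic b/se with se from the observed
information.  Missing dosages are mean-imputed per variant; sex is coded
male = 1 / female = 0 with unknown sex mean-imputed, so samples of
undetermined sex are retained.  Confidence intervals use exp(b ± 1.96·se);
the 1.96 quantile is also used when a standard error must be recovered from
a printed CI, because published CIs are built with it.

Rare variants in modest strata frequently produce quasi-separation, where
the ML estimate diverges.  Non-convergence, a singular information matrix,
or any fitted probability within 1e-8 of 0 or 1 triggers a refit with the
Firth (Jeffreys-prior) penalty — Newton iterations on the penalized score
U*(β) = X'(y − p + h(½ − p)) with step-halving on the penalized
log-likelihood — which always yields finite estimates; such records are
flagged `test=firth`.  Variants with no dosage variation are skipped with a
recorded reason rather than aborting a scan.

Principal components are computed on mean-imputed dosages standardized by
√(2p(1−p)), restricted to common variants (MAF ≥ 0.05) after index-window
LD pruning (window 50 variants, step 5, r² > 0.2 removes the later variant).
PC coordinates are the top left singular vectors scaled by their singular
values, signed so each component's largest-magnitude loading is positive.
Ten PCs is the default (`n_pcs`), matching common GWAS practice; scaled-down
simulations use fewer because the rank and the structure dimension are
smaller.

Genomic inflation λ is the median of the χ²₁ statistics implied by the
P-values divided by the χ²₁ median (≈ 0.4549).  One caution learned from
piloting: when PCs are estimated from few variants, or structure confounding
is extreme (naive λ ≫ 5), the *estimated* PCs leave a visible residual
(λ ≈ 1.1) that is a property of PC correction, not of the implementation.

### C+T polygenic risk score

Clumping is greedy: the unclaimed variant with the smallest training P
becomes an index variant and claims every unclaimed variant within
`window_kb` (default 250 kb) on the same chromosome whose dosage-correlation
r² with it exceeds `r2_threshold` (default 0.1); ties break by P then
position.  The LD reference is the training cohort's own genotypes.  The
model at threshold P_T keeps clumped variants with training P ≤ P_T and
weights each by β = ln OR.

Scores use the average-per-allele convention S_j = Σ β_i G_ij / (2 M_j),
where M_j counts model variants with non-missing dosage for sample j.  This
convention (the PRSice-2 default) is also what makes very small published
cutoff values (~1e-3) plausible, since raw sums of hundreds of ln-OR terms
would be orders of magnitude larger.  Model entries are reconciled to the
scored matrix by effect allele, flipping to 2 − G when the model's effect
allele is the matrix's other allele; irreconcilable or absent entries are
excluded from numerator and denominator and counted.

The inclusion threshold is selected from a 14-value grid
(1e-10 … 1e-4 by decades, 0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1) by AUC of
the scores against case status in the held-out half; AUC is the
Mann–Whitney pair statistic with ties counted one half.  Ties in AUC go to
the smaller threshold; thresholds yielding empty models are recorded as
missing rather than aborting.

### Stratification

The PRS cutoff maximizes the Matthews correlation coefficient over candidate
cutoffs placed at midpoints between consecutive distinct scores (plus
sentinels below the minimum and above the maximum), under the prediction
rule case ⇔ score > cutoff; the midpoint placement makes the inclusive
low-risk rule (score ≤ cutoff) unambiguous under floating-point equality.
MCC with a zero denominator factor is defined as 0.  The low-PRS scan then
compares low-PRS cases to low-PRS controls; by default PCs are recomputed
within the stratum (guarding against stratification-induced confounding),
configurable to reuse the full-cohort PCs.

### Heterogeneity and locus calling

Odds-ratio heterogeneity between the low-PRS and overall analyses of the
same variant is a two-sample z on log ORs assuming independence,
z = (β₂ − β₁)/√(se₁² + se₂²), two-sided normal P.  The low stratum is
nested in the overall cohort, so independence is formally violated; the
convention is kept because it exactly reproduces published heterogeneity
P-values computed the same way, and it is conservative in the usual
direction of interest.  Effect alleles must match; there is no silent
flipping.  Heterogeneity is evaluated at locus lead variants (genome-wide
significant, P ≤ 5×10⁻⁸ inclusive, in at least one of the two analyses).

Hits merge into loci by single linkage within `merge_kb` (default 500 kb —
the grouping distance is a conventional choice, exposed in config).  The
lead is the smallest-P hit (tie: smaller position).  A locus is *known* when
its lead lies within `flank_kb` (default 300 kb) of a user-supplied
known-locus interval, *high quality* when the lead's imputation r² > 0.9,
and *rare* when the lead's MAF < 5%.

## The synthetic cohort generator

`prstrat.simulate` emulates the two-subtype mixture the analysis assumes.
Each subtype s has a logistic disease model
logit Pr(case | G) = a_s + Σ_{i∈panel(s)} ln(OR_i)·G_i over its own causal
panel; the intercept a_s is calibrated by root-finding so the subtype's
marginal case probability equals `baseline_prevalence`, with the panel-score
distribution computed by exact convolution over genotype classes (pruned at
1e-15 mass; dense panels fall back to a fine-grid linear-interpolation
convolution).  Cases are rejection-sampled per subtype — which keeps the
configured ORs interpretable as the simulation's own parameters — and
controls are rejection-sampled non-cases from the subtype mixture.
Genotypes are Hardy–Weinberg binomial(2, MAF) and independent across
variants (no LD).

Defaults are the study conditions the package models: 6,599 cases and
12,350 controls; a common panel of (MAF 0.25, OR 6.0), (0.10, 2.2) and a
protective (0.25, OR 0.44); a rare panel of eight variants spanning MAF
0.002–0.035 with OR 9–2; minority `subtype_fraction` 0.08, inside the
reported 5–10% antibody-negative range; 20,000 effect-free variants with
MAF ~ U(0.01, 0.5); `baseline_prevalence` 0.004, a pediatric-T1D-like
figure chosen once since no value is stated anywhere.  Null-variant
positions tile chromosomes 1–22 at 1 Mb spacing; causal panels sit on
dedicated chromosomes outside locus-merging range of any null variant.
Optional structure draws per-variant null allele frequencies for two
subpopulations from a Balding–Nichols-style Beta divergence
(p(1−F)/F, (1−p)(1−F)/F) with configurable case/control subpopulation
imbalance; causal panels keep base frequencies in both subpopulations so the
prevalence calibration is unaffected.

What the generator does *not* emulate — and therefore what passing tests do
not establish about real data: linkage disequilibrium (clumping is exercised
on constructed correlated fixtures instead), genotyping/imputation error
(quality scores are metadata only), relatedness and family structure,
continuous admixture, and realistic allele-frequency spectra.  The analytic
oracle `expected_case_frequency` (3-term enumeration over genotype classes)
pins the generator's calibration in tests, and per-variant CI coverage of
true log ORs is verified at ~95% on a 10,000-sample simulation.

## Scaled problem sizes and observed behaviour

The test suite and the acceptance script run the full pipeline on reduced
cohorts (600–4,000 cases, 150–2,000 effect-free variants), sizes chosen so
the whole suite completes in a few minutes on one CPU; the generator's
defaults are unchanged.  Two behaviours at reduced scale are worth
recording:

* **Threshold selection needs genome-wide noise.**  With too few null
  variants every inclusion threshold scores a similar AUC, the grid can pick
  a lenient threshold, and the minority rare variants enter the PRS model —
  after which selecting *low*-PRS samples anti-selects their carriers and
  cancels the enrichment the design exists to produce.  With ≥ ~1,000 null
  variants the grid selects stringent thresholds and the rare variants stay
  out of the score, as in the motivating study (threshold 1e-5).

* **Concentration depends on PRS strength.**  A three-variant common panel
  yields test-half AUC ≈ 0.8, so the MCC cutoff labels a larger case
  fraction low-PRS than a stronger score would, and the minority subtype
  concentrates from 8% to ~15–22% of low-PRS cases rather than more.  The
  package therefore demonstrates the enrichment property in its qualitative
  form — minority rare variants gain significance in the low-PRS scan,
  majority common variants lose ~30–50 orders of magnitude of significance —
  rather than a fixed genome-wide-significance count.

## Numerical conventions and degenerate inputs

* Quality filter R² ≥ 0.3, hit filter P ≤ 5×10⁻⁸, MAF bounds: all
  inclusive.
* Cohort split: stratified by phenotype; odd stratum counts send the extra
  sample to cohort A; deterministic for a given seed.
* Constant variants: skipped in scans, excluded from PCA standardization.
* AssocResult invariants enforced at construction: or = exp(β),
  ln l95 + ln u95 = 2β, P ∈ (0, 1].
* P-values are floored at the smallest positive double rather than 0.
* Association tables round-trip through TSV at 6 significant digits.
* Genome build is carried as metadata (`hg38` default) and never validated.
* Strand-ambiguous (A/T, C/G) variants are kept and flagged, since all data
  flow through one harmonized dosage matrix.

## Known limitations

* No LD simulation; clumping correctness is established against a
  brute-force greedy oracle on constructed fixtures, not on realistic
  haplotypes.
* The heterogeneity test ignores the nesting of the low-PRS stratum in the
  overall cohort (see above).
* The Firth fallback uses the last Fisher information for its standard
  errors; profile-penalized-likelihood CIs are not implemented.
* X-chromosome handling, mixed models, meta-analysis, conditional analysis
  and imputation are out of scope.
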