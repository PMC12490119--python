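# Methods

## Setting

The package analyses family cohorts ascertained for autism spectrum
disorder (ASD): children with trio genome sequencing, gestational-age
records, medical-diagnosis histories, and polygenic score inputs. Two
group contrasts organize every analysis: preterm versus term birth within
ASD, and ASD versus non-ASD within preterm birth. Preterm birth is
delivery before 37 completed weeks, stratified as extremely (< 28 wk),
very (28–31), moderate (32–33), and late (34–36); a preterm birth with no
recorded gestational age keeps an explicit `unknown_ga` stratum rather
than being imputed.

## De novo variant pipeline

A candidate de novo variant is a trio Mendelian violation: child
heterozygous (hemizygous alternate on the male X, where only the mother
is required to be reference), both parents homozygous reference, and
child allele balance strictly above 0.25. Undefined allele balance (zero
informative reads) disqualifies a record. The production design around
real call sets uses two-caller consensus; here a single deterministic
rule set plays that role, and `detect_candidates` accepts an optional
external (child, variant) set to intersect for consensus workflows.

Candidates then pass an ordered rejection cascade. Filters, with their
thresholds: minimum GQ 20 and minimum DP 10 over the whole trio (a
`qc_scope="child"` mode restricts both to the child; trio scope is the
stricter reading and the default), population allele frequency at most
0.001 with a missing frequency treated as zero (absence from reference
databases means the variant is novel, hence rare), homopolymer alleles
(a run of ten or more consecutive A or T inside the REF or ALT string —
flanking-context scanning would need a reference genome and is out of
scope), centromere/low-complexity region membership, carriage by a
parent of another family, candidate recurrence in children of more than
three distinct families (the boundary is strict: three families pass,
four fail), and more than three ALT alleles at the original site
(multiallelic sites are decomposed at input, but each decomposed record
keeps the site-level ALT count so this filter still sees it).

The filter order is fixed as listed so per-filter audit counts are
reproducible; each call records every failing filter in cascade order,
and audit counts attribute a rejection to the first failing filter, which
makes candidates = passed + Σ per-filter rejections an exact identity.
Finally, children whose passing count lies more than three sample
standard deviations from the cohort mean — on either side; the exclusion
is deliberately two-sided since an implausibly low count also signals a
sample problem — are removed entirely.

Classification: loss-of-function (LOF) means any consequence term, after
stripping an optional `_variant` suffix, is one of frameshift,
splice_acceptor, splice_donor, start_lost, stop_gained, stop_lost; NDD
means the gene is in the supplied neurodevelopmental-disorder panel;
`lof_ndd` requires both. Event rates are per-group means of per-child
counts with standard errors sd/√n, with zero-count children included.

## Inherited variants

Only panel genes with a usable inheritance annotation participate
(monoallelic/dominant → dominant, biallelic/recessive → recessive;
conflicting annotations for one gene raise an error rather than being
silently resolved, since no principled tie-break exists). Rarity
thresholds are mode-specific: allele frequency ≤ 0.001 in dominant genes,
≤ 0.01 in recessive genes. Genotype-mode consistency requires a dominant-
gene call to be a heterozygous child with at least one carrier parent; a
recessive-gene call is a homozygous-alternate child with two carrier
parents, or a heterozygous child kept as a compound-heterozygote
candidate. GQ/DP thresholds (20/10) apply to the child and every
transmitting parent — stricter than a child-only reading, on the view
that an unreliable transmitting genotype invalidates the transmission
itself.

Compound heterozygotes are resolved purely by transmission phasing: two
heterozygous calls in the same recessive gene of one child, one maternal
and one paternal. Hets whose origin is ambiguous (both parents carriers)
are unphaseable and excluded from pairing; unpartnered recessive hets are
dropped. Damaging-missense classification applies to dominant-gene
variants only and requires a missense consequence plus at least one of
CADD ≥ 20, SIFT D, PolyPhen P or D, PhyloP ≥ 2.0, REVEL ≥ 0.5 (the
PolyPhen rule reads "P and D" as membership in {P, D}; a single label
cannot be both). Missing scores never satisfy their condition.

## Phenotype statistics

A diagnostic category (behavior, development, mood, growth, birth, eat,
neuro, visaud, sleep) is present if any specific diagnosis within it is
recorded, regardless of how many; multimorbidity is the number of present
categories, bucketed 0, 1, 2, 3, 4, ≥ 5. Odds ratios use the
Haldane–Anscombe 0.5 correction when any cell is zero and Woolf
(log-normal) 95% intervals; p-values come from the Pearson χ² without
continuity correction, switching to Fisher's exact test when any expected
cell is below five. These CI/correction choices are the package's own —
several defensible alternatives exist — and covariate-adjusted odds
ratios from family-clustered GEE logistic fits are available alongside
the crude ones. Trend across ordered preterm strata uses Kendall's τ
between stratum rank (lowest gestational age first) and prevalence, so
negative τ means prevalence falls toward term; constant prevalences leave
τ undefined. Score comparisons use the two-sided Wilcoxon rank-sum
(normal approximation with tie correction) for two groups and
Kruskal–Wallis for more. Multiplicity is controlled by Benjamini–Hochberg
FDR within an analysis family — the nine categories, the six measures, or
the set of post hoc stratum pairs — matching how results are grouped for
display.

## Clustered models

Siblings share rearing environment and half their genome, so outcomes
correlate within families. All burden, adjusted-odds and probability
models are therefore marginal regressions fit by generalized estimating
equations with family as the cluster, an exchangeable working correlation
by default (independence available), and robust sandwich standard errors;
statsmodels solves the estimating equations. Count models use the Poisson
family with log link and no offset (outcomes are per-child counts, not
per-base rates); binary models the binomial family with logit link. With
one individual per cluster the fit coincides with the ordinary GLM to
numerical precision, which the tests assert at 1e-8. Apparent separation
in a logistic fit (a diverging coefficient) raises an error naming the
covariate. The burden contrast is count ~ group + sex; the probability
model is ASD ~ sex + preterm + standardized PRS, optionally with a
preterm × PRS interaction; the age covariate in adjusted odds ratios is
age at registration in years.

One calibration subtlety: GEE estimates population-averaged effects,
while the synthetic generator plants conditional (family-intercept)
coefficients. Recovery checks therefore compare the GEE estimates against
the marginal truth obtained with the standard logistic-normal attenuation
factor 1/√(1 + 0.3457 σ²), σ being the family-intercept SD.

## Polygenic scores

Raw scores are per-allele weighted averages: Σ dosage × weight over
non-missing variants divided by twice the number of variants used (the
convention of standard scoring tools; a plain-sum mode is provided).
Effect alleles are resolved against the genotype file's alleles — a
weight stated on the reference allele is applied to the flipped dosage,
and a weight matching neither allele is skipped and counted. Restating a
weight on the other allele with negated sign shifts every raw score by
the same constant (−2w per variant before averaging) and therefore leaves
the z-scores, and every downstream analysis, exactly unchanged; the
invariance contract is asserted on z-scores for this reason. Scores are
z-standardized over the cohort; zero variance is an error. Explained
variance of ASD status is reported as McFadden pseudo-r² from ordinary
logistic fits, both as the full-model value 1 − ll(sex + PCs + PRS)/ll(∅)
and as the increment over the covariate-only model, since either
convention appears in practice. Predicted-probability grids average the
fitted model's predictions over the observed covariate distribution at
fixed focal values (PRS grid × sex × preterm), the marginal-effects
display of the model.

## Birth-feature prediction

The feature table uses only birth-available information: sex, gestational
age (term births missing it are imputed at 40 weeks; preterm births
without gestational age cannot supply the feature and are dropped with a
warning), birth complications, insufficient oxygen at birth, variant-class
counts, DNV CADD summaries, and the standardized PRS. Selection runs
recursive feature elimination with random-forest importances under
stratified cross-validation (subset size chosen by AUROC), then prunes
feature pairs with |Pearson r| strictly above 0.7, keeping the more
general member of a pair as given by a configurable generality ordering
(e.g., all-LOF counts before LOF-on-NDD-genes counts); correlations are
rounded to 12 decimals so floating-point noise cannot push a boundary
pair over the strict threshold.

Evaluation is nested cross-validation: stratified outer folds (ten by
default) whose held-out data never touch tuning, and an inner repeated
stratified k-fold grid search selecting hyperparameters by AUROC (the
inner criterion is configurable; AUROC is the default because the class
mix is imbalanced). Metrics — accuracy with an exact Clopper–Pearson 95%
CI, AUROC, sensitivity and specificity with ASD positive, F1 — are pooled
over out-of-fold predictions. Class imbalance is handled by
stratification only; no resampling. Attributions use exact TreeSHAP
contributions (computed natively by XGBoost) per person on that person's
held-out fold, summarized as mean |SHAP| with a direction sign; non-tree
models fall back to permutation importance, flagged in the output.

## Synthetic cohort generator

The generator produces what the analyses assume, not sequencing realism:
no read-level error model, no mutational spectrum, no linkage
disequilibrium between PRS SNPs (scores are binomial-genotype weighted
sums). Families draw 1–3 children (mix 0.50/0.35/0.15, ≈ 1.65 children
per family, matching a multi-child cohort of ~5,700 trios from ~3,400
families). ASD status follows a logistic liability with sex, preterm,
standardized-PRS and optional interaction terms plus a family-shared
normal intercept — a random intercept rather than marginal draws, because
only genuine within-family correlation exercises the clustered models.
Diagnostic categories are drawn from logistic models with ASD- and
preterm-dependent odds, so multimorbidity rises with ASD and falls with
gestational age; quantitative measures are normal with group shifts.

Defaults anchored to the emulated cohort's published figures: 75.9 true
DNVs per child; exonic fraction 16,155/432,903 ≈ 0.037; P(LOF | exonic)
986/16,155 ≈ 0.061; dominant inherited variants 245,671/5,712 ≈ 43.0 per
trio and recessive 4,346/5,712 ≈ 0.76; compound-het rate 0 (none were
observed; tests switch it on to exercise the pairing logic); ~10% preterm
births with stratum mix 0.08/0.12/0.14/0.66 and 6% of preterm births
lacking gestational age; male liability log-OR 1.1 (≈ 3:1 male excess
among cases), preterm log-OR 0.9, PRS log-OR 0.35, baseline log-odds
−0.6 (an ASD-enriched cohort, ~40–50% cases), family-intercept SD 0.5.
The ASD-preterm DNV rate ratio of 1.5 is the planted recovery target.
Magnitudes with no published anchor (category base prevalences 0.08–0.25,
category log-ORs, measure shifts, 200 PRS SNPs with N(0, 0.1) weights)
were chosen once for statistical power at a few hundred families and are
not tuned thereafter.

Artifact planting injects candidate records that each violate exactly one
QC filter — low GQ, low DP, common allele frequency, homopolymer allele,
excluded-region position, a matching heterozygous parent in an unrelated
family, the same candidate in children of four families, or a four-ALT
site — labelled in the truth set with the expected rejecting filter, so
the cascade's per-filter audit is verifiable record by record. Because
each artifact violates exactly one rule, a mis-attributed rejection is
detectable, not just a missed one.

What passing these tests shows, and does not: the pipeline applies its
stated rules exactly, the clustered estimators recover planted effects at
realistic sample sizes, and the classifier finds planted birth-feature
signal; none of this certifies performance on real sequencing data, where
artifacts co-occur, annotations err, and effects are smaller.

## Problem sizes and numerics

Validation runs use 200-family cohorts for cascade specificity (~26,000
planted DNVs), 50 replicates of 300 families for parameter-recovery
coverage, 250 families for classifier controls (null: 20 label
permutations with a reduced inner loop, since tuning depth is irrelevant
under the null; positive control: five seeds with ten outer folds), sizes
chosen so each check has clear statistical resolution while the whole
suite runs in minutes. All randomness flows from explicit
`numpy.random.default_rng` seeds; a fixed seed reproduces cohorts
byte-identically. Ties in the correlation-pruning comparison and the
strict AB/threshold boundaries are covered by dedicated boundary tests.

## Known limitations

Real annotation pipelines disagree between tools; annotations here are
taken as given input fields. The X chromosome is handled only as male
hemizygosity with pseudo-autosomal regions treated as diploid; chrY is
not searched. Population phasing, CNV/SV detection, PRS weight estimation
and liftover are out of scope. The generator's diagnostic-category
magnitudes are power-motivated, not epidemiological estimates.
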