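# Methods

## Normalization model

Specimens differ in sequencing depth, so raw read counts are rescaled by a
per-specimen size factor before any comparison. The housekeeping set is
defined operationally — every miRNA with at least one read in every
specimen — and the size factor is the 75th percentile of the housekeeping
counts in that specimen (a robust upper-quartile scheme in the spirit of
DESeq-style size factors). Normalized expression is reads / size factor,
which makes the transform exactly invertible (`normalized × size factor =
raw`, tested to 1e-9 relative) and invariant to rescaling any one library.

The percentile uses the Hyndman–Fan type-7 (linear interpolation)
convention, the default of the mainstream statistical environments; a
nearest-rank alternative is exposed via `percentile_method="nearest"`.
"At least one read" is evaluated on raw counts, before normalization.

For PCA, each miRNA is divided by its row maximum so highly expressed
miRNAs do not dominate, all-zero rows are dropped (counted and logged —
max-scaling is undefined for them; they are kept everywhere else), and the
max-scaled variables are mean-centered before projection. Whether to
center after max-scaling is genuinely open; centering is the standard
choice and is configurable (`center=False`).

## Differential testing

Tests run on log2(normalized + 1). The default is a Welch unequal-variance
t-test per miRNA; a moderated alternative shrinks each per-miRNA pooled
variance toward a common prior fitted across miRNAs by the method of
moments on log-variances (digamma/trigamma moment matching of a scaled
inverse-chi-square prior, in the style of empirical-Bayes linear models
for expression data) and tests on the augmented degrees of freedom.
Multiple testing uses Benjamini–Hochberg step-up q-values.

The log2 fold change is the log2 ratio of group means with a pseudocount
(ε = 0.5 by default) in both numerator and denominator; the
difference-of-log-means reading is available as `log_ratio_fc=True` but is
not the default. The log-transform pseudocount for testing is +1. Both are
configurable; they only matter near zero counts.

The candidate filter has four clauses: expressed in all specimens (raw
count ≥ 1 everywhere), larger group mean normalized expression ≥ 50
(inclusive boundary: 50.0 passes, 49.9 does not), p < 0.05 (or BH q < 0.05
with `use_fdr`), and — in diagnostic mode only — |log2FC| > 1. The mean
clause uses the larger of the two group means; a pooled-mean variant is a
config option (`mean_rule="pooled"`). Metastatic discovery omits the
fold-change clause.

## Ratio biomarkers and decision rules

AUC is the Mann–Whitney estimator — the fraction of (case, control) pairs
where the case scores higher, ties counted ½ — computed from average ranks.
Orientation is fixed by the declared case class; a "protective" marker
reports AUC < 0.5 with no silent flipping. The ROC curve sweeps all
distinct thresholds and its trapezoidal area equals the Mann–Whitney value
(cross-checked to 1e-12).

The ratio search is exhaustive over the candidate pool: for a fixed
numerator, the AUC of numerator/denominator is computed for every
denominator, sorted descending with ties broken by denominator id.
Specimens whose denominator normalized value is 0 are excluded from that
ratio (logged), not imputed — candidate denominators are high-abundance,
so the case should not arise in practice.

Decision boundaries follow the rule's printed form strictly: the ratio
rule calls Tumor at x ≥ cutoff (Benign only when x < cutoff), and the
combined rule calls Benign only when x < 0.06 **and** CA19-9 < 300 U/ml.
Consequently the combined rule's Tumor region is a superset of the ratio
rule's, so its sensitivity can never be lower (tested as a set-inclusion
property). A missing CA19-9 degrades the combined rule to the ratio-only
rule with a logged warning. How the 0.06 and 0.15 cutoffs were originally
derived is not documented; they ship as fixed defaults with a Youden-index
maximizer (`strategy="youden"`, ties toward the smaller cutoff) as the
data-driven alternative. Sensitivity and specificity are percentages
rounded half-up to one decimal.

## Bayesian network

Normalized expression is binarized per miRNA at its median (high iff value
≥ median; even-n medians are midpoints, so a constant row is all-high),
and three pathology indicators are appended: cancer (PDAC), pancreatitis
(CP), metastasis (M1 PDAC only). Structures are scored with the BIC for
multinomial data: per family, the conditional log-likelihood of the child
given each parent configuration minus ½·ln(n)·(r−1)·q free parameters
(0·ln 0 = 0). A BDeu score (equivalent sample size 1) is available as an
option; which score the original analysis used is unknown, so both knobs
are exposed. Pathology nodes are unconstrained — miRNAs may sit upstream
or downstream of them.

Search is greedy over single-edge additions, deletions and reversals with
a tabu list of the last 10 *visited structures*; when no move improves,
the least-worsening non-tabu move is taken for up to 10 iterations without
a new incumbent. The structure-based list (rather than a move-based one)
is essential: score-equivalent DAGs form net-zero move cycles that a
move-based list cannot break, and escaping them is exactly what lets the
search recover collider structures. The search is fully deterministic —
moves are enumerated in lexicographic order, first best wins — and
acyclicity is checked before every application. `exhaustive_search`
enumerates every DAG on ≤ 4 variables (each unordered pair assigned
none/→/←, cyclic assignments discarded) as the optimality oracle; tabu
search matches its score on all 25 three-node generating structures at
n = 1000. "Causes" and "consequences" of a node are its parents and
children in the learned DAG, with the induced subnetwork over that
neighborhood. Full 337-node learning is supported, but the pipeline's
default restricts the network to the ~27 most abundant miRNAs plus the 3
pathology nodes (30 nodes), which is the scale the validation suite
exercises; the published node/edge totals are data-dependent and not
reproduction targets.

## Survival

Kaplan–Meier estimation and the two-group log-rank test are delegated to
lifelines and wrapped in light containers; tests verify them against a
hand product-limit computation and a hand-built hypergeometric table sum.
Ties of deaths and censorings at a time follow the standard convention
(deaths first, censored specimens still at risk). The KM median is the
earliest time with survival ≤ 0.5 (infinite when never reached). No
continuity correction is applied in the log-rank statistic. Ratio
stratification is strict: "above" requires value > cutoff, so exact
equality falls to "below". The external-cohort survival validation of
metastasis candidates is replaced by an internal filter: a candidate is
retained only if its median split yields log-rank p < 0.05 on the supplied
survival table.

## Synthetic cohorts

The generator emulates the study design the pipeline assumes, not any
particular dataset. Counts are negative-binomial with mean
a_m · s_j · 2^effect(m, group(j)) and variance μ + φμ² (dispersion
φ = 0.1 by default, a typical bulk-RNA-seq value); baselines a_m are
log-uniform over 10^0–10^4 reads and library factors s_j are
log-normal(0, 0.25). The defaults mirror the study conditions: 30 PDAC /
18 CP (training), 40% of PDAC metastatic, 334 miRNAs (337 network nodes
once the 3 pathology indicators are added), PDAC CA19-9 560.7 ± 496.7 U/ml
and CEA 5.5 ± 4.0 ng/ml. CP CA19-9/CEA moments are not published; defaults
of 24 ± 15 U/ml and 2.5 ± 1.5 ng/ml represent a typical benign range and
are configurable. Clinical covariates are log-normal with moments matched
exactly (verified within 3 SE at 10,000 draws).

Four planted markers are named for the roles they emulate: a diagnostic
pair (numerator up 2^2 in PDAC, denominator up 2^2 in CP) and a metastasis
pair (up in M1 / up in M0, 2^1.5 — the weaker of the two signals, as in
the motivating data). Planted baselines sit at high abundance
(25 × the top of the baseline range) so they clear the mean ≥ 50 clause
the way real candidates do, and the denominator baselines are scaled so
the group-geometric center of each planted ratio lands at the scale of its
decision cutoff (≈ 0.06 diagnostic, 0.15 metastatic) — this makes the
fixed published cutoffs meaningful on simulated data. The top-abundance
decile is floored at 1 read per specimen, guaranteeing a housekeeping
pool. Survival is exponential with hazard h₀ · exp(β · ln marker); the
default h₀ is calibrated so a patient at the 0.15 metastatic cutoff has a
median OS of ~413 days, and censoring is uniform on (0, 1500] days. One
global seed feeds three spawned streams (counts, clinical, survival), so
each component is reproducible independently.

What the generator does **not** emulate: hemolysis and EV-isolation batch
effects, read-level artifacts, heavy-tailed abundance distributions,
miRNA–miRNA correlation structure beyond the planted effects, and
non-proportional hazards. Passing recovery tests therefore demonstrates
that the pipeline finds the structure it is designed to find under its own
model assumptions — not that the published biomarkers are correct. The NB
count model itself is an assumption; the source analysis does not describe
its count distribution.

`analytic_ratio_auc` provides the closed-form recovery target: when the
log-ratio is normal in both groups with common SD σ and mean difference Δ,
the AUC is Φ(Δ/(σ√2)). For the planted pair, Δ = 2·log2fc·ln 2 and
σ² ≈ 2(φ + 1/μ) by the delta method (library size cancels in the
quotient).

## Validation sizes and numerical choices

The default test suite and the acceptance script use: 1,000 random
instances for the AUC-vs-enumeration oracle; 200 simulated cohorts for
ratio-pair recovery; 1,000 miRNAs for the null calibration of the
differential tests (binomial 99% bounds around 0.05); all 25 three-node
generating DAGs at n = 1,000 for tabu-vs-exhaustive equivalence; 200 seeds
at n = 200 for cancer-child neighborhood recovery; 500 replicates for the
log-rank type-I error. Module-level recovery examples run at reduced
replicate counts (20–50) chosen to keep the default suite fast while
retaining power against the asserted rates. Score comparisons use a 1e-12
improvement threshold (tabu) and 1e-9 equality tolerance; confusion
percentages round half-up to 1 decimal; degenerate inputs (all-zero rows,
zero denominators, one-class labels, zero events) raise or are dropped
with a logged count as documented per function.

## Known limitations

- The moderated test uses a moment-matched prior, not the exact REML fit
  of the reference empirical-Bayes implementations; with very few miRNAs
  the prior-df estimate is unstable (it falls back to complete shrinkage).
- Tabu search is a local method; optimality is only guaranteed against the
  enumeration oracle at ≤ 4 nodes, and larger networks are heuristic.
- The pipeline treats the train/test split as given; it does not perform
  cross-validation or nested selection.
- Healthy controls flow through normalization/PCA as a third label but do
  not participate in the diagnostic contrasts.
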