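# Methods

This note documents the models and procedures implemented in `cranesig`,
the numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the known limitations.

## 1. Phenotype definition

Patients with a pretreatment history, a prior glioma, or unknown vital
status are excluded. The remaining *deceased* patients are ranked by
survival days; the bottom and top fractions (default 0.25 each, counts
floored) become the short-term (STS) and long-term (LTS) survivor classes.
The cutoffs induced by the split are recorded (the GBM cohort design this
package models corresponds to < 225 and > 635 days). Alive patients whose follow-up
exceeds the upper cutoff can optionally be admitted to LTS
(`admit_censored_lts`, off by default: censored survival is not observed
survival, and the primary definition uses deceased patients only).

## 2. Binarization

Expression is binarized **per gene across the cohort's samples**: values
at or above the gene's `1 - top_fraction` linear-interpolation sample
quantile are H (high), the rest L. Defaults: `top_fraction = 0.25` (top
quartile H). Ties at the threshold go to H so that borderline high values
are not silently dropped. Because the rule depends only on within-gene
ranks, binarization is invariant under strictly monotone per-gene
transforms; constant genes have no top quartile and are set all-L with a
warning. An independent test cohort is binarized with its own quantiles
(not the training cohort's thresholds), absorbing platform shift.

## 3. State functions, J-values, mutual information

For an ordered gene list (g1..gk) forming a connected subgraph of the PPI
network, each sample exhibits a state function f — its H/L string. With
phenotype class C ∈ {STS, LTS} and subnetwork state variable F, the
plug-in estimates over the labeled samples are

- support σ(f) = n(f)/n,
- confidence = p(f | LTS), anti-confidence = p(f | STS)
  (confidence is read literally as the fraction *of long-term survivors*
  showing the state; the posterior reading p(LTS | f) is available as a
  derived accessor but is not used in scoring),
- J(f) = Σ_c p(f, c) · log2( p(c|f) / p(c) ),
- I(C;F) = H(C) − H(C|F) = Σ_f J(f)  (exact identity, asserted to 1e-10).

All logarithms are base 2 (bits). Probabilities are maximum-likelihood
plug-ins with no pseudocounts; unobserved states contribute nothing
(0·log 0 = 0).

## 4. Subnetwork search

Candidates are connected subgraphs of at most `d_max` genes (default 10)
over the genes shared by the network and the matrix.

**Exhaustive mode** enumerates every connected subset (ordered-extension
enumeration, each subset produced exactly once) and ranks by plug-in
I(C;F). It is selected automatically whenever at most `max_exhaustive`
subsets exist, and is the correctness contract for the heuristic search:
on small graphs the best candidate equals the enumeration maximum by
construction, which the test suite verifies against an independently
written oracle.

**Beam mode** is a seeded beam search: every gene seeds a candidate;
candidates grow one adjacent gene at a time; per seed and per size the
`beam_width` (default 5) best extensions survive, scored by their best
single-state J-value (supported-MI as tiebreaker — a true module gene
preserves *all* of a parent's states, a lucky noise gene only the best
one). Beam selection guarantees each surviving parent its best child
before filling remaining slots, so one high-J lineage cannot monopolize
the beam. Already-grown gene sets are not re-expanded from later seeds.

**Honest ranking.** At realistic sample sizes the in-sample plug-in MI is
useless as a ranking score: a 10-gene subnetwork induces up to 2^10
states, most observed states are singletons, and H(C|F) collapses toward
0 for *any* candidate — maximizing in-sample MI over ~10^5 visited
candidates returns pure selection artifacts (e.g. "cover sets": genes
whose H samples jointly cover one class, leaving a large spuriously pure
state). The beam-mode ranking therefore mirrors the two-stage logic of
identifying high-scoring subnetworks by their J-values and then sorting
those by mutual information, with three guards:

1. **Supported states only.** The ranking MI sums J over states with
   support ≥ `min_support` (default 0.10) of the scoring fold; rare states
   are noise at these sample sizes.
2. **Minimum over two folds.** The labeled samples are split into two
   stratified folds (deterministic given `seed`); a candidate's score is
   the *minimum* of its fold scores. Chance structure does not replicate
   across folds, so selection artifacts gain nothing; moreover each
   irrelevant gene fragments real states on its weak fold and actively
   costs score.
3. **ε-maximality.** Candidates within a fraction `epsilon` (default
   0.25) of the best score are statistically indistinguishable at these
   fold sizes; among them the maximal subnetworks are reported first
   (size, then score, then lexicographic tie-break) — the maximality
   convention of subnetwork pattern mining. Internal parameters were fixed
   on development simulations and confirmed on held-out seeds.

Reported `Subnetwork.mutual_information` is always the full-sample plug-in
I(C;F), so the J-decomposition identity holds for every returned state
table. Runs are deterministic given the seed.

**Signature composition** greedily scans the ranked candidates, skipping
any candidate sharing a gene with an already selected one, until `k`
(default 5) disjoint subnetworks are chosen; fewer available disjoint
candidates produce a warning, not an error.

## 5. Survival classification

Features are the per-gene binary H/L states (H→1) of the union of the
top-k subnetworks — not one-hot state identities, which explode
combinatorially. The default classifier is a feed-forward neural network
with one hidden layer as wide as the feature vector, logistic activations,
Adam, fixed seed. Early stopping on a 20% validation split is enabled only
for cohorts of ≥ 200 samples: on smaller cohorts the validation accuracy
(the stopping signal) is too coarse and halts training before anything is
learned; smaller cohorts instead train to convergence under a fixed
iteration cap. A deterministic logistic-regression model is available via
`model="logistic"`.

Cumulative evaluation retrains at each k = 1..k_max and reports accuracy
(S + L)/T and per-class positive predictive value on the test cohort; all
reported rates are exactly recomputable from the confusion counts in the
same report. PPV of a never-predicted class is NaN with a warning.

## 6. Centroid subtype assignment

Arrays are log2-transformed (configurable pseudocount shift if
non-positive values are present), median-centered per sample, and scaled
by the per-sample standard deviation (n−1 form); probe-level rows are
averaged into gene symbols after processing. Each sample is assigned to
the centroid with maximal Spearman correlation over the genes shared
between sample and panel (per-sample intersection; minimum 3 genes).
Ties break to the first subtype in declared column order, with a warning.
Assignments are invariant to monotone per-sample transforms.

## 7. Survival statistics

Kaplan-Meier curves use the product-limit estimator (lifelines); censored
times reduce the risk set without a step. The logrank test handles tied
event times with the standard simultaneous-event (hypergeometric)
convention and returns a chi-square statistic with groups−1 degrees of
freedom; applying it to uncensored quantities (e.g. age distributions)
amounts to passing all-event flags, which is how age-distribution
comparisons are expressed here. The chi-square independence test is the plain Pearson statistic
Σ(O−E)²/E without continuity correction, with a warning when any expected
count is below 5.

## 8. Peptide-level differential expression

Pipeline order (deliberate): **impute → normalize → model**.

1. *Imputation*: a missing cell takes the median of the peptide's observed
   intensities within the sample's survival group; peptides with no
   observation in a group are dropped (logged).
2. *Standard normalization*: each peptide is z-scored across all samples
   (n−1 sd). Consequence: for every protein the normalized group means
   obey n_STS·m_STS + n_LTS·m_LTS = 0 exactly; with the 10 STS / 6 LTS
   validation design the LTS mean is −5/3 of the STS mean. The acceptance
   suite verifies this identity against a reference set of group-mean pairs from
   the 16-patient design, reproducing each implied LTS mean to 2 decimals.
3. *Mixed model*: per protein, intensity = μ + β·group + b_peptide + ε
   with a random peptide intercept, fitted by **maximum likelihood** (not
   REML, because the likelihood-ratio test compares fixed-effect
   structures). The group effect is tested by LRT against the no-group
   null, p from chi-square with 1 df. Single-peptide proteins drop the
   random effect and reduce to the ordinary two-group linear model. A
   non-converged fit — common when the peptide variance MLE sits on the
   zero boundary, which per-peptide normalization makes routine — is
   retried with the variance floored at 0 (exact OLS ML) and the better
   likelihood wins; the boundary LRT is accepted as-is since the test
   concerns the fixed effect (a mild approximation, noted). Calibration at
   the study scale (6 peptides, 10+6 samples) is verified by simulation:
   type-I error ≈ 0.04–0.05 at α = 0.05.
4. *Reporting*: group means on the normalized scale; the LTS/STS ratio
   from the **raw-scale** (imputed) intensities as the ratio of plain
   means over all peptide-sample cells (median-based ratio behind
   `ratio_stat="median"`); significance at p ≤ α with **no**
   multiple-testing adjustment — the protein sets are pre-specified, not
   discovered, and the omission is logged.

CART panels use greedy Gini splits with axis-aligned thresholds, default
depth ≤ 2 and ≥ 2 samples per leaf — enough to express a two-protein
rule at the 16-sample scale without pruning; `max_depth=0` yields a
majority stump.

## 9. Individual-marker baseline and proteomic yield

Individual gene markers are genes whose raw-scale group-mean ratio passes
a two-sided fold-change filter (≥ 2 or ≤ 1/2 by default; a log2-difference
variant is available via `fc_scale`), ranked by |t| with
t = (mean_LTS − mean_STS)/pooled sd and
pooled sd = sqrt(((n1−1)s1² + (n2−1)s2²)/(n1+n2−2)). Note this t is the
plain standardized mean difference the comparison calls for, not the
two-sample t statistic (no sqrt(1/n1+1/n2) factor). The proteomic yield of
a ranked gene set counts, per prefix size, the genes identified in the
proteome and those differentially expressed; the "rate of return" is the
ordinary least-squares slope (fitted intercept) of the DE count against
prefix size, reported as a percentage. Prefix step size is a parameter.

## 10. Synthetic-data generators

All generators are deterministic given their seed and write/consume the
exact in-memory types the pipeline reads.

**Expression cohorts.** A Barabási–Albert preferential-attachment network
(attachment 2 → heavy-tailed degrees) with planted connected gene sets.
Each planted subnetwork carries a list of states with class-conditional
probabilities (confidence = P(state | LTS), anti-confidence =
P(state | STS)); every sample draws a state or falls to background. Each
planted gene's H count is then topped up to the binarization quartile
using background samples only (class-neutral), so the quartile cut falls
in the gap between the two expression components — without this, binomial
variation in state draws corrupts ~3 cells per gene and fragments deep
states. H cells get expression `h_effect` (default 2.0) above L cells,
both with Gaussian noise `noise_sd` (default 0.2, ~10 sd separation);
unplanted genes are standard-normal noise. Survival days are
class-conditional log-normal (STS median 120, LTS median 1000, log-sd
0.35), clipped inside the 225/635-day cutoffs; middle (unlabeled) samples
fill the inter-quartile range so a 25/25% split over deceased patients
recovers the planted classes exactly.

Two planted designs are provided. `two_state_design` (one H-half state
per class) plants strong, partly gene-level signal — the appropriate
emulation of dysregulated-module data, used at conditions
confidence 0.44 / anti 0.0 in the recovery and end-to-end simulations
(design MI ≈ 0.44 bits; confidence near 0.5 would saturate the
binarization quartile and systematically clip planted H cells).
`balanced_design` (two states per class with identical per-gene marginals
across classes) plants *purely combinatorial* signal — no single gene is
informative, as in an XOR pair — and is what the pair-MI and
combinatorial tests use.

**Peptide tables.** log-intensity = protein baseline (N(14,1)) +
group effect + peptide intercept (N(0, 0.5)) + residual (N(0, 1)),
exponentiated to a strictly positive raw scale; peptides per protein are
1 + Poisson(mean−1) with default mean 3.4 (the study's 5019/1491 ratio);
default groups 10 STS / 6 LTS; missingness MCAR at a flat or
group-dependent rate (default 0.1).

**Centroid panels.** Independent N(0,1) centroids per (gene, subtype);
sample raw expression 2^(centroid + noise + 10) with true labels
returned.

What the generators do **not** emulate: multi-platform probe effects,
intensity-dependent (MNAR) missingness, retention-time artifacts,
correlated gene-gene background, or censored survival. Passing tests
therefore demonstrate correctness of the algorithms under their stated
assumptions, not performance on real cohort data, which requires real cohorts and is
out of scope here.

## 11. Problem sizes used in validation

The acceptance checks run at these scales (chosen as the package's own
validated conditions): subnetwork recovery at 2000 genes × 100 labeled
samples with one planted 10-gene module (20 seeds in the test suite, 10 in
the acceptance script); search-vs-enumeration agreement on 50 (script: 30)
random ≤12-node graphs at n = 40; mixed-model calibration on 1000
(script: 400) null proteins at the 6-peptide, 10+6-sample design;
end-to-end discovery + validation at 400 genes, five planted 10-gene
modules, 200-sample cohorts over 10 (script: 6) seeds.

## 12. Known limitations

- The beam search is a heuristic; only the small-graph regime carries an
  optimality guarantee (via exhaustive enumeration).
- The split-fold ranking spends half the labeled samples per score; on
  very small cohorts (< 8 per class) it falls back to in-sample supported
  MI with a warning.
- The boundary-variance LRT is slightly conservative in principle; the
  simulated type-I error at the validation scale is nevertheless within
  [0.03, 0.07].
- Identifier harmonization is out of scope: expression, network, and
  proteome symbols are intersected case-insensitively, with counts
  logged, and no cross-vocabulary translation is attempted.
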