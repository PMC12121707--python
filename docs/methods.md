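# Methods

`helpnet` implements the statistical chain used in brain-wide studies of
rodent helping behavior: classify which rats learn to free a trapped
cagemate, map task-evoked c-Fos activity onto that classification with a
mean-centered task PLS, build a correlation-threshold functional network,
and screen bulk expression data for group differences with a sex
covariate, a fold-change cutoff, promoter-motif enrichment, and qPCR
confirmation. This note records the models, the parameters that matter,
and the choices made where the design was genuinely open.

## Behavioral classification

The helping behavior test (HBT) runs for D days (default 12); each day
the free rat has 40 min to open the restrainer door. A pair's free rat is
an **opener** iff it opened on at least 2 of the last 3 days. An optional
alternative rule (`alt_rule_consecutive_plus_final`, off by default)
additionally accepts a rat that opened on two consecutive days and on the
final day; it exists because cohorts occasionally contain such a border
case and the call must be reproducible. Non-opening days are scored at
the 40 min maximum when averaging latencies, so a rat that never opens
has mean latency exactly 40.

Boldness roles: the rat that peeked first on >= 3 of 5 cage-top trials
becomes the free rat. The assay cannot guarantee a qualifier (ties credit
neither rat), so a tie rule is configurable; the default assigns the rat
with the lower mean peek latency, which is deterministic and uses the
same construct the assay measures. `tie_rule="error"` refuses instead.

Fisher's exact test (two-sided, point-probability method — the sum of
hypergeometric probabilities of all tables as or more extreme than the
observed one) and Pearson correlations with the t-transform p-value are
provided as utilities; both are delegated to scipy and cross-checked in
the tests against full enumeration / textbook formulas.

## c-Fos preparation

Counts are normalized to cells per 250 µm² (`count * 250 / area`), which
makes differently sized sampled areas comparable. Regions with fewer than
3 observed values in **any** condition are excluded; remaining missing
cells are filled with the mean of the observed values for that region
within the same condition. The order is fixed — exclusion, then
interpolation — because interpolating first would let imputed values
rescue regions the sparsity rule should drop; a test pins the order.
Condition-mean interpolation preserves per-(condition, region) means
exactly, which the permutation and bootstrap machinery relies on.

Whether densities should be re-weighted by slice counts is left to the
upstream quantification: the reader accepts an optional `n_slices`
column but treats each (subject, region) density as final.

## Mean-centered task PLS

Let X be the n x p density matrix and M the k x p matrix of condition
means. The decomposition is the SVD of

    R = M - mean_rows(M),

where `mean_rows` is the **unweighted** mean of the k condition rows (not
the subject-weighted grand mean), so unbalanced groups do not tilt the
centering; a `subject_weighted` mode is available. Each latent variable
pairs a condition contrast u_i, a region salience pattern v_i, and a
singular value s_i; at most k-1 are non-null, and singular values below
1e-10 x s_1 are dropped as numerically null. Brain scores project subject
rows, centered by the same unweighted grand-mean row, onto V. For k = 2
the decomposition has a closed form (salience = normalized mean
difference, s_1 = ||d||/sqrt(2)) used as an oracle in the tests.

**Permutation test.** Condition labels are shuffled over subjects without
replacement (unstratified), the centering and SVD recomputed, and
p_i = (1 + #{s_perm >= s_obs}) / (1 + n_perm) with n_perm = 500 by
default; the add-one convention keeps p > 0. Under a simulated null the
LV1 rejection rate at alpha = 0.05 is within the exact binomial interval
(the test suite re-verifies this with 500 simulated datasets).

**Bootstrap ratios.** Subjects are resampled with replacement within
condition (n_boot = 500); each draw's decomposition is aligned to the
original by an orthogonal Procrustes rotation computed from the unit
saliences (collapsing sign and axis-order indeterminacy; a sign-flip-only
mode covers the L = 1 case). The bootstrapped quantity is the
singular-value-weighted salience V diag(s) — for two groups, the centered
mean-difference pattern itself. Bootstrapping the unit-normalized
saliences instead would understate the SE: normalization projects each
draw onto the unit sphere and shrinks its fluctuations by roughly 30% in
our simulations, inflating null bootstrap ratios and the false-positive
rate. BR = weighted salience / bootstrap SD; |BR| > 2.57 (the two-sided
99% normal point) flags a region as reliable. Because the null BR is
closer to a t variate with group degrees of freedom than to a standard
normal, the realized null flagging rate at small n is ~2-3%, not 1%;
at the simulated effect size of 1.5 SD with 10 + 10 subjects this yields
sensitivity ~0.8 and false positives <= 5%.

The single integer seed expands into independent named streams for the
permutation and bootstrap draws, so changing `n_perm` never perturbs the
bootstrap sample path.

## Correlation network

Pairwise Pearson correlations of region densities across the subjects of
one condition (constant regions yield NaN with a warning, never a silent
zero). The cutoff is the value at rank ceil((1 - fraction) * Npairs) of
the ascending-sorted upper triangle with fraction = 0.10, and edges
require r **strictly above** it — so with 10 pairs exactly the single
largest correlation survives, and a fully tied matrix yields no edges
(documented degenerate case). The decile is taken over signed
correlations (the strongest positive couplings) by default because the
network is meant to capture co-activation; `mode="absolute"` ranks |r|
instead. Regions with degree >= 1 count as connected to the network.

Clusters come from average-linkage hierarchical agglomeration on the
distance 1 - r over the full correlation matrix, with k supplied by the
user (k = 4 is the pipeline default); the method is deterministic and
order-invariant, but the cluster count is an interpretation, not an
estimate — a dendrogram cut, with Leiden/modularity detection available
through the networkx export for users who prefer it. The
region-by-behavior screen reports per-region Pearson r with raw p and a
0.05 flag (matching how such screens are conventionally reported) plus a
Benjamini-Hochberg column for multiplicity-aware readers.

## Expression arm

Per gene, ordinary least squares of log2(TPM + 1) on intercept + group +
sex; the pseudo-count of +1 TPM is configurable (`log_offset`) since no
single convention dominates. The group coefficient is a log2 fold change
(FC = 2^beta), its t statistic uses m - 3 degrees of freedom, and a
rank-deficient design (sex confounded with group) is refused by name.
The DEG screen is inclusive at the boundary: FC >= 1.5 is up,
FC <= 1/1.5 is down.

**TFBM statistic.** For motif m, log2[(mean promoter count over up genes
+ 0.5) / (mean over down genes + 0.5)]; the additive 0.5 stabilizes
sparse motifs. The statistic is antisymmetric in the two sets. The motif
count matrix is an input — promoter scanning and match stringency live
upstream.

**Bootstrap SE (200 cycles).** Genes are resampled with replacement;
each drawn gene carries its intact fitted + residual expression vector
(within-gene dependence across samples preserved) and its motif counts.
The model is re-evaluated on the pseudo-data, the screen re-derives the
up/down sets, and the statistic is recomputed; the SD over cycles is the
SE, z = statistic/SE, p = 2 Phi(-|z|). Two tempting alternatives fail
and are deliberately rejected: reassigning per-gene residual vectors to
other genes' fitted values changes no coefficient (OLS residuals are
orthogonal to the design — the bootstrap SD is exactly zero), and
resampling per-sample residual vectors conditions on the observed motif
counts of the stably selected genes, understating the null SE several
fold. Under the gene bootstrap, simulated null motifs reject at roughly
the nominal rate (~5-8% at alpha = 0.05) and a planted 4x promoter
enrichment gives z >= 4. Cycles with an empty up or down set are skipped
with a warning; more than 20% skipped aborts, since the DEG signal is
then too weak for the SE to mean anything.

**ddCt.** Per sample, dCt = Ct_target - Ct_reference; ddCt subtracts the
reference group's mean dCt; FC = 2^-ddCt. The reference group's geometric
mean FC is exactly 1 by construction, and adding a constant to all target
Cts rescales every FC by the same factor, leaving group ratios invariant.
The companion two-sample test is Student's (pooled variance, integer
n1 + n2 - 2 df), the convention qPCR reports with 5 + 5 designs use.

## Synthetic data

The generators exist so that every stage has a parameter-recovery test
with known ground truth, and their defaults mirror the scale of the
studies this pipeline serves: 137 regions; a 13-subject c-Fos cohort
split 9 openers / 4 nonopeners; 32 behavioral pairs over 12 days with an
opener fraction of 0.4375; 20 expression samples balanced over group and
sex; 5 qPCR samples per group. Densities and log2 expression use Gaussian
noise (densities truncated at zero — a mild deviation from normality,
negligible at baseline means of 5-15 cells per 250 µm²); promoter motif
counts are Poisson with a multiplicative enrichment factor in planted
up-gene promoters. Counts and areas are back-computed from the drawn
densities so the density convention round-trips exactly. Opener learning
curves draw a learning day near day 5 and open on every later day with
decaying latency, guaranteeing the classification rule recovers the
designated openers exactly; social-interaction counts couple linearly
(negative slope) to mean opening latency.

What the generators do **not** emulate: inter-region correlation
structure beyond planted blocks, overdispersed (negative-binomial) RNA
counts, batch or litter effects, hemispheric asymmetries, censored
behavioral observations. Passing recovery tests therefore demonstrate
correctness of the estimators under their stated assumptions, not
robustness to the full messiness of real data.

## Problem sizes and numerical conventions

The test suite and the acceptance script run simulations at desk scale:
500 null datasets of 20 subjects x 20 regions for permutation
calibration, 20 replicates of 20 x 50 for bootstrap-ratio recovery, 20
replicates of 400-500 genes for DEG recovery, 6 replicates of 1000 genes
x 50 motifs for the TFBM bootstrap — sizes chosen so a full run completes
in minutes on one CPU while leaving Monte-Carlo error well inside the
asserted bands. Numerical tolerances: SVD reconstruction and
orthogonality to 1e-8, closed-form two-group algebra to 1e-10, formula
oracles to 1e-12. Ties: the network cutoff is tie-conservative (strictly
above), the Fisher test follows the point-probability convention, and
role-assignment ties fall back to mean latency as described.

## Known limitations

- Bootstrap-ratio thresholds inherit the normal approximation; at very
  small group sizes the realized false-positive rate exceeds the nominal
  1% (documented above).
- The TFBM z-test is a bootstrap-t without refinement; its null rejection
  runs slightly above nominal for sets of a few dozen genes.
- The cluster count k is user-supplied; nothing in the pipeline validates
  that the dendrogram supports k groups.
- The per-gene linear model assumes homoscedastic Gaussian noise on the
  log2 scale; no empirical-Bayes variance moderation is applied.
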