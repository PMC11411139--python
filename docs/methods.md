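# Methods

## Problem and approach

`connfp` quantifies how individually distinctive a person's functional
connectome is — their "brain fingerprint" — from a single resting-state
fMRI acquisition, and how that fingerprint reorganizes across clinical
groups (cognitively unimpaired, mild cognitive impairment, dementia).  A
session of T volumes over R parcellated regions is split into a first half
("test") and a second half ("retest"); each half yields a functional
connectome (FC), the R×R matrix of pairwise Pearson correlations between
regional signals.  All analyses operate on the strict-upper-triangle edge
vector (row-major, length R(R−1)/2), defined once in `connectome` and
shared by every stage.

The pipeline has four levels:

1. **Whole-brain identifiability.**  The identifiability matrix M is N×N
   with M[i,j] = corr(test FC of subject i, retest FC of subject j).
   ISelf(s) = M[s,s]; IOthers(s) = (Σ_{i≠s} M[s,i] + Σ_{i≠s} M[i,s])/(2N−2);
   IDiff = mean ISelf − mean IOthers; the identification success rate is the
   percentage of subjects whose ISelf strictly exceeds every off-diagonal
   entry of their row and column ("max" rule, the default) or their own
   IOthers ("mean" rule).  Ties count as failures under both rules, and
   IDiff is reported unscaled (no ×100).
2. **Edgewise reliability.**  Per edge, a one-way random-effects ANOVA over
   subjects × 2 sessions gives ICC(1,1) = (MS_R − MS_W)/(MS_R + (k−1)MS_W),
   k = 2.  High ICC means between-subject variance dominates session noise:
   the edge is a fingerprint.  Negative estimates are retained.  ICC(2,1)
   and ICC(3,1) are available but not used by the main pipeline, which
   leaves session-level error sources unspecified.
3. **Network reconfiguration.**  Supra-threshold edges (strict ICC > 0.6,
   the conventional "good" reliability bound) are counted within and
   between each of the eight networks (VIS, SMT, DA, SA, L, FPN, DMN, SBC).
   P_ICCo is the count over the block's edge total; R(net) =
   P_ICCo(disease)/P_ICCo(health) − 1; a 2×2 chi-square of homogeneity
   (supra/sub × within/between, no continuity correction) is Bonferroni-
   corrected ×8.
4. **Fingerprint hubs.**  A group-unspecific surrogate null draws 5
   subjects from every group per run (default 1000 runs), pools them, and
   recomputes the ICC map.  Edge p = proportion of runs with surrogate >
   real; edges with p < 0.05 keep their ICC, others are zeroed; nodal
   strength is the row mean including those zeros, and hubs are regions
   strictly above the 75th percentile of strength.

## Inference

* **Shuffled-matrix null** (IDiff, success rate): each surrogate is a
  uniform rearrangement of the N² entries of M (implemented by permuting
  the sorted entries, so results are exactly invariant to subject
  relabeling); p = (1 + #{null ≥ observed})/(B + 1), default B = 1000.
  The add-one correction keeps p strictly positive; the hub-level edge
  p-values instead default to the literal proportion rule (which can return
  0), with an add-one variant behind a flag — recommended whenever the
  p-values feed further computation.
* **Paired ISelf vs IOthers**: Shapiro–Wilk on the differences at α = 0.05
  gates a paired t-test (normal) vs the Wilcoxon signed-rank test; both are
  always reported.
* **Group effects on per-subject metrics**: a permutation F-test with
  nuisance covariates (age, sex, education, motion), default 5000
  permutations.  Among the established schemes for permuting in the
  presence of nuisance variables we use Freedman–Lane — residuals of the
  covariate-only model are permuted and added back to its fitted values —
  because it is the best-calibrated general-purpose choice for small,
  unbalanced samples and makes the group factor exchangeable under the
  null by construction.

## Quality control

Volumes are tagged from per-volume traces: the conjunctive rule requires
FD > 0.3 mm AND standardized DVARS > 1.7 AND SD above the subject's own
boxplot fence (75th percentile + 1.5·IQR, linear-interpolation
percentiles); the FD-only rule tags FD > 0.5 mm.  A subject is excluded
when strictly more than 30% of volumes are tagged; tagged volumes are
never removed — motion enters the group models as a covariate.  Note a
structural property of the conjunctive rule: because the SD fence is
computed from the same trace it thresholds, at most ~25% of volumes can
exceed it, so the conjunction alone can never drive a subject past the 30%
exclusion bound; exclusion-boundary behavior is exercised with the FD-only
rule and with the disjunctive (`combine="any"`) variant.  A region missing
in strictly more than 10% of subjects is excluded for all; sporadic
missingness is masked and statistics use available data only (per-edge
subject dropping in the ICC, common-edge masking in the identifiability
matrix).  Splitting an odd-length session drops the single middle volume,
keeping the halves equal and symmetric (a drop-the-tail policy is
available).

## Synthetic cohorts

The generator implements the minimal model under which the statistics
above have analytic ground truth: per subject s, edge e, session j,
y = mu[e] + b[s,e] + eps[s,e,j] with b ~ N(0, σ_b²) and eps ~ N(0, σ_w²),
so the true ICC is exactly σ_b²/(σ_b² + σ_w²).  Edge panels are drawn
directly from this model and are deliberately not clipped into (−1, 1) by
default — clipping would bias the analytic target.  Time-series cohorts
instead build a per-subject target correlation (template from mu plus a
subject perturbation scaled edgewise by σ_b, projected to the nearest
positive-definite correlation matrix by eigenvalue clipping at 1e−8 and
diagonal renormalization) and draw T multivariate-normal volumes, so
split-half FCs inherit the subject signature by construction.  Each
subject has an RNG substream keyed by (group index, subject index):
dropping subjects or groups never reshuffles anyone else, and identical
spec + seed is bit-reproducible.

Default study conditions: group sizes 16/32/6 (CU/MCI/AD), eight
contiguous network blocks, within-network true ICC 0.8 and between-network
0.2 (σ_w = 0.1), mean edge FC 0.3, T = 200 volumes.  Ten percent of
between-network edges are made as reliable as within-network ones: real
cohorts carry a minority of reliable long-range connections, and this
keeps healthy between-block proportions strictly positive so R(net) is
defined.  `plant_topology_shift` emulates disease reconfiguration as a
count-preserving move: the source block's supra-threshold edges lose their
subject variance and an equal number of target-block edges (lowest index
first, deterministic) gain it — reliable-edge counts are conserved, only
their topology changes, which is what flattens the disease group's
within/between proportion contrast.

What the generator does *not* emulate: hemodynamics, scanner noise
spectra, spatial autocorrelation of parcels, motion-FC coupling, or
amyloid/tau biology.  Passing tests therefore demonstrate that the
estimators and inference are correct and well calibrated under the
variance-components model — not that any clinical effect size is
reproduced.

## Numerical choices

* Bootstrap ICC draws subject subsets *without* replacement (duplicated
  subjects would violate the one-way ANOVA's independence across rows);
  with-replacement sampling is available behind a flag.  Averaging order:
  ICC per run → average → threshold.
* Percentiles use linear interpolation; all block/hub thresholds are
  strict inequalities; all-equal strengths yield an empty hub mask with a
  warning.
* Surrogate runs are streamed (running mean + exceedance counts), so
  memory is O(R²) in the number of runs, with results identical to
  retaining every run.
* Degenerate inputs: zero-variance regions are flagged missing with a
  warning; edges with fewer than two complete subjects return NaN; a zero
  contingency marginal or a zero healthy proportion returns NaN with a
  warning rather than raising.
* Matrices are written as labeled CSV at full repr precision, so
  write→read round-trips are value-exact; every pipeline run writes its
  resolved config (seeds included) next to the outputs.

## Problem sizes used in the shipped checks

Simulation-based tests and the reproduction script run at desk scale
chosen to keep Monte-Carlo error well inside the asserted bands: ICC
recovery at 50 subjects × 528 edges × 50 seeds; identifiability limits at
N = 30 (high SNR, σ_w/σ_b = 0.25) and 100 exchangeable replicates;
permutation-ANOVA calibration at 300–500 simulations × 400–500
permutations; planted-reconfiguration recovery at R = 40, groups 16/6, 20
seeds with 200 bootstrap runs.  Defaults inside the library remain at the
full values (1000 bootstrap/surrogate/permutation runs, 5000 ANOVA
permutations).

## Known limitations

* Within-session split-half fingerprinting shares slow drifts between
  halves; it is an upper bound on between-day identifiability.
* The surrogate edge-null is well calibrated when the pooled surrogate
  sample size matches the group size being tested; with very small groups
  the real and surrogate ICC sampling distributions differ and edge
  p-values become conservative or liberal accordingly.
* The 2×2 chi-square construction is one reasonable reading of "within vs
  between edge counts"; other contingency constructions are possible and
  would change absolute statistics (not the planted-shift direction).
* ICC estimates at group sizes like 5–6 are noisy; bootstrap averaging
  equalizes sample size across groups but does not remove that noise.
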