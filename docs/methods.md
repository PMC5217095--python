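# Methods

This note documents the statistical procedures implemented in
`motionqc`, the conventions and defaults chosen where a choice had to be
made, what the synthetic-cohort generator does and does not emulate, and
the known limitations.

## Framewise displacement and the summary hierarchy

FD at frame t is the L1 norm of the first difference of the six
rigid-body realignment parameters, with the three rotations converted
from radians to millimetres of arc on a 50 mm sphere (approximately the
distance from cortex to the centre of the head; `radius` is
configurable). FD is defined only for frames 2..T, so a T-frame run
yields T−1 values and the run summary is their mean (or median). An
`include_leading_zero` flag prepends a structural 0 for comparison with
tools that use that convention; it is off by default because a forced
zero deflates run means.

The participant index FD̄_all-task averages run means within task and
then task means across tasks. This two-level average intentionally
ignores run counts and frame counts: a task sampled by three runs
carries the same weight as a task sampled by one. Missing runs are
dropped from the within-task mean, never imputed.

High movers are participants with FD̄_all-task strictly greater than the
sample mean plus `k` (default 1.5) sample standard deviations (n−1
denominator). The threshold is recomputed from exactly the supplied
sample; ties at the threshold are not flagged.

## Ratings

The composite rating is the ordinal minimum (most stringent) of the
raters' pass/warn/fail judgements. Cohen's κ is the unweighted point
estimate; its confidence interval uses the Fleiss–Cohen–Everitt
asymptotic variance and its p-value the null-hypothesis standard error
with a two-sided normal approximation. Cohort rating distributions are
compared with a 2×3 Pearson contingency chi-square (df = 2, no
continuity correction); empty rating columns are dropped with a warning
and the degrees of freedom reduced. The contingency form reproduces the
published statistics exactly even though the source table's footnote
describes expected counts scaled from the reference cohort — the two
descriptions coincide numerically only for the contingency form, which
is the one implemented.

## Resampling conventions

All permutation and bootstrap p-values use the plus-one rule
(1 + exceedances)/(1 + n), so a reported p is never exactly zero. Every
randomized analysis derives its own generator from the master seed and a
stage/cell label (via `SeedSequence` spawn keys), so results are
bit-reproducible for a given (seed, n_iterations) and adding an analysis
never perturbs another's draws.

Cross-run stability uses Spearman correlations (average ranks for ties;
Pearson available behind a flag) on pairwise-complete observations, with
a one-sided (positive-association) permutation test and Bonferroni
correction over the k(k−1)/2 run pairs. One-sided upper tails are also
used for the sensitivity and specificity nulls, where the *fail* set is
redrawn uniformly without replacement from the cohort. Sidedness is a
convention choice here, recorded because the direction of each test is
scientifically unambiguous (stability and detection can only be degraded
by chance).

Pairwise rank-sum contrasts report the Mann–Whitney U of the first
group, a tie-corrected normal-approximation z (no continuity
correction), Bonferroni-adjusted two-sided p over the three pairwise
comparisons, and z²/n as an approximate rank eta-squared — the last is a
pragmatic effect-size convention, labelled approximate because it has no
exact small-sample interpretation.

## ANCOVA and effect-size change

Models are ordinary least squares with sum-to-zero contrasts for
categorical predictors. The full-factorial model (all interactions) is
fitted first with type III sums of squares; if no interaction term
reaches α = 0.05 the model is refitted with main effects only and those
terms are reported (with main effects only and sum contrasts, type III
and type II coincide). When a small factor cell makes the full
interaction model rank-deficient — e.g. three *fail* participants of one
gender cannot support per-cell slopes — the main-effects model is
reported directly and the screen marked untested; a rank-deficient
main-effects design is an error naming the aliased columns. Partial
eta-squared is SS_term/(SS_term + SS_resid).

The effect-size-change test compares the age partial η² between a model
with age and gender only and one that adds FD̄ and the QC rating. The
null permutes the (FD̄, QC) rows jointly against the fixed (age, gender,
outcome) — preserving the FD–QC dependence while severing both from the
outcome — and the upper-tail p asks whether the observed reduction
exceeds chance.

## Partial correlations, maps and FDR

The full-partial correlation of y and x given covariates is the Pearson
correlation of their OLS residuals, with a t-based p on n − k − 2
degrees of freedom. Vertex-wise maps vectorise the same residualisation
across the thickness matrix; constant vertices are reported as NaN and
excluded from the Benjamini–Hochberg adjustment with a count. FDR is
applied across the whole map for correlation maps and within hemisphere
for the group t-maps (pooled-variance t by default, Welch optional) —
per-hemisphere adjustment for t-maps follows the stated analysis
convention; for correlation maps the choice was open and whole-map
adjustment was adopted as the more conservative default.

## Matched resampling

For each flagged participant the matched pool is the `pool_size`
(default 10) retained participants of the same gender closest in age,
with ties in |Δage| broken by the lexicographically smaller ID so pools
are deterministic. The bootstrap null draws, with replacement, one pool
member per flagged participant and records the control group's mean
metric; the default lower tail asks how often a matched group is as thin
as the flagged group.

The leave-out envelope builds control groups of the same size as the
retained sample by removing one *distinct* pool member per flagged
participant from the full sample; when overlapping pools collide during
a draw, the member falls through to its next-nearest available
same-gender candidate rather than deadlocking. The envelope is the
pointwise 2.5/97.5 percentile band of the control groups' correlation
CDFs evaluated on a common grid, and the after-flagging CDF is flagged
when it exits the band anywhere (the fraction of grid points outside is
also reported). Two caveats are inherent to this construction and
verified by the test suite: the band is a pointwise, not simultaneous,
95% region, and because every control group retains the influential
high-FD participants the band is tight and the procedure is
anti-conservative under the null — treat an exit as descriptive, and
prefer the matched bootstrap for a calibrated test.

Fisher-z comparison of the age correlation before and after flagging
uses the independent-samples standard error
√(1/(n₁−3) + 1/(n₂−3)) even though the after-sample is a subset of the
before-sample; the overlap makes this an approximation (flagged as such
in the output), retained because it matches the conventional reporting
of such contrasts.

## Synthetic cohorts

The generator emulates a single-session adult lifespan protocol: ages
with a minimum of 30 per decade over 20–89 plus a uniform remainder,
~64% female, seven fMRI runs in four task categories (two passive-view
runs of 202 frames, one word task of 231, three scene runs of 171, one
rest run of 154), two T1w raters and a vertex-wise thickness matrix
(default 2,000 vertices in two hemispheres, 148 parcels — far below
acquisition resolution, for desk-scale testing).

*Motion.* A run's mean FD is log-normal:
log FD̄ = c + b·age + u_p + e_run with u_p ~ N(0, σ_b²) and
e_run ~ N(0, σ_w²). The defaults are inverted analytically from two
targets — age–FD̄_all-task Spearman ρ = 0.44 and run-pair Spearman
ρ = 0.80 (total log-sd 0.5, median FD̄ 0.12 mm at the mean age) — using
the bivariate-normal rank relation r = 2 sin(πρ/6) and the run-manifest
averaging factor. Realised correlations at n = 2,000 land within ±0.05
of the targets. Realignment files are six independent random walks whose
increments are rescaled so the computed run mean FD equals its sampled
target exactly (FD is linear in the increments).

*Ratings.* The latent T1 artifact severity is the participant's log
motion propensity plus N(0, 0.25) link noise — the premise that people
who move in one scan move in others, made explicit and tunable. Each
rater thresholds a noisy copy (rater noise sd 0.51) of the standardized
severity at fixed marginal cutpoints matching the published per-rater
rating shares; this calibration yields inter-rater κ ≈ 0.48 at large n.

*Thickness.* thickness(v, p) = 2.5 mm + slope_v·age_p + 0.02·female_p +
β·severity_p·1[v ∈ bias region] + offset_p + ε, with per-vertex thinning
slopes N(−0.006, 0.002²) mm/year, a participant-level global offset
N(0, 0.1²) mm, residual sd 0.1 mm, and the bias region a contiguous
block of parcels covering 20% of vertices in each hemisphere (echoing
regionally patterned motion effects without claiming anatomical
correspondence). The offset gives whole-brain mean thickness a realistic
age correlation (≈ −0.77) instead of a noiseless age function. The
default bias amplitude β = −2.5 mm per mm of severity is deliberately a
*stress* amplitude: it is set so that every planted feature — including
the flagged group's global mean-thickness deficit probed by the matched
bootstrap — is recoverable from a single default cohort of n = 300,
which requires the 20%-region bias to overcome the matched-null spread
set by the participant offsets. Published experimental-motion studies
suggest sub-millimetre, far smaller effects; analyses at realistic
amplitude should lower `motion_beta` (≈ −0.7 gives bias-region partial
correlations near 0.35).

What passing tests on these cohorts do *not* show: the generator has
i.i.d. Gaussian vertex noise (no spatial autocorrelation or smoothing),
a linear age effect (no nonlinear lifespan trajectories), a
single-latent artifact model (visual ratings carry no information beyond
the motion latent, so the independent QC contribution to thickness seen
in real data is absent), and no segmentation or registration error.
Recovery on synthetic data demonstrates the statistics are implemented
and calibrated correctly, not that the flagging procedure will achieve
any particular sensitivity on real cohorts.

## Problem sizes and defaults

Pipeline defaults: 10,000 permutations for correlation and overlap
nulls, 1,000 for the effect-size change, 10,000 bootstrap replicates,
1,000 leave-out control groups, pool size 10, FDR α = 0.05. The test
suite and the acceptance script use the same machinery at desk scale
(2,000-participant calibration cohorts, 200–2,000 iterations per null,
50-seed replication for the attenuation property), sizes chosen so the
full suite runs in well under a minute per heavy test while keeping
Monte-Carlo error far below the tolerances asserted.

## Known limitations

- fMRI motion is a proxy: nothing here measures motion during the T1w
  acquisition itself.
- The envelope analysis is descriptive (see above); the matched
  bootstrap is the calibrated test of group bias.
- Cohort chi-squares follow the contingency form; scaled-expected-count
  variants would give different statistics for unequal cohort sizes.
- κ's asymptotic CI can be inaccurate for very sparse categories; a
  bootstrap CI is not currently implemented.
- The generator's rating model cannot produce rater disagreements more
  than one category apart only approximately (threshold noise makes
  two-category jumps rare but not impossible), unlike stricter real
  rating protocols.
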