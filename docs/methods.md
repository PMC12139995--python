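# Methods

## Experimental design the package models

A pulse-chase degradation experiment: nascent proteins are metabolically
labeled during a pulse (default 7 days), then the labeled pool is followed
through a chase sampled at 16 h, 3 d, 7 d and 14 d, with 4 biological
replicates per timepoint. All replicates and timepoints of one brain region
× age are assumed to be quantified together in one multiplexed (TMT-style)
run, alongside wildtype background channels that carry no label and report
nonspecific binding. Quantification is protein-level reporter intensity;
non-normalized values are used throughout the enrichment and turnover
stages, because the labeled-over-background and across-timepoint intensity
differences are the signal and would be destroyed by normalization.

The first chase timepoint (16 h) is the origin of all kinetics: decay
curves are evaluated at t − t₁, so TP1 maps to t = 0 and the default model
grid is (0, 2.333, 6.333, 13.333) days. The absolute offset is retained in
the sample metadata.

## Enrichment over background

1. log2 transform; zero intensities are treated as non-detections and
   become missing (counted in the log).
2. Valid-value filter: a protein is kept if at least ⌈f·group size⌉
   replicates of some group carry a value. The default fraction f = 0.51
   (just above half) reproduces the usual per-experiment presets — 3 of 4,
   2 of 3, 2 of 2 — which can also be given literally as `"k/n"`.
3. Imputation: each missing cell in sample column s is drawn from
   Normal(mean_s − 1.8·sd_s, (0.3·sd_s)²), the down-shifted narrow Gaussian
   that emulates left-censored sub-detection-limit intensities. Imputation
   is per column; columns with fewer than two present values raise rather
   than silently borrowing global statistics. Present values are never
   altered.
4. Hit calling: per-protein mean log2 difference labeled − background and a
   two-tailed two-sample t-test. Welch's unequal-variance test is the
   default (robust at n = 3–4 replicates; a pooled-variance option exists).
   Presets: stringent log2 FC > 1 and permissive > 0, both at p < 0.05 on
   raw p values; Benjamini–Hochberg adjustment is available behind a flag
   but off by default, matching the raw-p convention of this assay class.

## Degradation trajectories

Per protein, replicate means are computed per timepoint; percent remaining
at TPk is 100·mean(TPk)/mean(TP1). Two filters, both with reason codes so
that input count = retained + Σ excluded:

- TP1 enrichment gate: log2(mean TP1 / mean background) must exceed 1.5 —
  TP1 is the point of maximal labeling, so gating there discards true
  background without penalizing late timepoints that naturally approach
  background. "Enriched > 1.5" is read as log2 fold change > 1.5, the unit
  of the computation immediately preceding the rule. A protein undetected
  in background is maximally enriched and passes; a TP1 mean of zero
  excludes the protein without division.
- Rise filter: labeled protein cannot increase during a chase, so any rise
  above 5 between consecutive timepoints marks the trajectory as
  noise-dominated and excludes it. The threshold is in percentage points of
  percent remaining (the axis's natural unit); a relative-5% variant exists
  behind a flag.

Trajectory construction is scale-invariant: multiplying a plex by any
positive constant changes nothing downstream.

## Kinetic models, AIC, half-life

Trajectories are normalized to 1 at t = 0 and fitted by least squares.

**One-level:** Λ₁(t) = exp(−k_A t), k_A ≥ 0. The 1-D objective is scanned
on a dense rate grid (half-lives 0.01–1000 days plus k_A = 0 exactly) and
polished by bounded scalar minimization — deterministic and global for this
smooth 1-D problem. Half-life = ln 2 / k_A; a constant trajectory yields
k_A = 0 and a non-finite half-life, flagged.

**Two-level (precursor pool):** label first resides in a precursor pool
(rates k_B, k_AB) before incorporation and degradation (k_A), giving

    G(t) = k_AB/(k_AB + k_A) · e^(−k_B t) + k_B/(k_A − k_B) · e^(−(k_AB + k_A) t)
    Λ₂(t) = (G(t) − G(T + tp)) / (G(0) − G(T + tp)),   T = pulse length (7 d), tp = 0

The printed form of this ratio is typographically ambiguous where the
denominator would vanish at tp = 0; the implemented form above is the
unique reading that satisfies the required boundary conditions Λ₂(0) = 1
and Λ₂(T + tp) = 0 while preserving the functional shape. The reading,
pulse length and tp are configurable and recorded in fit metadata. Fitting
is bounded multi-start local least squares over (k_A, k_B, k_AB) with
|k_A − k_B| kept above a separation tolerance (the curve is singular at
k_A = k_B); start rates span half-lives 0.1–100 days, or center on the
one-level rate when available. Because a chase curve cannot rise, monotone
solutions are preferred among local optima of comparable RSS (within 4×);
rises below 10⁻⁶ count as numerical noise, and a non-monotone winner is
flagged. Non-convergence marks the fit failed. Half-life is the 50%
crossing of the fitted curve by linear interpolation on a dense grid
(horizon 200 days; non-finite beyond it).

**Selection:** AIC = n·ln(RSS/n) + 2k with natural log, k = 1 vs 3. The
lower AIC wins; ties and failed two-level fits fall back to the one-level
model (parsimony). RSS is floored at 10⁻¹² before the log so perfect fits
do not produce −∞.

A model-free half-life is also provided: the first downward crossing of 50%
remaining, linearly interpolated between bracketing timepoints; undefined
if the trajectory never reaches 50%. On noiseless single-exponential data
both estimators bracket the same grid interval and coincide as the grid
densifies.

**Age and region comparisons:** per-protein log2(aged/young half-life),
non-finite pairs excluded with a logged count, paired t-test on log2
half-lives, and a regional-vulnerability table flagging proteins whose
half-life fold change differs between two regions by more than 1 log2 unit.

## Trajectory clustering and aging scores

Fuzzy c-means is implemented directly (membership update
u_ij ∝ d_ij^(−2/(m−1)) normalized per protein; centroid update weighted by
u^m), iterated until the objective changes by < 10⁻⁷, with the objective
asserted non-increasing. Fuzzifier m = 2 (conventional default).
Trajectories are clustered on raw percent-remaining values — the shared
100% origin already aligns them — with a z-score option behind a flag. Hard
labels are argmax memberships, ties broken toward the lowest cluster index.

Cluster number: for each candidate c the minimum pairwise centroid distance
is computed. This distance stays large while every centroid claims a
distinct real cluster and collapses once two centroids must share one, so
the chosen c is the left endpoint of the last drop reaching 25% (the
configurable fraction) of the largest observed drop; a manual override is
provided. Clustering is deterministic under a seed and invariant to protein
order.

Older ages inherit the young model's hard labels by protein identity
(proteins absent from the young model are excluded with a logged count).
Aging is scored per protein by the trapezoidal area under the trajectory;
the delta integral is aged minus young area (positive = slower degradation
with age), averaged per cluster, compared across clusters by one-way ANOVA
with Tukey HSD (clusters of < 2 members keep their average but leave the
ANOVA). Per-protein least-squares slopes of percent remaining vs time are
summarized the same way.

## Set overlap

Venn partitions of 2–3 deduplicated protein lists into exclusive regions;
pairwise overlaps are totals (any triple region included). Enrichment of an
observed overlap o between sets of sizes a and b against a background of N:
expected = a·b/N, enrichment = o/expected, and p = P(X ≥ o) for
X ~ Hypergeom(N, a, b) — upper tail, inclusive of the observed count. The
default background N = 3787 (the maximal labeled neuronal proteome) is
used only when the caller supplies none, and is logged. The three-way
expected count uses the independence approximation a·b·c/N², flagged as
such in the output. Burden summaries count focal-list members carrying at
least one aberration (union of aberration lists), reported as count and
percent to two decimals. log2 fold changes are convertible to percent
change as 100·(2^fc − 1).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the mass spectrometer: per-protein baselines are log-normal (median 10⁶,
log-sd 1); labeled channels decay as the one-level curve (or, for a
configurable fraction, the two-level curve clipped at zero — label is fully
chased out at its zero crossing); background channels share each protein's
baseline and noise model but are constant in time at a configurable
fraction of TP1 (default 0.1, i.e. ~3.3 log2 units below); measurement
noise is multiplicative log-normal parameterized by CV (mean exactly 1), the
natural model for positive, heteroscedastic reporter intensities;
missingness is missing-at-random at the measurement level — the
intensity-dependent (left-censored) missingness that the imputation model
presumes is deliberately not simulated, since no mechanism is specified for
it. True half-lives are log-normal (default median 5 days, log-sd 0.5);
planted clusters shift cluster medians log-spaced over a configurable fold
range; the aged condition multiplies every half-life by a configurable
fold. Young/middle/aged plexes from one seed share the same protein cohort
(rates, baselines, clusters) with independent noise, so cross-age analyses
are biologically paired by construction.

Noise magnitude and dropout rates are free parameters, not estimates of any
particular dataset: defaults (CV 0.1, dropout 0) are plausible for
well-behaved reporter-ion data. Consequently, passing tests demonstrate
correctness of the estimators under the assumed generative structure; they
do not certify performance on real LC-MS data with ratio compression,
co-isolation interference, or intensity-dependent missingness, none of
which are simulated.

Protein-set fixtures are built by slicing a shuffled universe according to
exclusive Venn-region counts, so requested intersection structures hold
exactly; infeasible plans (regions exceeding set sizes or the background)
raise.

## Pipeline and reproducibility

All stage parameters live in one config that round-trips through YAML and
rejects unknown keys. One root seed is split into per-stage seeds (all
below 2³¹); identical config + seed reproduces byte-identical numeric
outputs. Every report carries package version, UTC timestamp and a config
hash. Stages never mutate inputs on disk; every excluded protein is counted
by reason so input = retained + Σ excluded.

## Problem sizes and numerical choices

Simulation-based checks use 150–500 proteins: large enough that binomial /
Monte-Carlo error is well below the asserted margins, small enough to run
interactively. Optimizer tolerances are scipy `least_squares` defaults;
FCM convergence tolerance 10⁻⁷ with a 300-iteration budget (non-convergence
raises with diagnostics); the half-life interpolation grid is 4001 points
over 200 days (resolution 0.05 d).

## Known limitations

- The two-level model with 3 parameters against 4 timepoints is weakly
  identified; distinct parameter sets can fit the sampled points almost
  equally well. The monotonicity preference and the AIC fallback to the
  one-level model mitigate but do not remove this.
- No cross-plex normalization or isotopic-impurity correction; inputs are
  assumed to be single-plex, protein-level, non-normalized intensities.
- The three-way overlap expectation is an independence approximation.
- Hard (not fuzzy) membership is used when projecting older ages onto young
  clusters.
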