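# Methods

## The inference problem

The unit of replication is the well: 3–5 worms are tracked together and
their feature values averaged into a single vector per well per recording
window (pre-stimulus, blue light, post-stimulus; 2763 features per window
by default, 8289 after concatenation). Wells are replicated across
independent tracking days, and everything recorded on the same day shares
day-level variation (temperature, humidity, food batch, rig state). When
strains are not measured evenly across days, that shared variation
masquerades as a strain effect under any test that treats wells as
exchangeable. The analyses here therefore treat the tracking day as a
block throughout.

## Day-blocked permutation t-test

For each feature, the observed two-sample statistic is the pooled-variance
t (Welch available via `statistic="welch_t"`; pooled is the default because
within-block exchangeability under the null is exactly the assumption the
permutation scheme encodes). For each of B Monte-Carlo permutations,
group labels are shuffled uniformly and independently within each day
block, preserving per-block group counts; blocks containing a single group
contribute no exchange. Sampling is with replacement from the blocked
arrangement space (standard Monte-Carlo practice, unbiased). The
two-sided p-value uses the add-one estimator

    p = (1 + #{|t_perm| >= |t_obs|}) / (1 + B),

which is strictly positive and valid for any B. Defaults: B = 100,000,
FDR level q = 0.05.

Numerical choices:

- **Missing values** are handled by per-feature pairwise deletion; a
  feature is skipped (with reason) if either group retains fewer than
  `min_finite_per_group = 2` finite values. Skipped features are excluded
  from the BY family. The testing path never imputes.
- **Zero variance in both groups**: t is defined as 0 (p = 1), so constant
  features cannot become spuriously significant. Zero pooled variance with
  unequal means gives t = ±∞, which the comparison logic handles exactly.
- **Degenerate permuted assignments** (a group left with fewer finite
  values than the minimum, possible only through missingness) count as
  extreme, which is conservative.
- **Ties** between |t_perm| and |t_obs| are counted as exceedances, with a
  1e-12 relative tolerance guarding floating-point noise.
- **Row-order invariance**: wells are sorted internally by (block, group,
  feature values) before the permutation stream is drawn, so permuting the
  input rows cannot change any p-value for a fixed seed.

An exhaustive oracle enumerates the Cartesian product of within-block
label arrangements (bounded at 10⁶) and returns the exact permutation
p-value; the test suite checks the sampled estimator against it to 0.01
absolute on random small instances.

## Multiple testing

The Benjamini–Yekutieli step-up is applied across all tested features of
one comparison (one strain vs control, or one treatment vs untreated);
separate comparisons are separate families, so per-strain significant
counts are comparable. With m tested features and c(m) = Σ_{i≤m} 1/i, the
i-th smallest p receives candidate p·m·c(m)/i and the adjusted value is
the running minimum from the top rank down, capped at 1. BY is valid
under arbitrary dependence — appropriate here because behavioural features
are strongly correlated (speed measured on different body parts, for
instance). Significance is strict: adjusted p < q. NaN entries (skipped
features) pass through and do not count towards m.

## Kruskal–Wallis screens

Compound-screen comparisons across k ≥ 2 condition levels use the
tie-corrected Kruskal–Wallis H referred to a chi-square with k − 1 degrees
of freedom (delegated to `scipy.stats.kruskal`), followed by the same BY
correction. Features constant across all wells, or with fewer than 2
finite values in any level, are skipped with a reason.

## Fingerprints and phenospace

Z-scores are computed per feature over all wells pooled across strains
(sample SD, n − 1); features with zero SD or fewer than two finite values
are dropped with a warning. For clustering and PCA only, residual NaNs
are imputed to 0 (the grand mean on the z scale) and the imputation count
logged. Fingerprint rows are strain means of z-scores; rows and columns
are clustered with average linkage on Euclidean distances (the common
clustermap default; both are configurable).

The phenospace PCA is fitted on well vectors pooled across strains and
windows — not on strain means — so per-stratum dispersion is estimable.
Centroids are per-(strain, window) means of well scores; error bars are
per-axis SDs by default (SEM available). The recovery score for a strain
is r = ‖c_post − c_pre‖ / ‖c_blue − c_pre‖ in the retained component
space (2 components by default); r > 0.5 flags a non-recovering strain,
and r is undefined (NaN with a warning) when the stimulus displacement in
the denominator is below 1e-12. The threshold is exposed because the
underlying judgement — "does the strain return towards baseline?" — has no
canonical cut-off; 0.5 (returning at least half-way) separates the
generator's relaxing and non-relaxing configurations cleanly.

## Pulse-aligned response statistics

Time runs in seconds from recording start, frames are 0-based at fixed
fps, and all windows are half-open [start, stop) so boundary frames are
never double-counted. The default protocol is 300 s pre-stimulus, 360 s
blue light with three 10-s pulses starting 60, 170 and 280 s into the
segment (the "100 s apart" gap reading; configurable), 300 s
post-stimulus, at 25 fps. Analyses align to the first pulse by default.

Fraction-moving curves divide worms in the requested motion mode by
detected worms per frame and well, average wells within each
biological-replicate day, then average days. The 95% band is a percentile
bootstrap that resamples wells within day (B = 1000, seeded) — the well is
the replicate unit, and day-first averaging keeps unbalanced days from
dominating. The curve method itself was unconstrained by any convention;
the percentile bootstrap was chosen as the simplest scheme respecting that
hierarchy. Scalar response features reduce (mean or median) frame values
over 10-s windows centred −5, +10 and +20 s relative to pulse onset,
i.e. [t₀−10, t₀), [t₀+5, t₀+15), [t₀+15, t₀+25).

Skeleton plausibility filtering keeps records with length in [700, 1300]
and width in [20, 200] µm, bounds inclusive at both ends to match the
range phrasing. Well exclusion for contamination or agar damage is a
metadata flag (`is_bad_well`) honoured by all loaders; no automated
detection is attempted.

## Synthetic-data generator

The generator emulates the screen's statistical structure, with known
ground truth, for calibration and power testing. Feature entries follow

    y = mu_f + beta_{strain,f} + shift_w + delta_{day,f} + eps,

with baselines mu_f ~ N(0, 1), day effects delta ~ N(0, sigma_day²) per
(day, feature) shared by all wells tracked that day, per-window shifts
modelling the stimulus state, and well noise eps ~ N(0, sigma_well²)
(Student-t with matched SD behind the heavy-tail option, default off —
additive Normal structure is the simplest that exposes what the blocked
test is for). Strain effects are drawn for a configurable fraction of
features from a configurable distribution, in units of sigma_well, and
recorded exactly in the ground-truth table. NaNs are injected uniformly
at random. Defaults reflect the screen's conditions: 3–5 worms per well,
2763 features per window, wells replicated across independent days,
5% missingness, sigma_day = 0.5·sigma_well, blue-light shift of one well
SD with partial (0.25) post-stimulus retention.

The `confounded` day assignment places even-indexed strains mostly on
early days and odd-indexed strains mostly on late days with a configurable
overlap — balanced designs cancel day effects and cannot demonstrate
naive-test inflation. A single global seed fans out to per-purpose
substreams (baselines, effects, day effects, noise, NaN mask, worm counts,
timeseries), so enabling one generator never perturbs another, and
identical config + seed gives bit-identical output.

Locomotion is a three-state (forward/paused/backward) Markov chain
discretized at the frame interval (P = I + Q·dt, rejected if any total
exit rate exceeds the frame rate). During a pulse the rates switch to a
pulse matrix biased towards reversal; after pulse end they relax
exponentially (tau = 5 s) back to baseline. Initial states are drawn from
the baseline chain's stationary distribution. Speeds are state-conditional
means (+250/0/−150 µm/s) plus Gaussian noise.

What the generator does *not* emulate: real Tierpsy feature definitions
and their correlation structure (synthetic features are independent given
the day effect), worm-to-worm heterogeneity within a well, rig and plate
effects beyond labels, drifting baselines within a recording, and
non-random missingness. Passing calibration and power tests on this
generator therefore demonstrates correctness of the statistical machinery
under the assumed hierarchical model, not performance guarantees on any
particular real screen.

## Sub-sampling power analysis

Each draw samples n wells per group without replacement (independently
across draws), applies Student's two-sample t-test per feature, and
BY-corrects within the analysed feature subset per draw — the subset is
the family, and it is recorded in the report. Draws deliberately ignore
day blocks, matching how a small compound screen would actually be
analysed; a day-blocked variant is available behind a flag for comparison.
The detection fraction is the proportion of draws with adjusted p < alpha.
The suite checks the machinery against closed-form noncentral-t power at
n = 3 (df = 4, noncentrality d·√(n/2)).

## Problem sizes used in the checks

The calibration, FDR and power checks run on deliberately compact
configurations chosen to give tight Monte-Carlo bands: 2000 null
features × 48 wells with B = 1000 for calibration under confounding
(binomial ±3σ band 0.035–0.065 at α = 0.05); 100 random instances of ≤ 12
wells against the exhaustive oracle at B = 100,000 (MC error ≲ 0.006);
50 seeds of 500 features × 60 wells at B = 2000 for realized FDR; and
600 wells × 20 features with 1000 sub-sampling draws for the n = 3
collapse. These sizes make the full suite run in well under a minute of
statistics while keeping every assertion's tolerance dominated by the
property being tested rather than by sampling noise.

## Known limitations

- The Monte-Carlo permutation stream is drawn with replacement; for tiny
  blocked designs the exhaustive oracle is the better tool and is exposed
  publicly.
- BY correction is conservative under the near-independence the generator
  produces; realized FDR typically sits far below q.
- The recovery score depends on the retained number of components and on
  PCA being dominated by the stimulus displacement; with very weak
  stimulus responses it is noisy and its undefined-denominator guard
  matters.
- The CLI loads whole feature tables into memory; at the default 8289
  columns this is a few MB per hundred wells, fine for realistic screens
  but not for streaming use.
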