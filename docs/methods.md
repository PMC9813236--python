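# Methods

## Task model

One trial: the participant fixates a cross on a 5-cm obstacle two steps
ahead; at t = 0 a cue appears (left arrow, right arrow, or horizontal bar);
at t = 300 ms a Gabor patch tilted left or right of vertical appears for
77.8 ms at one of four walkway locations (R1, L1 in the first step, R2, L2 in
the second); the cross and cue disappear 44.4 ms after Gabor offset
(422.2 ms). On arrow trials the participant steps with the cued leg first —
right cue: into R1 then L2; left cue: L1 then R2 — and crosses the obstacle;
on bar trials they stand still. The cue therefore fixes each location's
*relevance* (stepping / non-stepping / not applicable) and each location has
a fixed *step* index (first or second). Tilt magnitude at each location is
that location's 79%-discrimination threshold, measured beforehand with an
interleaved staircase.

## Staircase (3-down/1-up)

Level starts at 6.0° and moves in 0.3° steps: down after three consecutive
correct responses, up after any error; the correct-counter resets after every
adjustment. A reversal is logged at the level being adjusted away from; a
track stops at its sixth reversal and its threshold is the mean of the last
four reversal levels. The fixed point of the rule is the level where
p(correct)³ = ½, p ≈ 0.7937. Conventions the protocol leaves open, fixed
here: levels are floored at 0.3° (one step above zero), and a down-move at
the floor is held but logs a "bounce" reversal so an error-free responder
still terminates; the first adjustment has no direction history, so the first
reversal needs one prior adjustment.

Two estimator properties, measured by simulation and worth knowing before
interpreting thresholds from this short protocol:

* **Start-point transient.** Long-run reversal levels converge to the fixed
  point (mean late-reversal level sits at p ≈ 0.789 over 200 extended runs),
  but with only six reversals from a 6° start the estimate is biased high by
  roughly +0.6° when the true threshold is near 3–4°. The calibration test
  therefore places the observer's true threshold at the start level, the
  standard condition for assessing the estimator itself; there the true
  percent correct at the mean estimate is within a point of 79%.
* **Single-run noise.** The estimate's SD is ≈ 0.55°, so a single run cannot
  reliably rank four thresholds spaced 0.3–0.4° apart; only the mean over
  many runs preserves their order. Tests assert the mean-level ranking and
  above-chance pairwise concordance, not per-run ranking.

A stationary cumulative-Gaussian observer (lapse ≤ 0.05) finishes the four
interleaved tracks in ~100–200 trials, below the ~200–443 reported for human
observers; real participants evidently make more (and less stationary)
errors than this observer model, which is a known mismatch of the generator.

## Synthetic cohort

The generator imposes the analysis-level effect directly on per-cell response
probabilities rather than through psychometric-slope changes; the staircase
module instead consumes the full psychometric function. This decouples the
two test surfaces: threshold estimation is validated against the psychometric
function, response analysis against cell probabilities.

* **Responses.** Stationary percent-correct probability is 0.90 per location;
  crossing cells subtract an attention deficit of 7.3 percentage points at
  the cells in the modulation map (default: stepping x step1 only). Each
  participant gets a baseline ability shift ~ N(0, 0.02) on all cells and a
  crossing-cost shift ~ N(0, 0.0175) on crossing cells only. The crossing
  cost is the between-participant component of the Δ-score model; 0.0175 was
  derived analytically, not tuned: with 48 trials per cell at p ≈ 0.9 the
  binomial variance of one cell's percent correct is ≈ 18.75 pp²; the shared
  stationary reference contributes ≈ 6.25 pp² of average within-participant
  covariance that the random intercept absorbs, leaving ≈ 31.25 pp² residual,
  so an ICC of ≈ 0.23 requires ≈ 3.1 pp² of genuine crossing-cost variance
  (SD ≈ 1.75 pp). Replicate simulations confirm a mean fitted ICC ≈ 0.24.
  An optional log-odds response bias shifts "right" reports for β testing.
* **Gaze.** Fixational noise is zero-mean Gaussian (SD 0.3°) per axis at
  120 Hz over the fixation-to-cross-offset window; with probability 0.001 a
  Gaussian-shaped excursion peaking at 4° (width 30 ms, random sign) is
  injected and flagged in the truth ledger. At these settings the 2° rule
  recovers exactly the injected violations (the noise-only false-alarm
  probability is negligible), so the exclusion rate reproduces the ~0.1%
  design value.
* **Gait.** Step onsets are drawn from Normal(741, 105) ms truncated to the
  valid (377.8, 1000] ms window (rare deliberate violations: 0.07% too fast,
  0.59% too slow) and snapped to the 100 Hz sampling grid — a sampled system
  can only realize events on the grid, and snapping makes onset recovery
  testable sample-exactly. Trajectories are flat (jitter SD 0.005 cm) until
  onset, where the lead foot's forward coordinate jumps to 0.55 cm so the
  0.5 cm detector fires exactly at the embedded onset sample, then follow
  raised-cosine forward profiles with sinusoidal vertical arcs. Crossing
  swings are symmetric about the obstacle plane, so the drawn clearance is
  realized exactly where the marker passes the obstacle. Stance scatter per
  axis is 4.79 cm (step 1) and 5.67 cm (step 2), chosen so the mean planar
  distance to the Gabor center (a Rayleigh mean, s·√(π/2)) equals the design
  values 6.0 and 7.1 cm; between-participant step-location spread makes up
  the remainder of the obstacle-distance SDs (10.8 and 7.5 cm). Trajectory
  shape between the endpoint constraints is not data-driven — only the
  endpoint metrics (onset, placements, distances, clearances) are.

What passing tests show, and do not show: the pipeline recovers what this
generator plants — balanced cells, conditionally independent Bernoulli
responses given participant, smooth single-peak swings, stationary gaze
noise. Real data add non-stationary observers, sequential dependencies,
marker noise and dropout, and gait variability that none of these components
model; passing here validates the analysis code, not those assumptions.

## Quality control and kinematic events

Gaze deviation composes horizontal and vertical angles by the small-angle
Euclidean norm; "more than 2° in any direction" is implemented as composed
magnitude > 2° (the stricter reading; a per-plane mode is provided since the
phrasing is ambiguous). The comparison is strict, so exactly 2.0° passes.
The reference is the mean gaze over the first 100 ms of the window (damps
sensor noise; a single-sample mode exists).

Step onset is the first sample with forward or upward deviation ≥ 0.5 cm
from the position at cue onset; validity requires onset > 377.8 ms (the
Gabor offset — the protocol prints both 377.8 and "<377.9"; we treat the
boundary as exclusive) and ≤ 1000 ms. Clearance is the marker height above
the obstacle top edge at the plane crossing, located by linear interpolation
in x between the straddling samples; negative clearance flags contact.
Stance phases are maximal runs of planar speed < 2 cm/s whose height stays
within 1 cm of the run minimum (≥ 3 samples); midstance is the temporal
midpoint — the protocol never defines midstance, and this rule is
deterministic and robust on both smooth and jittered traces.

## Scoring and inference

SDT scoring follows the standard two-response convention with right tilt as
the (arbitrary) signal. The log-linear correction is applied to every cell
unconditionally — it preserves ordering and keeps rates strictly inside
(0, 1), so d′ is always finite; percent correct uses raw counts. β is the
likelihood-ratio criterion exp[(Z_FA² − Z_hit²)/2] (β = 1 unbiased, < 1 a
"right" bias). Crossing trials fill four relevance x step cells of 48 trials
each; stationary trials two step cells of 48; Δ scores subtract the
stationary cell matched on step.

Each Δ outcome is fitted by maximum likelihood as a random-intercept model
with treatment-coded relevance and step (referents: stepping, step1). The
interaction is kept only if its Wald p < 0.05 *and* AIC improves. AIC counts
fixed effects plus both variance components; ICC = τ²/(τ²+σ²); marginal and
conditional R² use the variance-partition definition (fixed-effects variance
over total, plus the intercept variance for the conditional version).
Contrast and coefficient t statistics are referred to t(n − p) — the
numerical backend offers no Satterthwaite approximation, and at n = 48,
p = 4 this df (44) is close to the ~39 a Satterthwaite method reports for
such designs. Cohen's d for pairwise contrasts divides the difference by the
residual SD (this convention reproduces the reference analysis's printed
effect sizes exactly); d for change-vs-zero tests divides the cell estimate
by the between-participant SD of that cell's Δ scores. Pairwise comparisons
are evaluated at the Bonferroni-corrected α = 0.013 for the four planned
contrasts; contrasts are formed on the interaction model, where all four
cell means are identified. Degenerate inputs (constant outcome) return an
exact zero-variance fit with a warning rather than failing.

**Known calibration limitation.** Δ scores within a step share one
stationary reference cell, so their residuals are equicorrelated within
steps but not across steps; the random-intercept model assumes a single
compound-symmetric correlation. Consequently the two across-step planned
contrasts are mildly anticonservative (simulated null rate ≈ 3.6–4.4% at
nominal 1.3%) while the within-step contrasts are conservative (≈ 0.2–0.4%),
and the familywise null rate over the four contrasts is ≈ 7% rather than the
Bonferroni-nominal ≤ 5% (500-replicate simulation; ML's downward-biased
variance estimates at 12 participants contribute). This is a property of the
prescribed model-plus-change-score construction itself, and the
corresponding calibration test documents it by failing.

## Problem sizes and reproducibility

Default analyses use the study-scale configuration (12 participants x 288
trials). Replicate studies in the tests use 200 recovery replicates and 500
null replicates via the trace-free cohort path (binomial per-cell counts,
distributionally identical to trial-level simulation when all trials pass
QC); staircase calibration uses 500 runs; detector checks use 2000 embedded
trials. All randomness flows from a root seed through named substreams, and
a pipeline run writes a manifest of per-stage SHA-256 digests: identical
(config, seed) pairs reproduce identical files.
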