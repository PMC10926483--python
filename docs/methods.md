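# Methods

## The assay and its quantities

A tethered insect walking on an air-supported trackball is shown translating
vertical sine-wave gratings on surrounding monitors, creating rotational
optic flow. The intact optomotor reflex turns the animal in the direction of
perceived scene motion; a tracker (FicTrac-style) reports per-frame ball
rotation from which the fictive heading is integrated. The protocol presents
each grating as alternating constant-direction epochs (default 10 s leftward
then 10 s rightward, repeated 4 times = 80 s of stimulation per grating),
with gratings defined by spatial frequency (cpd) and temporal frequency
(Hz); their ratio is the angular velocity in deg/s. Stimuli are ordered by a
seeded permutation and separated by an inter-stimulus interval (default
180 s).

Within each epoch the accumulated rotation is reset to 0 rad at 0 s,
leftward positive, giving (by default) 8 replicate paths per
animal-stimulus pair. Five features summarize them:

* **ymax** (rad): the maximum of the sign-corrected accumulated-rotation
  path per replicate (rightward paths inverted onto the leftward scale),
  averaged per direction and then over both directions. The per-replicate
  *maximum* rather than the terminal value is used because a response can
  peak before the epoch ends.
* **tortuosity** (dimensionless, [0, 1]): the mean R² of per-replicate
  ordinary least-squares fits of accumulated rotation on time. Responses
  that switch direction promptly and hold a steady yaw are nearly linear
  (R² ≈ 1); wavering or slow-switching paths are not.
* **walking pace** (cm/s): summed per-frame total ball-rotation magnitude
  (norm of the 3-axis lab-frame increment) × ball radius, divided by
  stimulated time and averaged over replicates.
* **absolute turning velocity** (rad/s): |mean of the 8 *signed* regression
  slopes|. The signed mean is taken first so that symmetric left/right
  following cancels to 0 and only a consistent turn bias survives.
* **rotation asymmetry** y_sym = |ymax_r − ymax_l| / max(ymax_r, ymax_l)
  ∈ [0, 1]: 0 for symmetric responses, 1 for fully one-sided ones.

### Numerical choices

* The replicate OLS includes an intercept by default (`fit_intercept`):
  reaction latency shifts the line vertically, and forcing it through the
  origin would contaminate R² with origin misfit rather than path
  tortuosity. Fits on fewer than 3 points are flagged invalid and dropped
  from the means; a stimulus with fewer than 2 valid replicates per
  direction is flagged low-confidence.
* When both direction means of ymax are (near-)zero, y_sym is 0/0; it is
  defined as 0 (a symmetrically *absent* response) and flagged degenerate.
  Bias direction ties within 1e-9 rad report no bias.
* Flat (zero-variance) paths get slope 0 and R² 0 rather than NaN.
* Angles are radians throughout; degrees appear only in presentation.
  Heading is unwrapped on read, so ±π wraps in raw logs never corrupt
  accumulated rotation. If a log's timestamp column is unusable (constant),
  time falls back to frame index / nominal frame rate, logged.

## Consensus clustering and the choice of k

Responses (one row per animal × stimulus) enter as the five features,
z-scored column-wise with the sample standard deviation, pooled across
treatments. Rows with any undefined feature are excluded (counted in the
log) before standardization.

Each consensus iteration draws 90% of rows and 80% of features (4 of 5)
without replacement and partitions the subsample with k-means (k-means++
seeding, 25 restarts, Lloyd iterations run to assignment stability). Entry
(i, j) of the consensus matrix is the fraction of co-clustering among
co-sampling iterations. Stability at one k is summarized by PAC, the
proportion of off-diagonal consensus entries strictly inside (0.1, 0.9).

The optimal k is selected against a Monte-Carlo reference: B structureless
surrogate datasets drawn from a zero-mean multivariate normal whose
covariance equals the data's empirical feature covariance
(principal-component-preserving simulation). For each candidate k the
relative cluster stability index RCSI(k) = ln(mean null PAC / real PAC) is
computed with both PACs floored at 1e-4, and a lower-tail p-value comes from
a normal fit to the null PAC spread. The chosen k maximizes RCSI. Final
labels are an average-linkage hierarchical cut of the consensus
dissimilarity 1 − M at the chosen k, renumbered by descending cluster size;
per-(treatment, stimulus) cluster proportions retain counts.

Defaults follow the common conventions: k ∈ 2..10, PAC window (0.1, 0.9),
2000 consensus repetitions. The bundled tests and the acceptance script run
a scaled-down configuration (200 repetitions, 25 reference datasets) on a
288-response cohort; at that scale the selection is stable across seeds on
the default cohort.

### Degenerate inputs

Exact duplicate-point data (point masses) make every k "perfectly stable"
(PAC = 0), so the RCSI ranking is decided by the reference term alone and
is not meaningful; any infinitesimal within-mass spread restores ambiguity
for k above the true count. Structureless (single-Gaussian) data gives
RCSI values fluctuating around 0 — the real data is one draw from the same
distribution as its covariance-matched reference — roughly an order of
magnitude below values produced by genuine cluster structure. A degenerate
feature covariance is ridge-regularized before simulation (logged).

The k-means inner loop is an authored numba-compiled k-means++/Lloyd
implementation: a k-selection run issues ~47,000 k-means calls on
subsamples of a few hundred rows, a regime where the per-call overhead of
general-purpose implementations dominates. Its partitions are checked
against scikit-learn's KMeans in the test suite.

## Group statistics

Kruskal-Wallis rank-sum tests (midranks, tie correction, chi-square p with
g − 1 df; all-identical data returns H = 0, p = 1) with pairwise
Mann-Whitney U post hocs and Bonferroni adjustment over the comparisons
actually performed. Mann-Whitney p-values are exact by enumeration when the
samples are tie-free and n_a·n_b ≤ 400, otherwise a tie-corrected normal
approximation with continuity correction. Mixed models, beta regression and
Kenward-Roger post hocs are deliberately out of scope.

## Exposure-dose arithmetic

ppb is read as ng of active ingredient per mL of feeding solution; solution
density is ignored (the convention under which the standard printed
conversions are self-consistent). ppb → nM is conc × 1000 / MW; the daily
dose is consumption (µL/day) × conc / 1000 ng/day. Conversions to nM are
conventionally reported as the integer part.

## The synthetic generator

`simulate_trajectory` integrates a per-frame yaw rate

    dθ/dt = direction(t − latency) · gain + bias + noise

with Euler steps at the frame rate (default 50 Hz); `direction(t)` is ±1
inside grating epochs (0 during inter-stimulus intervals and static
gratings), latency is a pure delay of that signal, and the Brownian noise
increment is scaled by √dt so feature statistics are frame-rate invariant.
`forward_pace` is the animal's total substrate speed: the forward-rolling
ball component is √((pace/r)² − yaw²) so the all-axes movement magnitude —
what the pace feature measures — equals the parameter. When instantaneous
yaw exceeds the pace budget the forward component clamps at 0.

Three archetypes mirror the observed response phenotypes — FOLLOWER (high
gain 0.5 rad/s, negligible bias), BIASED_TURNER (strong signed bias
0.7 rad/s over a weak gain, faster pace), SHALLOW_WALKER (small gain and
bias, noise-dominated) — with animal-level lognormal jitter (sd 0.10 on
gain/latency/pace, 0.15 on bias magnitude, bias sign random per animal).
These parameters are free synthetic choices set so the archetypes are
separable at the feature level; no generative parameters exist to copy.

The default cohort design is 4 treatment groups × 6 animals on the full
12-grating battery (288 responses): the control mixture is dominated by
FOLLOWER (0.75/0.10/0.15 over FOLLOWER/BIASED_TURNER/SHALLOW_WALKER) while
the three exposure groups carry elevated turner/shallow fractions
(0.35/0.35/0.30, 0.25/0.40/0.35, 0.30/0.35/0.35). The cohort is smaller
than a real study (one session per animal, all animals see all stimuli) and
each animal keeps one archetype across all stimuli.

**What the generator does not emulate.** Real optomotor responses are tuned
to the stimulus: gain collapses for gratings below the resolvable spatial
frequency or below saturating angular velocity, so a real control animal
produces follower-like responses to mid-range stimuli and weak responses to
extreme ones. The generator's gain is stimulus-independent, so passing
recovery tests demonstrates that the pipeline separates the three response
*types*, not that it reproduces spatiotemporal tuning curves. Likewise
absent: session-level drift, grooming pauses, tracking dropouts, and any
direct coupling between treatment and kinematics other than the mixture
weights.

## Problem sizes used in tests

Unit tests run on purpose-built small schedules (2 s epochs, 2 repeats) and
cohorts of ≤ 10 animals; the consensus k-selection checks use 50–200
repetitions and 5–25 reference datasets. The full-suite k-selection and the
acceptance script use the default 288-response cohort at 200 repetitions
and 25 references, chosen as the package's scaled-down standard
configuration for exploratory runs; production analyses should use the
2000-repetition default.
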