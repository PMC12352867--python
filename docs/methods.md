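# Methods

This note documents the analysis model, the synthetic-data generator that
stands in for recorded sessions, the numerical choices, and the known
limitations of `instasub`.

## Data model and preprocessing

A *session bundle* is one recording session in one behavioral context
(execution or observation): per-unit spike times, per-trial event markers
(start, instruction on/off, go, movement onset, hold on/off, end), the
target object (sphere, button, coaxial cylinder, perpendicular cylinder) and
a success flag.  Times are milliseconds on a session clock; only successful
trials enter analysis.

Spike trains are binned at 1 ms, smoothed with a unit-area Gaussian kernel
(σ = 50 ms, truncated at 4σ), converted to spikes/s, and square-root
transformed so the trial-to-trial variance of the rate estimate is similar
at low and high rates (the standard variance-stabilizing transform for
Poisson-like counts).  Smoothing is done per trial on a window padded 800 ms
before and 400 ms after the trial, so kernel tails near snippet edges see
real data where it exists and zeros otherwise; no edge renormalization is
applied, so a kernel-induced dip near alignment boundaries is possible and
expected.

Each trial contributes four event-aligned snippets, concatenated in order:

| event | window (half-open, ms)                    |
|-------|-------------------------------------------|
| I     | [−500, +500) around instruction onset     |
| G     | [−median_delay, +median_reaction/2)       |
| M     | [−median_reaction/2, +200)                |
| H     | [−200, +200) around final-hold start      |

giving T = 1600 + median_delay + 2·round(median_reaction/2) columns, each
mapped back to (event, offset).  Columns are half-open 1 ms bins; an event
time falls at the left edge of its column.  **Medians are session-level**
(pooled over objects) so all four objects share one time base — required
because the instantaneous subspace needs all four condition means at every
column.  Per-object medians are computed and reported but not used for
truncation.  When execution and observation are analyzed together, the
medians are pooled over both contexts' successful trials so the two tensors
share one time base; this is this package's choice where the original
procedure is underdetermined.

The condition-independent (CI) course is the unweighted mean of the four
object trial-averages; condition-dependent (CD) courses are the per-object
residuals, which sum to zero exactly.

## Unit classification

Per context, spike counts from eleven 200 ms windows anchored to the
behavioral events (before/after instruction on, off, go, movement on, hold
on; before hold end) enter a two-way fixed-effects ANOVA with interaction
(object × period, trials as replicates; statsmodels OLS + anova_lm, type II).
A unit is modulated in a context if any of the three p-values is below
α = 0.0083 (0.05/6, Bonferroni over the six tests across two contexts).
MN = modulated in both contexts, AE = execution only, AO = observation only,
NS = neither.  A repeated-measures variant (trial as a random factor) would
be a defensible alternative; the fixed-effects layout matches the
trial-level count table actually described and keeps the null calibration
testable (the per-context false-positive rate is 1 − (1 − α)³ and is
verified by simulation).

## Instantaneous subspaces and principal angles

At each 1 ms column the four object condition means are centered on their
unweighted mean and decomposed by SVD; the top three right singular vectors
form the orthonormal filter W_t.  Three components capture all the variance
of four centered points, a conservation property tested to 1e−10.  When the
means span fewer than 3 dimensions (degenerate inputs, or times before any
condition information exists), the frame is completed deterministically with
the lowest-index canonical directions orthogonalized against the span, and
the corresponding explained variances are zero.  Basis column signs are
fixed (largest-magnitude entry positive) for bit-reproducibility; all
downstream quantities are subspace properties and do not depend on this.

Principal angles between two frames are the arccosines of the singular
values of W_aᵀW_b (clipped to [0, 1]).  Because arccos is ill-conditioned
near 1, angles whose cosine exceeds 1/√2 are recomputed from the sines
(singular values of B − A(AᵀB)), the standard mixed algorithm; agreement
with an independent implementation is tested at 1e−8 on the cosine scale.

Angle time courses use a reference subspace computed from **all** trials at
the reference event and, per fold (10), an instantaneous-subspace series
rebuilt from 20 trials/object drawn with replacement; the mean therefore
does not reach zero even at the reference time.  Chance is calibrated by the
first principal angle between a fixed random 3-frame and 5000 random
3-frames (Gaussian QR, i.e. Haar) in R^N, summarized as mean and
mean − 3 SD.  For multi-session reports the smallest N across sessions is
used.

An important estimation property, verified and quantified by the test suite:
subspaces estimated from noisy condition means sit at a **positive noise
floor** angle from the true subspace (angles are non-negative, so noise
biases them upward), while the fold-to-fold SD is much smaller than this
bias.  Bootstrap angle courses on Poisson data therefore run several degrees
above the planted-oracle course almost everywhere even when the subspace is
recovered well in the sense that troughs, trends, and timing all match.
Noise-free condition means recover the planted subspaces to fractions of a
degree (bounded only by intensity rectification, below).

## Trajectory segments, separation, decoding

Segments are the 100 columns starting at an event (continuing into the next
contiguous block if the event's own block is shorter than 100 ms).
Projection uses L = (X − c)W with c the condition-mean centroid at the
subspace's own time step, so latents are displacements from the
instantaneous population centroid; projecting the raw X without centering
changes nothing that depends only on differences between objects.
Cumulative separation is CS = (1/T)Σ_t Σ_{i<j} d_ij(t) over the six object
pairs, T = 100.

Decoding uses a bidirectional LSTM written in numpy (one layer, 3 inputs,
20 hidden units per direction, final forward/backward states into a softmax
over 4 classes; Adam, learning rate 1e−3, batch 16, ≤100 epochs with early
stopping on a training-loss plateau — all configurable and pinned for
reproducibility).  Class balance follows the minimum-trial rule: every
object contributes the minimum per-object count, drawn with replacement.
To keep the 40/60 train/test split disjoint at the trial level, each
object's available trials are partitioned 40/60 first and the balanced
resamples are drawn within each side.  The balanced sample is drawn once
per fold and reused at every grid time so grid times are comparable within
a fold.  The chance band projects the same segments into random 3-frames
(same Gaussian-QR scheme), redrawing the balanced sample per repetition.
Because the instantaneous subspaces are computed from all trials, a small
optimistic leakage above exact chance (a few hundredths) is inherent to the
procedure.

## CCA alignment

For each dataset the four trial-averaged 100-point object segments, in the
dataset's own all-trial instantaneous subspace at the segment event, are
**centered across objects at each time point** and stacked (fixed object
order) into 3 × 400 matrices.  The per-time centering makes the alignment a
comparison of the *relations among objects*: without it the
condition-independent drift common to all four segments — and to any two
datasets — saturates the leading coefficient near 1 regardless of whether
the object structure corresponds.  Alignment is the QR + SVD construction
(columns of Lᵀ centered, economy QR, SVD of Q_AᵀQ_B, transforms R⁻¹U and
R⁻¹V), validated to 1e−10 against a covariance-eigenvalue CCA and exactly
invariant to invertible 3 × 3 transforms of either input.

Bootstrapping draws 20 trials/object with replacement from each dataset
independently per iteration (500 by default).  Within-group consistency uses
two independent resamples of the same dataset.  Sessions with fewer
successful trials than the resample size for any object are excluded.  The
significance reference is a label-shuffling null: the second dataset's four
slots are rebuilt from resamples with exactly one quarter of the trials
drawn from each object, destroying condition-dependent structure while
preserving noise level and smoothness.  Exact composition balance matters:
an unbalanced shuffle leaves a residue inside the true latent family, and a
block permutation of the four finished segments is degenerate because any
four centered points in three dimensions can be matched exactly by an
invertible linear map.  Group comparisons use Kruskal–Wallis across
iteration values per coefficient, with Tukey-HSD pairwise follow-ups.

Short smoothed segments have few effective temporal degrees of freedom, so
even the balanced null's CC1 is high in absolute terms; the discriminating
signal is the gap between the genuine distribution and the null's upper
tail, not the raw magnitude.

## The synthetic generator

`generate_session` emulates one session of the delayed RGM task per context:

- **Trials**: blocks of the four objects in shuffled order, ~20 successful
  trials per object plus a couple of flagged failures; initial hold
  500–1000 ms, instruction 500 ms, delay uniform on 500–2000 ms, reaction
  ≈ 250 ± 30 ms, movement ≈ 400 ± 50 ms, final hold 1000 ms.
- **Intensity**: λ_n(t) = base + ci·f(a(t)) + amp_ctx·c_n·[B_ctx(a(t))
  z_obj(a(t))]_n + slow drift, rectified at zero; spikes are an
  inhomogeneous Poisson process on 1 ms bins (Fano ≈ 1 verified).  a(t)
  maps real trial time to the canonical event-aligned axis piecewise
  linearly between the trial's own I/G/M/H anchors, so planted structure is
  expressed in aligned time.
- **Geometry**: the planted basis B(τ) rotates at a constant rate (default
  0.03°/ms) within a 6-dimensional ambient block; the observation basis is
  cos φ·B_exec + sin φ·C with C in a disjoint block, so all planted
  cross-context principal angles equal φ = arccos(context_overlap).
- **Latents**: z_obj(τ) is a static asymmetric zero-sum core (all six
  pairwise distances distinct) plus per-object two-harmonic curves
  (periods 900 and 400 ms), redrawn deterministically until the centered
  four-object configuration keeps a rank-3 margin at every time.  Asymmetry
  and genuine per-object dynamics are what make relation-based comparisons
  (CCA vs its shuffling null) informative; a symmetric configuration would
  be invariant under label permutation up to rotation.
- **Classes**: MN units carry CI + CD in both contexts, AE only during
  execution, AO only during observation, NS fire at base rate; per-unit CD
  gains c_n are uniform on [1 − s, 1 + s] (default s = 0.5).
- **Operating point**: base 20 spikes/s, CI amplitude 10, CD amplitudes
  5 (execution) and 2.5 (observation).  These keep the additive intensity
  clear of the rectification floor (well under 1% of samples clipped), so
  the planted linear geometry survives in the noise-free condition means —
  a prerequisite for sub-2° planted-subspace recovery.  Lower observation
  amplitude reproduces the weaker observation modulation and smaller
  trajectory separation expected of mirror populations.
- **Condition-dependence onset**: by default the CD envelope is zero before
  instruction onset (the subject cannot know the object earlier) and ramps
  on over 200 ms; experiments that need condition information at every time
  (e.g. rotation-recovery) set `cd_onset=None`.

`GroundTruth` exposes, on the canonical axis: the effective planted bases
(orthonormalized diag(c)·B(τ), the subspace the condition means actually
span), the latent courses, noise-free condition-mean rates (packageable as a
1-trial-per-object tensor), unit classes and gains.  `planted_first_angle`
applies the same SVD definition to the noise-free bases and is the oracle
for all angle-course tests.

What the generator does **not** emulate: refractoriness, adaptation, firing
rate heterogeneity beyond the gain spread, eye movements, error-trial
dynamics, non-stationarity across a session, correlated (shared) noise, and
latent dimensionality above 3.  Passing recovery tests therefore shows the
pipeline is correct for data matching its assumptions; it does not certify
behavior on real recordings, where condition-dependent structure is not
exactly low-rank and noise is correlated.

## Reproducibility

All randomness flows through named substreams derived from one seed via
CRC32-hashed labels (stage, context, event, fold, iteration), so any stage
re-run in isolation reproduces its outputs byte-for-byte; the pipeline
writes a manifest with seed, parameter hash and per-stage outputs.  Problem
sizes used by the shipped acceptance checks (50-unit sessions, 20 trials
per object, a six-point decoding grid, 150-iteration CCA bootstraps) were
chosen so the complete suite runs in minutes on a single CPU while leaving
the tested effects far from their decision thresholds.
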