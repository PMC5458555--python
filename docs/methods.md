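# Methods

## Signal model

A surface-tethered molecule carries one donor and one acceptor dye.  Its
conformation follows a K-state continuous-time Markov process observed at a
fixed frame time Δt = 50 ms.  We use the discrete-time embedding: the
per-frame probability of leaving state *i* is Δt/τ_i, where τ_i is the mean
dwell time; exits split uniformly over the transitions allowed by the
preset's connectivity mask.  This is accurate when τ_i ≫ Δt (the shortest
preset dwell is 0.8 s = 16 frames), and makes sojourns exactly geometric,
which the dwell-recovery oracles exploit.  The first state of each trace is
drawn from the chain's stationary distribution.

Per frame, the apparent FRET efficiency is the state mean plus Gaussian
emission noise (s.d. `state_sigma`, clipped to [−0.2, 1.2]), and the
channel intensities are

    donor    = I·(1 − E) + N(0, σ_D)
    acceptor = I·E + β·donor + N(0, σ_A)

with total intensity I, bleed-through β = 0.075 and constant Gaussian
channel noise.  Shot-noise scaling is deliberately omitted: the experiments
this emulates characterise noise by a single background s.d., and constant
noise reproduces the observed histogram widths.  No detection-efficiency
(γ) correction is applied anywhere; all efficiencies are apparent FRET.

Each dye photobleaches once, at an exponential time (donor mean 30 s,
acceptor mean 60 s, 60 s records).  After the acceptor bleaches the
apparent efficiency drops to zero and the donor recovers the full
intensity, so the only catastrophic drop in *total* intensity is the donor
bleach — this is what makes the single-step selection rule meaningful.
Pathological molecules can be mixed in: aggregates (sum of two independent
molecules, hence multiple bleach steps) and donor-only molecules (acceptor
channel carries bleed-through only, giving positive channel correlation).

## Condition presets

| preset family | K | state means | mean dwells |
|---|---|---|---|
| AS_apo / AS_GDP / AS_GDPAlF4 | 2 | 0.35, 0.72 | 45 s, 105 s |
| AS_GMPPCP | 2 | 0.35, 0.72 | 1.0 s, 0.8 s |
| RR_apo / RR_GDP / RR_GDPAlF4 | 3 | 0.35, 0.55, 0.85 | 1.5 s each |
| RR_GMPPCP | 3 | 0.35, 0.55, 0.85 | 1.0, 1.5, 2.5 s |
| RR_R640A / AS_R640A | 1 | 0.90 / 0.95 | static |

Shared defaults: Δt = 0.05 s, I = 1000 a.u., σ_D = σ_A = 25 a.u. (SNR 20,
comfortably above the 8:1 selection gate), β = 0.075, `state_sigma` 0.06.
Three-state presets allow only low↔med and med↔high exchange.

The quiescent-condition dwells (45/105 s) are a design choice constrained
by three requirements: the stationary high-state occupancy must be exactly
105/150 = 0.70; dwells must exceed the dynamic condition's; and transitions
must be *rare* on the bleach-limited observation window (~19 s on average),
because the donor–acceptor cross-correlation amplitude of a trace collapses
only if the trace contains no transition at all — a single switch already
produces a near-full anti-correlation amplitude under per-trace
normalisation.  With these dwells the expected number of transitions per
window is ≈ 0.25, giving a several-fold amplitude contrast against the
dynamic condition.  Consequence: with rare transitions each trace
contributes essentially one independent draw of its initial state, so the
idealized-occupancy estimate over 200 traces has an irreducible s.d. of
≈ 3 percentage points.  Trace lengths, intensities and bleach-time
statistics are declared defaults, not measured quantities.

## Trace selection

Background noise is estimated per channel as 1.4826 × MAD over the
post-donor-bleach segment (or the last 50 frames when no bleach is found);
the robust estimator tolerates residual signal.  Bleach detection runs on
the median-filtered (window 9, truncated shrinking edge windows) total
intensity: an event is a drop ≥ 3 background s.d. below the running plateau
mean with no later 20-frame stretch recovering above that threshold (drops
that recover are blinks, not bleaches).  After an event the plateau
restarts at the new level, so staircases (aggregates) yield one event per
step; triggers within 2 frames merge and each event is localised at the
largest one-frame drop of the filtered series, which places it within ±5
frames of the true bleach on >95% of clean traces.

The acceptor bleach is the same drop rule on the acceptor channel plus two
guards: a concurrent donor *rise* ≥ 3 s.d. (the anti-correlation signature
separating it from the donor bleach), and a post-event acceptor level
consistent with bleed-through alone (post_A − β·post_D < 3 s.d.).  The
second guard matters: a final high→low FRET transition that never reverses
before the donor bleaches also drops the acceptor and raises the donor, but
leaves genuine acceptor signal; without the guard such traces get truncated
early and the occupancy statistic biases high by 2–3 points.

A trace passes iff it shows exactly one catastrophic event, SNR
(mean total / (σ_D + σ_A)) ≥ 8, and raw donor–acceptor Pearson r < 0 over
the analysis window [0, first bleach).  Pearson is computed pre-correction
by default (configurable).  FRET frames with total intensity below
5·(σ_D+σ_A) are marked invalid (NaN) and skipped downstream.  Failures are
recorded as reasons, never raised, so batch screening always completes.

## HMM fitting and idealization

One global K-state Gaussian-emission HMM is fitted per condition by
Baum–Welch over all selected traces jointly (per-trace forward–backward
with per-frame scaling, pooled M-step).  K is an input per condition (2 for
the two-state construct, 3 for the three-state one, 1 for the mutants),
mirroring how state counts are fixed from the histogram decomposition; a
BIC table (`select_n_states`) is provided as a diagnostic only.
Initialisation comes from a Gaussian mixture on pooled frames with a sticky
(0.95-diagonal) transition matrix; 5 restarts jitter the initial means by
±0.05 and the best final log-likelihood wins, ties to the lowest restart
index.  Convergence is |ΔLL| < 1e-4 (absolute, max 500 iterations);
per-restart log-likelihood monotonicity is asserted in tests.  Emission
s.d. is floored at 0.01 to prevent variance collapse on noiseless data;
emission densities are floored at 1e-300 to keep the recursions finite.
States are always reported sorted by ascending mean.  The inner loops are
numba-compiled; an independent EM implementation (hmmlearn) reproduces the
fitted parameters and likelihood in the test suite, and Viterbi decoding is
verified against exhaustive path enumeration for short traces.

## Condition statistics

*Histogram decomposition*: pooled valid frames, 0.025-wide bins over
[−0.2, 1.2], K-component Gaussian mixture (scikit-learn, multi-start).
Bootstrap resamples whole traces (frames within a trace are correlated;
the trace is the exchangeable unit), refitting warm-started from the point
estimate; 1000 replicates by default.

*Occupancy*: the fraction of idealized frames per state is the primary
statistic; the mixture weights are reported alongside as a cross-check
(they agree within a few points on well-separated data).

*Dwell times*: dwell = segment length × Δt from the Viterbi path; the first
and last segment of every trace are excluded as censored.  Bootstrap over
dwell observations (100 replicates) gives the s.d. of the mean.  Known
bias: a complete dwell must fit strictly inside the observation window, so
the censored mean underestimates the true mean by O(dwell/window) — about
1% for 10-frame dwells on 1000-frame windows, but 5–8% for the 16–20-frame
dwells of the dynamic condition on its bleach-limited (~380 frame) windows.
This is a property of the estimator, not of the decoding: censored means
computed from ground-truth state paths show the identical shortfall.

*Transition density plot*: for each state change, initial/final coordinates
are the mean *raw* FRET over the preceding/following segment (segment
averages of the data, not model means), binned at 0.02 and normalised to
transitions per molecule, so total mass = transitions / traces exactly.

*Cross-correlation*: per trace, the normalised donor–acceptor
cross-covariance over the pre-bleach window, averaged across traces;
error bars are the s.d. across 5 equal trace batches (emulating independent
experiments).  The amplitude statistic is −CC at a one-frame lag: the
zero-lag point is dominated by the anti-correlated per-frame emission
noise, whereas lag one isolates state dynamics.

## Channel registration

A full 6-parameter affine map (least squares on matched bead centroids)
takes donor-channel positions to acceptor ones; affine subsumes the
similarity/translation alternatives a split-view path can produce.  Fewer
than 10 beads warns, fewer than 3 (or collinear fields) fails.  Under
isotropic centroid noise σ the fit residual rms approaches σ·√(2 − 6/n)
and the field-averaged mapping error ≈ σ·√(6/n), both verified by
Monte-Carlo.  No outlier rejection (bead fields are clean); hook available.

## Determinism and problem sizes

Every random draw descends from one user seed via `numpy.random.SeedSequence`
spawning: datasets, EM restarts, bootstraps.  Two runs on identical inputs
produce byte-identical outputs.  Study-scale analyses use 200 traces per
condition (~55k pooled frames after selection); unit tests use 50–100
traces, which keeps the full suite and the acceptance script within a few
minutes on one core.

## Known limitations

* No dye blinking, spectral fluctuations, drift or shot-noise scaling in
  the generator — traces are cleaner than real recordings, so the QC pass
  rates and localisation accuracies measured here are upper bounds.
* Donor intensity can go slightly negative at very high FRET (emission
  noise on E, constant total intensity); harmless for the ratio-based
  estimators but not physical.
* An acceptor that bleaches within the first few frames is undetectable
  (there is no drop to see); such traces occasionally pass selection and
  contribute a small near-zero-FRET contamination (~1% of pooled frames in
  the dynamic condition), slightly widening the low-FRET component.
* Mean dwells carry the window-truncation bias described above; no
  survival-style correction is applied because the plain censored mean is
  the estimator of record.
* Occupancy estimates for quiescent conditions are noise-limited by design
  (see presets section): ±3 points at 200 traces is a 1σ statement.
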