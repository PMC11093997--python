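# Methods

This note documents the models, defaults and numerical choices behind
`marmonav`, and what the synthetic-session tests do and do not establish.

## Coordinate and data conventions

Right-handed coordinates, z vertical (up), units cm, origin at the lowest
south-west corner of the enclosure. Quaternions are stored scalar-first
(w, x, y, z) at unit norm; norms deviating by more than 1e-3 are
renormalized on construction and deviations beyond 1e-2 are errors. The
head's forward (visual) axis is the body-frame +x axis. Time intervals are
half-open [t0, t1); sample indices are 0-based; all per-interval kinematic
quantities are timestamped at interval midpoints. Tracking gaps are stored
as explicit missing samples and propagate as missing through every
downstream quantity — nothing is interpolated.

Default rates: tracking 60 Hz, LFP 1 kHz.

## Kinematics

Translation speed differentiates the 4 Hz zero-phase low-passed position
(4th-order Butterworth applied forward-backward, per contiguous valid run
so occlusions never leak through the filter). Angular head velocity uses
the geodesic quaternion angle 2·arccos(|⟨q₁, q₂⟩|), which is insensitive to
the q/−q double cover and invariant under global rotation of the reference
frame.

Movement detection: maximal supra-threshold runs (head 200 °/s, body
16 cm/s) are extended on both sides to the nearest local minimum below half
the threshold; epochs that merely touch at a shared valley sample remain
separate events, and epochs that genuinely interleave are merged. Amplitude
is the path-integrated quantity (Σ v·Δt), not net displacement — for
ballistic, monotone rotations the two coincide, and the integral is robust
for curved body paths. Amplitude floors: 10° (head), 30 cm (body). Peaks
above 2000 °/s / 300 cm/s are artifactual and excluded (kept in a separate
artifact list). On velocity plateaus the earliest sample is the peak.

The Naka–Rushton fitter uses non-linear least squares with 10 jittered
restarts from (max r, 2, median x, min r), positivity bounds on R_max, n, K,
and keeps the lowest-residual solution. With amplitudes confined to
10–90°, R_max and b are partially collinear; recovery error on the
asymptote is typically 1–3% at 5000 events with 5% multiplicative noise.

## Cell typing

The burst index compares the measured 1 ms-binned ISI histogram over
2–40 ms against the exponential ISI density λe^(−λt) of a Poisson process
at the unit's whole-session mean rate. The predicted mass is bin-integrated
by default (`predicted_isi_mode="center"` evaluates the density at bin
centers instead — the difference is negligible for λ·Δt ≪ 1 but the
integrated form is exact). Both histograms are normalized over 2–40 ms; the
index sums 2–20 ms and is bounded in [−1, 1].

Classification is 2-means on per-feature standardized (BI, mean rate) with
10 restarts; standardization makes the partition invariant to affine
feature rescaling, which matters because Hz and a unitless index share no
scale. The higher-rate cluster is labeled interneuron (fast-spiking).
Duplicate units (>50% shared spike times at 1 ms resolution) keep the
higher-SNR member, or the higher spike count when waveforms are absent.

## Place, view and speed selectivity

Place bins tile the interior as a per-floor x–y grid stacked over floors
(default 7×4×3 = 84 bins). View is the facing location: the forward ray's
first intersection with the six inner faces, binned as a per-face grid of
25 cm tiles (76 bins for the default enclosure). Bins sampled on three or
fewer independent visits (maximal contiguous dwells) or under 200 ms of
total occupancy are excluded from the bin count and the occupancy
normalization.

The SIC permutation null circularly shifts spike times by uniform offsets
(minimum 1 s from either end to avoid near-identity shifts), preserving
spike count and autostructure while destroying the behavioral relation.
Cell-level selectivity uses the 95th percentile of 5000 shuffles; per-bin
fields use the same null's per-bin rates at the Bonferroni-corrected
percentile 100·(1 − 0.05/L). Both percentiles are configurable because
cell- and bin-level conventions legitimately differ.

Speed scores correlate the 250 ms-SD Gaussian-smoothed rate and speed
series at the tracking rate; classification requires r > 0.3 **and**
r above the 95th percentile of 1000 circular shifts. The null is computed
via a single FFT cross-correlation, which is exact for integer-sample
circular shifts of z-scored series.

## Encoding models

Putative pyramidal cells are offered place (x, y, z), view (u, v on the
unwrapped faces) and head direction (yaw, pitch, roll); putative
interneurons are offered AHV and TS. Each multi-dimensional variable enters
as additive per-dimension smooths but is selected as one unit. Linear
dimensions use cubic B-splines (8 basis functions, second-difference
penalty); angles use a periodic sin/cos harmonic basis (order 3) with a
curvature-weighted ridge penalty — exactly periodic by construction.

The solver is a penalized IRLS for the log-link Poisson likelihood with a
fixed smoothing weight (default 1.0) rather than per-fit generalized
cross-validation: forward selection refits each candidate ~100 times per
iteration against shuffle nulls, and a fixed mild penalty keeps those fits
deterministic and fast while leaving recovery and type-I behavior intact
(verified in the test suite, including a cross-check against statsmodels'
GLM on an identical basis). Explained deviance is the conventional
ED = 1 − D_fitted/D_null with the null deviance taken at the mean count;
the alternative `ed_formula="printed"` returns D_fitted/D_null.

Selection: first-order nulls circularly shift the spike-count vector;
higher-order nulls shift only the candidate predictor's time series (a row
permutation of its basis matrix), leaving the response and already-selected
predictors intact. A candidate is accepted when its real ED exceeds the
Bonferroni-corrected 95th percentile of its 100-shuffle null (corrected by
the number of candidates at that iteration); among significant candidates
the largest shuffle-normalized ED (real − mean null) wins, ties broken
alphabetically. Selection stops when no candidate passes.

Prediction scoring: five contiguous equal-time folds; per-fold R² is the
squared Pearson correlation between the held-out predicted rate and the
real counts and the reported R² is the fold mean; the significance test is
the F-test of the pooled held-out correlation with (1, n−2) degrees of
freedom. Per-frame counts at 60 Hz are Poisson-noise dominated, so absolute
R² values are small even for strongly tuned units; the F-test carries the
significance claim.

Because the behavioral variables are correlated in any real (or realistic
synthetic) session — head direction constrains view, position constrains
both — the predictor-shift null tests *conditional* information, and a unit
tuned to one variable can legitimately acquire a correlated second one.
Exact-match recovery rates on single-variable synthetic units are therefore
below 100% by design (measured ≥ 70% under the default conditions).

## Place decoding

Trials are 200 ms windows centered on local AHV minima inside sub-200 °/s
runs, spaced at least one window apart; labels are floor-halves (two per
floor), with the four best-sampled of six classes retained and at least 50
trials per class required. The decoder is a linear SVC (C = 1, one-vs-one)
on features z-scored within training folds, evaluated by stratified
five-fold CV inside each of 10 balanced-subsample repeats; reported
accuracy is the mean over repeats (never the best). Greedy ensembles seed
with the best single unit and add the best-improving unit each iteration,
stopping at 20 members or when improvement over the last 3 sizes falls
below 0.005; ties break toward the lower unit index. Random-ensemble
controls draw 100 unique same-size subsets. Label-shuffled runs sit at the
theoretical chance 1/4 with the small negative bias characteristic of
cross-validated shuffled-label decoding.

## Event-aligned LFP

Preprocessing low-passes the broadband signal at 250 Hz (4-pole Butterworth,
zero-phase) before decimating to 1 kHz — a 250 Hz *high*-pass before
decimation would alias away everything the later 1–30 Hz analyses need; a
`printed_filter` flag reproduces that alternative for comparison. Then a
1 Hz high-pass, and artifact rejection: 100–249 Hz band-pass, analytic-signal
envelope smoothed with a 0.2 s boxcar, z-scored, thresholded at 4 with
±100 ms rejection padding.

The TFR uses 7-cycle complex Morlet wavelets at 1–30 Hz in 1 Hz steps,
computed on the continuous trace (a 7-cycle 1 Hz wavelet outlasts any
single event window) and then averaged over event windows, smoothed with a
25 ms boxcar. The baseline is the aperiodic (1/f) component of the
session's Welch spectrum — an iterative robust log-log linear fit that
discards points above the running fit so oscillatory peaks do not bias the
floor — and power is reported as 10·log₁₀(signal/baseline), median-centered
to place a pure 1/f signal at 0 dB.

Theta phase is the analytic-signal angle of the 4–10 Hz zero-phase
band-passed trace. Phase resetting is quantified per event-relative time
sample by the Rayleigh statistic Z = n·R̄² with Zar's finite-n p-value
approximation, significant at p < 0.01 over a 400 ms window.

Peri-movement modulation bins each unit's 1 ms raster into eight 50 ms bins
spanning ±200 ms around head-movement peaks. The null circularly permutes
the whole-session raster 1000 times and re-bins identically; "up" requires
a real bin above both the at-bin 97.5th percentile and the 97.5th
percentile of across-window maxima, "down" mirrors this at the 2.5th
percentile of minima, and both at different bins gives "down_up". The
across-bin extreme statistic controls the multiplicity across the eight
bins; measured false-positive rates on stationary Poisson units are ~5%.

## Synthetic sessions

The generator emulates the study conditions the analyses assume. Behavior
alternates uniform 1–6 s stops with straight locomotion bouts between
reward ports at 16–60 cm/s (so body-translation thresholds are exercised on
both sides), joined by fixed-duration 1.2 s alignment turns whose rotation
speed stays below the head-movement detection threshold. Head events follow
a log-normal amplitude distribution (median 25°, log-SD 0.5) truncated to
10–90°, with raised-cosine velocity profiles whose per-sample rotation
increments integrate exactly to the drawn amplitude; peak velocities follow
a Naka–Rushton main sequence (marmoset preset R_max = 795 °/s, rat preset
430.9 °/s; the remaining parameters n = 2, K = 20/25, b = 50/30 are free
choices giving saturating curves over the amplitude range) with 5%
multiplicative noise. Events during stops occur at 1.2 Hz; the number
during locomotion is derived from the realized stop-event count so the
configured during-stops fraction (default 0.8) holds by construction.

Spike trains are inhomogeneous Poisson at 60 Hz frames with log-link
tuning: Gaussian place fields, Gaussian view fields on a wall face,
von-Mises head-direction tuning (pyramidal; baseline ~1–3 Hz, doublets
injected at 2–15 ms with probability 0.3–0.5 so burst-based typing is
recoverable), and saturating-ramp AHV/TS tuning (interneuron; baseline
~8–20 Hz). Rates above 500 Hz are rejected as configuration errors.

The LFP is spectrally shaped 1/f^1.5 noise plus a theta oscillation
(7 Hz) with phase-diffusion jitter; at each head-movement peak the phase is
pulled toward a fixed reset phase by `reset_gain` (1 = full reset) and the
amplitude receives a transient bump decaying over 0.25 s. This is the
simplest generative model that produces event-locked phase concentration;
the analysis makes no use of its specific form.

Default session scale is 2400 s with 204 pyramidal and 127 interneuron
units (a realistic full-session preset); tests and the acceptance script
use 300–600 s sessions with 4–20 units so the full suite runs on one CPU
in minutes — these problem sizes are stated in the relevant tests.

**What passing tests show — and don't.** Recovery and type-I results on
synthetic sessions validate the *implementation* under the generator's
assumptions: Poisson spiking, stationary tuning, clean tracking, additive
LFP components. Real recordings violate all of these to some degree
(overdispersion, nonstationarity, occlusions, non-sinusoidal theta), so
passing tests certify the estimators, not any empirical claim about real
hippocampal data.

## Known limitations

- View is strictly a surface projection; no 3D view volumes, no eye-in-head
  gaze reconstruction (head direction is the gaze proxy throughout).
- No interaction/tensor smooths between behavioral variables; additive
  per-dimension terms only.
- The GAM smoothing weight is fixed, not data-adaptive.
- Pseudo-population trial pairing assumes exchangeability of same-class
  trials across units; within-session noise correlations are out of scope.
- The aperiodic fit is a robust power law, adequate for baselining but not
  a full spectral parameterization (no knee parameter, no peak models).
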