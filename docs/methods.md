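# Methods

`cadenza` implements a complete analysis chain for studying how dynamic
cerebral autoregulation (dCA) interacts with neurovascular coupling (NVC)
during cognitive task activation, together with a synthetic-recording
generator that provides ground truth for every estimator in the chain.

## Signal model and preprocessing

Recordings are multichannel 500 samples/s waveforms: continuous arterial
blood pressure (BP, mmHg), bilateral middle cerebral artery blood velocity
(MCAv, cm/s, transcranial Doppler), ECG, and a capnogram (EtCO2, mmHg).
Task recordings last 3 min (1 min rest / 1 min task / 1 min recovery);
baseline recordings 5 min.

Cleaning follows standard beat-to-beat practice:

- **Narrow spikes (< 100 ms)** are removed by linear interpolation.
  Detection flags first differences above `k·MAD` (default `k = 8`,
  MAD-scaled); consecutive boundary pairs bracket a candidate interval.
  Intervals at or above the width gate are reported but left untouched,
  as are lone steps; intervals touching a record edge are held at the
  nearest good value. If more than 10% of samples fall in cleanable or
  edge intervals the recording is rejected as unusable. The detection
  rule and kernel sizes are configurable; only the removal behaviour (not
  the detector) is prescribed by the underlying methodology.
- **Low-pass filtering**: zero-phase 8th-order Butterworth at 20 Hz
  (forward–backward `sosfiltfilt`, reflect padding of 3× the order).
- **Velocity median filter**: running median, default 5 samples at
  500 samples/s, for residual narrow Doppler artefacts.
- **Finometer calibration**: linear rescale `a·x + b` so the min/max of a
  stable early window (default first 30 s) match brachial cuff
  diastolic/systolic values.
- **R-wave detection**: band-pass 5–25 Hz → squared derivative → 150 ms
  moving-window integration → adaptive threshold at 0.3× the 80th
  percentile of candidate peak heights (robust to lone edge artefacts) →
  peak refinement on the raw ECG within ±150 ms. RR intervals outside
  0.3–2.0 s, or deviating more than 50% from the median RR (missed/extra
  beats), are flagged; `correct_beats` is the programmatic counterpart of
  manual mark editing.
- **Beat averaging** over half-open cardiac cycles `[beat_i, beat_{i+1})`;
  per-breath end-tidal maxima are linearly interpolated to beat times
  (boundary breaths held constant outside the breath span).
- **Resampling**: third-order (cubic) spline interpolation of all
  beat-to-beat series onto a uniform 5 Hz grid.
- **Normalization**: MCAv expressed in percent change relative to the
  mean of the 30 s immediately preceding task onset (first 30 s for
  baseline-only records).

## Transfer function analysis and the ARI

TFA treats mean arterial pressure (MAP) as the input and MCAv as the
output of a linear time-invariant system. Welch's method with a Hann
("cosine") taper, 50% segment superposition and per-segment mean removal
gives the auto- and cross-spectra; gain `|Sxy|/Sxx`, phase `arg(Sxy)` and
magnitude-squared coherence `|Sxy|²/(Sxx·Syy)` follow. Segment length is
256 samples (51.2 s) for 3-min task recordings — the short-segment
compromise that admits 6 windows in 3 minutes — and 512 samples (102.4 s)
for baseline recordings.

Before TFA both signals are put in the Tiecks model's normalized units:
pressure as `dP = (MAP − MAP₀)/(MAP₀ − CrCP)` with `CrCP = 12 mmHg`
(the model's conventional critical closing pressure; configurable) and
`MAP₀` the first-30-s mean, velocity as fractional deviation from its
baseline mean. Gain is then dimensionless and the measured step response
and the ARI templates share one normalization, so the template fit has no
free scale factor.

The impulse response is the inverse FFT of the complex frequency response
(DC bin replaced by the nearest estimated bin's gain, since per-segment
mean removal makes DC indeterminate; Nyquist forced real), and the step
response is its running sum — a unit spectral response integrates to a
unit step, matching the templates.

**Tiecks model.** Velocity response to normalized pressure deviation:

    x2[n] = x2[n−1] + (x1[n−1] − 2·D·x2[n−1]) / (f·T)
    x1[n] = x1[n−1] + (dP[n] − x2[n−1]) / (f·T)
    V[n]  = v0 · (1 + dP[n] − K·x2[n])

with one published (T, D, K) triplet per ARI grade 0–9, stored in a
checksummed CSV (`cadenza/data/tiecks_parameters.csv`). At 5 Hz the
smallest time constants (ARI 8–9) leave fewer than 5 Euler steps per T,
so the recursion runs internally at 10× oversampling (zero-order hold on
dP) and is decimated back; `f·T ≤ 1` is rejected. Sustained step `d`
settles at `V/v0 = 1 + d(1−K)` — the closed-form fixed point used as an
independent oracle in the tests.

**Template fit.** The measured step response is compared over a 0–10 s
fit window (configurable) with the ten template step responses generated
at the same rate and duration; the grade with the smallest NMSE wins,
ties toward the lower grade. NMSE is the mean squared error divided by
the mean square of the measured step over the window. Normalizing by the
mean square rather than the variance keeps the gate well defined for the
flat ARI-0 (no-recovery) response, whose in-window variance vanishes on
clean data while its power is ~1; the denominator is common to all
templates so the ranking is plain least squares either way.

**Acceptance gates.** An estimate is accepted iff (i) the mean coherence
over 0.15–0.25 Hz exceeds the 95% confidence limit of coherence between
independent signals at the actual window count, and (ii) NMSE < 0.3.
With 50% overlapping windows the classic limit `1 − α^{1/(L−1)}` (kept as
the analytic reference) does not apply, so the default limit is
Monte-Carlo: seeded surrogate pairs pushed through the identical Welch
estimator, the limit being the 95th percentile of their band-mean
coherence. Surrogates carry a 1/f amplitude spectrum (0.02 Hz to 90% of
Nyquist) rather than white noise: with only ~6 windows the band-mean's
null distribution depends on the inter-bin correlation induced by the
input spectrum, and white surrogates understate the limit for
low-frequency-dominated physiological signals by enough to inflate the
false-acceptance rate from 5% to ~8%.

Note the published template table is mildly underdamped at high grades,
so step responses of ARI 7–9 overshoot and cross pointwise around
t ≈ 3–7 s; the ordering invariant that actually holds (and is tested) is
recovery at t = 10 s, strictly increasing with grade.

## Responder / non-responder classification

Each subject × task × hemisphere percent-MCAv curve, time-locked to onset
(−60…+120 s) and averaged over visits, is scored with two statistics:

- **CCF peak**: maximum Pearson correlation against the cohort's coherent
  average over lags within ±5 s. The template is computed leave-one-out
  (scored curve excluded) so self-correlation does not inflate the
  statistic; the grand-average variant is available behind a flag.
- **Variance ratio (VR)**: sample variance of the 30 s post-onset window
  over the 30 s pre-onset window — an F-type statistic (it follows
  F(n−1, n′−1) exactly for independent stationary Gaussian windows, which
  the tests verify distributionally).

A subject is a responder if **either** statistic strictly exceeds its
90% null-distribution threshold; published values CCF₉₀ = 0.53,
VR₉₀ = 2.59 load without any data. `recalibrate_thresholds` re-derives
them as the (1−α) quantiles (α = 0.10) of both statistics over ≥ 50
unstimulated curves; in the cohort pipeline the baseline recordings
supply those null curves. Because the rule is a disjunction of two
α-level criteria, the combined null flag rate lies between α and 2α.

## Reproducibility statistics

Visit-to-visit agreement of ARI estimates uses the one-way
random-effects, single-measure intraclass correlation ICC(1,1):
`(BMS − WMS)/(BMS + (k−1)·WMS)` from the one-way ANOVA decomposition,
p-value from `F = BMS/WMS` on `(n−1, n(k−1))` df. The literature
frequently conflates this with the two-way mixed ICC(3,1); both are
implemented, ICC(1,1) is primary, and the variant is recorded in every
output row. Subjects missing a visit are dropped listwise. The
within-subject CV is `SD/mean` per subject pair, averaged. Interpretation
bands (half-open, boundary in the upper band): ICC poor < 0.40 ≤ fair
< 0.60 ≤ good < 0.75 ≤ excellent; CV very good < 0.10 ≤ good < 0.20 ≤
acceptable < 0.30 ≤ not acceptable. ICC is shift-invariant, CV is
scale-invariant but not shift-invariant; both properties are tested.

## Synthetic-data generator

The generator emulates the study conditions rather than any individual
physiology; its defaults are the conditions under which all properties
are verified:

- **MAP (5 Hz)**: 90 mmHg baseline + 1.5 mmHg Mayer-wave sinusoid at
  0.1 Hz + band-limited 1/f noise (0.02–0.45 Hz, 2 mmHg SD) + a 0.3 mmHg
  broadband microvariability floor up to Nyquist + a smooth task-locked
  rise (default +3.5 mmHg, 5 s raised-cosine ramps). The broadband floor
  reflects the genuinely broadband character of beat-to-beat pressure
  variability; without any input power above 0.45 Hz the transfer
  function is unidentifiable there and the inverse-FFT step response
  drowns in leakage noise. More than half of the MAP variance sits below
  0.15 Hz, as in resting recordings.
- **MCAv**: MAP passed through the Tiecks model (baseline ARI 6 at rest
  and recovery, task ARI 4 during the activation minute — activation
  depression is modelled by switching the true grade, not by a
  mechanistic interaction), v0 = 60 cm/s. The simulation is warmed up on
  a mirror-padded lead-in so the delivered record is in steady state.
  Responders (85% of subjects by default) receive a multiplicative NVC
  rise — default ramp-plateau: 3 s rise, plateau at 6.9% (a typical
  task-evoked magnitude), 5 s decay; a gamma-shaped variant is available.
  Independent Gaussian noise per hemisphere, default SD 10% of the
  clean-signal SD. Note the measured task-minute rise under full defaults
  is the NVC amplitude plus the pressure-driven contribution
  (~+1 pp via the model's steady-state gain).
- **Raw mode (500 samples/s)**: pulsatile BP and MCAv built per cardiac
  cycle around the 5 Hz trajectories with a zero-mean in-beat pulse shape
  (so beat averaging returns the trajectory to < 1%), impulse-train ECG
  at R-wave instants integrated from the HR trajectory (+6 bpm during
  task), a smoothed square-plateau capnogram (−0.6 mmHg EtCO2 drift
  during task), optional injected spikes for artefact tests.
- **Cohorts**: per subject, one baseline recording plus one recording per
  task, for each of two visits; visit 2 re-draws all stochastic
  components under a visit-keyed seed (or duplicates visit 1 for
  degenerate reproducibility tests). Generation is a pure function of the
  integer seed.

What the generator does **not** emulate: baroreflex and autonomic
feedback loops, respiratory–cardiac coupling, CO2 vasoreactivity,
between-subject ARI heterogeneity (every subject shares the configured
true grades, so cohort ICC of ARI is degenerate by construction and the
ICC estimator is instead validated on explicit variance-component
simulations), nonstationary task engagement, or measurement-device drift.
Passing tests therefore demonstrate estimator correctness under the
assumed linear model and noise structure, not robustness to every failure
mode of real recordings.

## Numerical choices and known limitations

- Welch segments are demeaned (not detrended); linear detrending was
  evaluated and degrades low-frequency transfer estimates on 1/f forcing.
- The DC bin of the frequency response is filled with the nearest
  estimated bin's gain; Hermitian symmetry is enforced via `irfft`.
- Short-segment TFA (6 windows) carries irreducible low-frequency
  estimation error; on noise-free records adjacent-grade confusions
  (almost always ARI 5 → 4) occur in roughly 1–2% of recordings. This is
  a property of the prescribed short-segment method, not of the
  implementation, and it motivates the acceptance gates.
- Analysis of a task recording spans the full 3 minutes (as the
  segmentation prescribes), so when the true ARI switches only during the
  task minute the estimate is a mixture biased toward the baseline grade;
  group comparisons against baseline recordings remain directional, which
  is the claim tested end-to-end.
- `fit_ari` ties break toward the lower (more conservative) grade;
  integer grades only, no continuous interpolation.
- The coherence-limit Monte-Carlo (2000 surrogates) is cached per
  (record length, settings, α, seed), so cohort runs pay its ~1.5 s cost
  once; its surrogate seed is recorded in every output row via the
  config echo.
- Problem sizes used by the verification suite: single recordings are
  900 samples (180 s at 5 Hz); noise-recovery checks use 50 seeds ×
  7 grades; null calibrations use 2000 + 2000 curves; the end-to-end
  cohort is 16 subjects × (baseline + task) in raw 500 samples/s mode.
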