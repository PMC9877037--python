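# Methods

`thetacode` re-implements, as a tested pipeline, the computational analyses
used to dissociate hippocampal spatial and temporal codes from theta
oscillations: information-theoretic classification of place/time/distance
cells from binarized calcium activity, naive Bayes decoding of behavioral
variables, optogenetic-modulation detection, and LFP analyses (oscillation
strength, quiet-rest segmentation, ripple detection). Because the package
is exercised entirely on synthetic data with known ground truth, this note
documents both the analysis conventions and what the generator does and
does not emulate.

## The task and its variables

A mouse shuttles on a 134-cm linear track. End sensors advance a tone
sequence; every 4th run ends with reward delivery at the starting end.
Three behavioral variables are tracked per frame (30 Hz): absolute
position `x` (cm), elapsed time `t` (s) and traveled path length `d` (cm),
the latter two measured since the departure (> 5 cm) from the reward site
and resetting together there. A run is scored as an error when the mouse
returns to the end zone it departed from before triggering the opposite
sensor — the operational, sensor-based scoring; mid-run meanders that stay
clear of the end zones are not observable by the hardware and are not
errors. A trial (4-run block) is correct when none of its runs is an
error.

## Binarization and tuning

Raw dF/F traces are low-pass filtered (zero-phase 4th-order Butterworth,
2 Hz default — the source method states only that high-frequency
fluctuations were removed), z-scored over the whole session, and a frame
is *active* when z > 2 and the first difference of the filtered trace is
positive. Only the rising phase of a transient is kept, so binary events
approximate transient onsets. Two consequences verified in the tests:
constant traces produce no events, and isolated single activations (or
weak bursts) remain below the 2-SD bar by design — the binarizer is a
transient detector, not an event counter.

Tuning curves are occupancy-normalized activity likelihoods
`P(A = 1 | S_i)` over binned states (location: 3-cm bins over 0–135 cm;
time: 1-s bins over 0–60 s; distance: 3-cm bins over 0–540 cm), computed
on locomotion frames only (speed > 5 cm/s on the track, > 2 cm/s in the
open field; speed is |Δd|/Δt smoothed with a 33-ms Gaussian). Frames whose
variable value falls outside the analyzed range carry no defined state and
are excluded from that variable's analysis (piling them into an edge bin
creates a spurious occupancy spike that contaminates every cell's
information estimate). Gaussian smoothing (sigma 5/10/15 bins for
location/time/distance) is applied to display and decoder curves;
mutual information is always computed on unsmoothed curves.

## Mutual information and the circular-shuffle null

MI (bits, log2) between binary activity and the binned state is

    MI = sum_i sum_j P(S_i, A_j) log2[ P(S_i, A_j) / (P(S_i) P(A_j)) ]

with zero-probability cells contributing zero. Significance uses 1000
circular permutations: the activity vector is rotated over the *full
session timeline* by an offset drawn uniformly from [1 s, N − 1 s], so
surrogate events may fall into masked (rest) periods exactly as when the
raw trace is permuted and the analysis re-run; this keeps the transient
autocorrelation and yields a conservative, calibrated null (the measured
false-positive rate on 200 untuned cells is 0.02–0.05 per variable at
alpha = 0.05). The p-value is the fraction of surrogates whose MI strictly
exceeds the actual MI; ties favor significance. A cell significant
(p <= 0.05) for exactly one variable gets that label; for two or more,
"conjunctive"; otherwise "none". Stimulation modulation treats the
binarized 5 s ON / 5 s OFF stimulation state as a two-state behavioral
variable under the same test, with direction from the sign of
`P(A|stim) − P(A|no stim)`.

## Naive Bayes decoding

The decoder is fit on 90% of locomotion frames (whole trials held out
from the end of the session; holding out contiguous trials prevents the
temporal leakage an interleaved split would allow) and evaluated on the
rest. Per-cell likelihoods are the smoothed training tuning curves,
clipped per bin to [1/(occ+2), 1 − 1/(occ+2)] so silent cells cannot zero
the posterior; smoothing is essential in the 180-bin distance space,
where unsmoothed curves of cells untuned to distance overfit
trial-specific path offsets and vote systematically wrong. The prior is
uniform over occupied bins. Per frame, evidence is combined across cells
assuming independence and accumulated over a trailing 2-s window; the MAP
bin (lowest index on ties) is the decoded state and the error is
|decoded − actual| at bin centers. Two scoring variants are provided: the
exact log-posterior using each cell's observed binary state, and the
historical `sum log(1 + P(A_k|S) P(S)/P(A_k)) − 1` score over active
cells. Per frame they select the same MAP bin on ~96% of frames; after
2-s accumulation the saturating form diverges more (log-probability
voting penalizes disagreeing cells, the saturating form does not), so the
exact/binary variant is the default. Bootstrap evaluation draws 50
surrogates of 160 cells with replacement, fits and decodes each, and
compares against matched surrogates whose cells are circularly shifted
before the split; performance is summarized by z = (mean actual − mean
shuffled)/SD(actual) (negative = better than chance; the display
convention may negate it).

## LFP analyses

* **Spectrograms.** Complex Morlet wavelets (bandwidth 1, center
  frequency 1.5) where joint time-frequency resolution matters;
  Hann-tapered moving-window Fourier power (2-s windows for theta, 5-s
  for gamma, 10-ms steps) where frequency resolution is privileged.
* **Oscillation strength (OS).** Per 2-s window, the cumulative power of
  the dominant contiguous ±1 Hz interval inside the 4–12 Hz band divided
  by the cumulative 4–12 Hz power, averaged across windows stepped every
  10 ms. A pure sinusoid gives OS = 1.000 (all band power in the peak
  interval); 59 five-second epochs of white noise average OS ≈ 0.50.
  Within the fixed 2-s/10-ms convention, the per-window dominant-interval
  form was selected over averaging the PSD first (≈ 0.37) or conditioning
  on the single peak bin (≈ 0.44) because it alone reproduces the
  white-noise calibration value.
* **Band powers.** Welch PSD integrated over delta 1–4, theta 4–12,
  alpha/beta 12–30, slow gamma 30–60, fast gamma 60–120 and HFO
  120–250 Hz; stimulation epochs are reported as portions of baseline
  power per band.
* **Theta-speed coupling.** Pearson R² between the per-step dominant
  theta frequency and running speed; under fixed-frequency pacing the
  dominant frequency stops varying and the relation is zero/undefined.
* **Quiet rest.** Theta and delta are band-passed, Hilbert amplitude
  envelopes taken, their ratio z-scored over the session, and rest is
  z < 0. Because the envelope ratio is right-skewed, somewhat more than
  half (~2/3) of a stationary signal falls below its mean; the mask is
  used as an eligibility gate for ripple counting, where this bias is
  immaterial.
* **Ripples.** The 150–250 Hz band signal is z-scored; the detection
  statistic is its Hilbert envelope smoothed with a 10-ms Gaussian
  (about two ripple cycles). Peaks >= 4 SD separated by >= 30 ms are
  events; width is the time the envelope stays above half threshold.
  Detecting on the raw oscillatory signal would make individual cycles of
  band-limited Gaussian noise cross a 4-SD peak threshold a few times per
  minute; the envelope statistic brings the false-alarm rate on
  burst-free noise to < 0.05 events/min while recovering >= 90% of
  injected 8-SD bursts within ±10 ms.

## The synthetic-data generator

The generator's role is to provide ground truth for every downstream
stage. Behavior, neurons and LFP are pure functions of their parameters
and a seed.

**Trajectory.** Runs are piecewise-constant-velocity with per-run speed
jitter (CV 0.45) around 20 cm/s, plus the non-stereotyped movements real
mice show: slow sniffing departures from the reward site, brief
sub-threshold hesitations, supra-threshold mid-run exploration meanders,
long rest bouts (3–40 s), partial double-backs (10–60 cm) that do not
reach the end sensors, occasional full returns (errors, 2% per run) and
false starts (15% of trials). A per-trial motivational state
(quantile-stratified log-normal pace factor, CV ≈ 0.45, with rest
propensity inversely coupled) makes some trials fast and direct and
others slow and resty. These behaviors are not decoration: on a
back-and-forth track a perfectly stereotyped trajectory makes `d` a
deterministic function of (run index, `x`) and `t` nearly so, in which
case every position-tuned cell genuinely carries distance information and
exclusive coding cannot exist even in principle. The non-stereotypy is
what mixes the three variables apart, as it does in real sessions. With
the default rates the expected fraction of correct trials is ~0.78.

**Neurons.** Per frame, activation is Bernoulli with
`p = baseline + (peak − baseline) * prod_c exp(−(v_c − center_c)² / 2 width_c²)`
(defaults peak 0.3, baseline 0.02). A per-traversal engagement gate
(`visit_reliability`) makes each pass through the field engage the cell
with fixed probability, reproducing the across-pass variability of CA1
calcium activity; the defaults equalize engaged passes per session across
classes (a place field is crossed every run, a time or distance field
once per trial). Traces are the activation train convolved with a
single-exponential kernel (tau 0.5 s, unit amplitude, no rise time —
sufficient to exercise a rising-edge binarizer) plus Gaussian noise.
Default field-center bands (place 15–129 cm, time 8–50 s, distance
60–500 cm) trim the strongly degenerate region near the trial origin,
where movement continuity ties the three variables together and an
exclusive label is undefined, while keeping broad coverage for decoding.

**LFP.** 1/f background plus a theta component whose instantaneous
frequency is `6 Hz + 0.05 Hz/(cm/s) × speed` (free parameters — the
coupling coefficients are not constrained by data). Pacing epochs replace
theta with a fixed 8 Hz sinusoid phase-reset at onset; scrambled epochs
with variance-matched white noise; `random_freq` epochs with one 4–12 Hz
frequency per epoch. Ripples are Gaussian-enveloped (SD 15 ms) sinusoid
bursts, default 180 Hz, amplitude in units of background SD.

**Open field.** An Ornstein-Uhlenbeck velocity random walk reflected at
the walls of a 45 × 45 cm arena; its speed distribution spans rest and
locomotion and it covers a 3 × 3 occupancy grid within 10 minutes.

**What the generator does not emulate.** No biophysical neuron or network
dynamics, no theta phase coding or phase precession in spiking, no
sharp-wave-associated population bursts (ripples are injected into the
LFP only), no sensory noise in tracking, no photobleaching or motion
artifacts in traces, no cross-day remapping statistics. Passing tests
therefore demonstrate that the analysis recovers the constructs it is
designed for under a behaviorally realistic trajectory model, not that it
is robust to every artifact of real recordings.

## Known limitations

* **Exclusive-label recovery saturates near ~0.7.** With well-sampled
  sessions, the shuffle test detects the *genuine* residual dependence
  between the three variables near the trial origin (on the first run
  after reward, distance tracks position; at small elapsed times distance
  is necessarily small; time and distance are co-monotone within a
  trial). A sizable minority of truly single-variable cells is therefore
  classified conjunctive no matter how non-stereotyped the behavior is —
  the misclassification reflects real information, not a miscalibrated
  test (the false-positive rate on untuned cells is at its nominal 5%).
  This mirrors the empirical finding that conjunctive cells outnumber
  exclusive place cells about two to one.
* The white-noise OS calibration is convention-dependent; changing the
  window, taper or interval rule shifts it by ~0.05–0.15.
* Quiet-rest segmentation uses the raw (not log) theta/delta envelope
  ratio, as specified by the source procedure; the skew of that ratio
  biases the rest fraction upward on stationary signals.
* Decoding quality depends on field coverage: variables are decodable
  only where tuned fields tile the range, and the default population
  leaves the first ~8 s / ~60 cm sparsely covered.

## Problem sizes

Defaults were chosen so a full pipeline run is desk-scale: 56-run
(~30 min simulated) sessions of 200 cells, 1000 circular shuffles per
cell and variable, 50 bootstrap surrogates of 160 cells, and LFP segments
of 1–20 minutes at 1 kHz. The complete test suite, including the
end-to-end acceptance checks, runs in a few minutes on one CPU.
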