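# Methods

## Scientific problem

Sensorimotor beta oscillations (15–35 Hz) occur as transient bursts.
The analysis implemented here asks whether a cortical beta burst is
accompanied by a transient rise in phase synchrony between the cortical
source and forearm muscles (CMC) and among the muscles (IMC), and
whether that association is specific to static posture holding (F0) as
opposed to resisting pulsed force perturbations of two strengths
(F1, F2). The package provides the full chain — synthetic cohort
generation, preprocessing, burst detection, sliding-window PLV,
burst-aligned map construction, and permutation-cluster inference —
with ground truth at every stage.

## Synthetic cohort generator

### Task structure

`TaskConfig` defaults reproduce the full experimental layout: 10 blocks
of 36 trials (12 per force condition per block, so 360 trials, 120 per
condition), phases Ready (2 s), Steady (4–5 s uniform), Go/reach
(latency + minimum-jerk movement + return), Relax (4–5 s), at 2048 Hz.
Conditions are shuffled within block; reach directions are balanced per
condition within block. A `fast` preset (2 blocks × 9 trials, Steady
3.6–4.2 s, 512 Hz) keeps the test and validation suites inside a few
minutes on one core; the methods are scale-free in everything but
statistical power, and the power-sensitive suites state their cohort
sizes below.

### Signal model

Each block is one continuous 5-channel recording (CTX + 4 bipolar EMGs):

* **Cortex** = 1/f^1 background + beta carrier + weak gamma carrier +
  optional 50 Hz line. The beta carrier has a Wiener-process phase
  (Lorentzian linewidth, default 3 Hz) and a slowly varying lognormal
  amplitude (σ = 0.5, ~0.7 Hz bandwidth). Bursts are placed in Steady
  phases by a homogeneous Poisson process (rates per condition default
  0.41/0.30/0.31 s⁻¹ at full scale, matching the reported per-condition
  burst counts of roughly 220/162/169 over 120 trials), with truncated
  log-normal durations (median ≈ 0.2 s, support [0.05, 0.6] s, mean
  ≈ 230 ms in F0) and an additive envelope elevation (gain 3.0/2.7/2.8).
  The lognormal AM matters: without it a burst is a 5-σ outlier of the
  band-filtered signal and the 4-SD artifact rule (below) rejects every
  burst trial, which real data plainly does not do.
* **EMG_j** = condition-scaled (1×/2×/3× for F0/F1/F2 during Steady)
  broadband noise (20–450 Hz shaped, rectification omitted) + a beta
  component of amplitude 0.5. Outside coupled bursts each EMG runs its
  **own independent beta oscillator**, so cross-channel phase
  differences drift and short-window PLV sits at its null floor. Inside
  a coupled burst the EMG beta phase is cross-faded (30 ms ramps) to the
  cortical carrier phase plus a **constant per-burst offset drawn from a
  von Mises distribution** with concentration κ(condition) — by default
  κ = 8 in F0 and 0 elsewhere. A burst is thus modelled as a single
  communication event with a fixed phase relation; the expected
  resultant of the offsets across bursts is the analytic target
  I₁(κ)/I₀(κ), which the parameter-recovery tests check to ±0.05.
  An earlier design that re-drew the offset every ~100 ms inside a burst
  was abandoned: the band-pass/Hilbert phase extraction (ring time
  comparable to a burst) cannot track offsets that change faster than
  the filter, and the piecewise-constant offsets inflate the no-burst
  sliding-window PLV toward 1.
* **Kinematics** (1 kHz): hold wobble (1.5 mm RMS smoothed noise), and
  in F1/F2 a damped displacement response (τ = 50 ms) to each 100 ms
  perturbation pulse with amplitude 4/8 mm and a random direction that
  never repeats its quadrant more than twice. τ is chosen so successive
  responses overlap and the speed trace oscillates at the 10 Hz pulse
  rate rather than its first harmonic. Reaches are minimum-jerk
  (latency 0.25 s, movement 0.6–0.7 s), which gives a closed form for
  the 10%-displacement reaction time used as a test oracle. Kinematics
  are generated independently of the neural channels given the trial
  labels.

`GroundTruth` carries every injected interval, the per-sample coupling
state, and the analytic target PLV per condition; generation is
bit-reproducible from a single seed.

### What the generator does not emulate

No volume conduction or channel mixing, no motor-unit EMG physiology
(the EMG is shaped noise, not spike trains), no ocular/movement
artifacts, no burst–kinematics relationship, no direction-dependent
muscle tuning. Consequently, passing tests demonstrate that the
*pipeline* recovers the statistical structure it assumes — not that the
biological claim is true of real data, and not robustness against
artifact classes the generator never produces.

## Preprocessing

Two-pass (zero-phase) second-order Butterworth high-pass at 1 Hz and
low-pass at 100 Hz, plus an IIR notch at 50 Hz (Q = 35, configurable).
Time–frequency decomposition is a 10-cycle complex Morlet CWT on a
1–100 Hz grid in 1 Hz steps (the fast presets use coarser grids). Maps
may be decimated in time (default factor 16, i.e. 128 Hz at full rate,
32 Hz in the fast preset); the 10-cycle Morlet envelope bandwidth
(f/10 Hz) is far below the decimated Nyquist, so no envelope information
is lost. Amplitudes are z-scored per 1 Hz frequency over each block,
with the first and last 0.5 s excluded from the statistics to avoid
filter/wavelet edge transients.

Trial rejection applies two sequential rules on the cortical source:
(1) any sample of |x| above mean(|x|) + 6·SD, and (2) any sample of the
15–35 Hz band-passed amplitude above mean(|x_bp|) + 4·SD(x_bp). The SD
in rule 2 is that of the (zero-mean) filtered signal, not of its
rectified amplitude: the rule is an artifact guard, and on data whose
beta envelope is lognormally modulated the rectified-amplitude SD is so
small that the rule would reject essentially every burst-carrying trial.
With the signal-SD reading the generator's rejection rate is ~9%, in
line with an artifact rule. Visual inspection rejection is out of scope;
the flags and reasons are reported per trial instead.

## Burst detection

Detection operates on the z-scored beta-band (15–35 Hz mean) series of
the whole block; the 75th-percentile threshold pools all conditions of
the block, so the three conditions share one raw threshold. Bursts are
maximal strictly-supra-threshold runs spanning at least
⌈0.1 s · fs_map⌉ samples; no-burst epochs are sub-50th-percentile runs
of ≥ 500 ms with no burst ending in the preceding 500 ms, kept only if
their onset lies in a Steady phase of a non-rejected trial. Burst
condition and phase are those of the trial containing the onset. Gamma
bursts use the identical rule on the 55–90 Hz series. Detection is
invariant under strictly monotone rescaling of the series
(percentile-based), which the tests assert.

Onset accuracy of a percentile detector depends on where the pooled
threshold cuts the Morlet-smoothed envelope: at very high burst gain the
threshold sits low on the rising edge and onsets are detected early by a
substantial fraction of the wavelet width. The high-SNR fidelity suite
therefore uses ~30% Steady occupancy at gain 2.5, where the threshold
crosses near the envelope half-rise; there the detector achieves
recall ≥ 0.99, ≈ 0.02 false detections per Steady phase, and a median
onset error just under one map time step (31.25 ms at the fast-preset
rate).

## Connectivity

Per centre frequency the signal is band-passed (two-pass Butterworth,
default width 8 Hz) and Hilbert-transformed; the PLV at each sample is
the resultant length of the phase difference over a centred 250 ms
window, with incomplete edge windows marked invalid (NaN) and never
averaged into epochs. The phase bandwidth default of 8 Hz is wider than
the 1 Hz map step on purpose: a ±2 Hz filter rings for ~0.5 s — longer
than a burst — and can neither track the onset of burst-locked coupling
nor let uncoupled phases drift within a window, which both flattens the
contrast and raises the null floor.

IMC maps are computed on the continuous block and then epoched
[−0.4, +0.8] s around burst / no-burst onsets (epochs crossing invalid
or out-of-range samples are dropped); pair maps are averaged (6 EMG
pairs), then blocks are combined weighted by epoch count, then
participants contribute equal-weight means to the group. CMC uses the
same phases but epoch-level PLV, because its comparison condition keeps
the cortical epochs fixed and permutes the EMG epoch assignment
(8 shuffles averaged, identity permutations re-rolled).

A participant enters a condition's group comparison only with at least
3 burst **and** 3 no-burst epochs (`min_epochs`). Means over one or two
PLV windows are heavy-tailed, and cohorts containing such participants
showed a 2–4× inflated pipeline-level false-positive rate under the
sign-flip cluster null even though the cluster test itself is exactly
calibrated on Gaussian cohorts; requiring 3 epochs restores the nominal
rate (measured ≤ 0.1 at n = 16 with the criterion seeds).

## Statistics

* **Cluster permutation**: per-pixel paired *t* across participants;
  pixels with t > 1.645 (the one-sided 5% normal critical value) form
  4-connected clusters (8-connectivity optional); the null records, for
  each of n_perm sign-flip permutations, the maximal cluster size and
  maximal accumulated *t*; p = (1 + #{null ≥ observed})/(1 + n_perm) for
  both statistics, accumulated-*t* primary. Only positive clusters are
  formed by default, matching the one-sided threshold. Zero-variance
  pixels get t = 0 and cannot enter clusters. Sign flips leave Σd²
  unchanged, so all permutation t-maps come from one matrix product —
  the 200-cohort calibration (n = 20, 40×60 maps, 500 permutations)
  runs in ~20 s and lands within [0.02, 0.08] at nominal 0.05.
* **Wilcoxon signed-rank**: normal approximation without continuity
  correction, zero differences dropped, mid-ranks with tie-corrected
  variance. Effect size r = |Z|/√n (n = all pairs) signed by the median
  difference — chosen because the complete-separation identity at
  n = 20 gives Z = −3.92 and |Z|/√20 = 0.88, whereas the matched-pairs
  rank-biserial correlation would be 1.0.
* **RM-ANOVA**: one-way within-subject sums of squares with
  Greenhouse–Geisser ε from the double-centred covariance applied to
  both dfs. Implemented directly (a few lines) so that `pingouin` can
  act as an independent oracle in the tests. The primary effect size is
  **partial** η² = SS_cond/(SS_cond + SS_err); SS_cond/SS_total is also
  reported. Partial η² is the convention consistent with published
  values of ~0.97 alongside huge F on behavioural data that necessarily
  carries between-subject variance.
* **Holm–Bonferroni** via `statsmodels.multipletests`.

## Pipeline and controls

`run_pipeline` simulates a cohort, analyses each participant, runs the
group statistics, and persists: burst and band-amplitude tables, delta
tables, cluster and ANOVA/post-hoc test tables, t-maps with
significance masks (HDF5), behavioural tables, and figures (difference
maps with significance contours, band amplitudes, delta summaries). All
tables are byte-identical across reruns with the same seed.

`report_burst_controls` re-aligns each participant's stored continuous
IMC/CMC maps to burst subsets, so the controls recompute no PLV:
median-split (low/high amplitude and duration, ties to the low half,
low half gets ⌈n/2⌉) compares the low-F0 delta against the normal F1/F2
deltas with Wilcoxon tests; subsampling draws equal numbers of bursts
per condition without replacement (defaults 100 × 100 at full scale)
and reports the averaged deltas, with explicit per-participant skip
records when a condition lacks the requested count. For these controls
the CMC baseline is the no-burst alignment of the continuous CMC map
(not the epoch-shuffle surrogate), a deliberate simplification noted
here because the shuffle requires per-subset epoch recomputation.

Reaching-phase burst analysis is not implemented; burst counts per
phase are available in the burst tables.

## Validation scales

The heavy suites use reduced but stated sizes chosen to keep the whole
test run near four minutes on one core: type-I calibration at 200 null
Gaussian cohorts (n = 20, 40×60, 500 permutations); parameter recovery
at 10 replicate cohorts per coupling state, 16 participants each, fast
preset, 200 permutations — coupled (κ = 8) cohorts must show a
significant F0 beta-band IMC cluster in ≥ 90% of replicates and
uncoupled (κ = 0) in ≤ 10%.

## Known limitations

* The no-burst epoch supply is the power bottleneck at small scale; the
  `min_epochs` guard trades participants for calibration.
* Percentile-threshold detection necessarily "detects" threshold
  crossings of the background as bursts (~50% of detections at default
  SNR); in the generator only injected bursts carry coupling, so
  measured deltas understate the per-event coupling strength — the
  paper-scale interpretation is unaffected because inference is on the
  contrast, not the magnitude.
* EDF output is 16-bit; round-trip error is bounded by the quantisation
  step (~1/65000 of the channel range), verified against MNE's reader.
* The sliding-window PLV floor for narrow-band signals is well above
  zero and depends on carrier linewidth and filter bandwidth; all
  comparisons are therefore within-pipeline contrasts, never absolute
  PLV levels.
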