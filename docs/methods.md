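# Methods

`nirsav` reimplements, as a tested pipeline, a cross-sectional infant fNIRS
analysis of audiovisual-speech integration: a 46-channel bilateral
fronto-temporal montage records dual-wavelength (780/850 nm) intensities
while infants watch 8 s trials of either synchronous audiovisual syllables
(the *bimodal* condition) or the same auditory and visual syllables
presented without temporal overlap (the *alternating unimodal* condition),
separated by 9–12 s jittered baselines, three trials per condition in every
2-minute block.  Because no recordings are distributed with the study, every
stage is driven and validated by a seeded synthetic-cohort generator with
known ground truth.

## Synthetic cohorts

Each simulated participant is built in concentration space and pushed
through the exact inverse of the analysis' Beer–Lambert conversion:

* **Evoked response.**  A gamma kernel (shape k = 6) convolved with the 8 s
  stimulus boxcar; the kernel scale is derived in closed form,
  τ = D / ((k−1) ln(t\*/(t\*−D))), so that the convolved response peaks at
  t\* = 9 s after onset (D = 8 s), matching the latency the analysis
  windows were designed around.  The convolution itself has the closed form
  G(t) − G(t−D) with G the gamma CDF, which the tests exploit as a
  quadrature oracle.  Condition amplitudes are set by an additivity gain on
  the alternating-condition amplitude: super-additive effects double the
  bimodal amplitude (gain 2), sub-additive effects halve it (gain 0.5).
  Amplitudes are free parameters in micromolar; no real-data amplitude scale is
  available, so defaults are chosen relative to the noise floor
  (effect studies use 3× the white-noise sd).
* **HbR coupling.**  ΔHbR = −0.3 × ΔHbO for evoked signal (typical
  anticorrelation; only the sign matters to any test), with independent HbR
  noise at half the HbO noise amplitudes.
* **Physiological noise** (per channel, random phase): cardiac 2.0 Hz
  (amplitude 0.2 µM), respiratory 0.6 Hz (0.3 µM), Mayer waves 0.1 Hz
  (0.3 µM), slow drift (0.01 Hz sinusoid plus linear ramp, 0.5 µM), white
  noise sd 0.3 µM.  The bands deliberately straddle the 0.03–0.50 Hz
  analysis passband so that filtering is testable: cardiac and drift fall
  outside it, Mayer waves inside.
* **Motion artifacts**, injected in optical density on top of the forward-
  modelled intensities: channel-specific spikes (Gaussian bumps, 0.6 s,
  0.8 OD, 0.5/min) emulate single-optode decoupling; global baseline shifts
  (2 s boxcar offsets, 0.3 OD, 0.2/min) emulate whole-head movement.  All
  injected segments are recorded as ground truth.
* **Attrition.**  Channels drop out independently (default p = 0.05; a dead
  optode is emulated by scaling its intensity to 10⁻⁴, below the pruning
  floor); per-trial looking proportions are Beta(8, 2) by default.
* **Cohort structure.**  Defaults mirror the study's final sample: 20
  younger and 22 older infants, of whom 3 and 7 are tagged as tested during
  the pandemic (leaving the 17/15 pre-pandemic subsets).

What the generator does **not** emulate: photon transport and scalp
coupling, channel-correlated physiological noise, serial correlation of
looking behaviour, heterogeneous HRF shapes across cortex, or amplitudes
calibrated to real infant data.  Passing tests therefore demonstrate that
the *analysis* behaves correctly (calibrated nulls, faithful rule
application, recoverable planted structure), not that the simulator
reproduces real infant recordings.

## Preprocessing

Stage order is fixed: prune → optical density → motion correction →
exclusion bookkeeping → band-pass → Beer–Lambert → epoching → window means.

* **Pruning.**  A channel is unusable if its mean raw intensity lies outside
  [0.001, 10] at either wavelength.  The bounds apply to raw intensity in
  the device's arbitrary units (the micromolar unit occasionally quoted for
  them is a carry-over from concentration tables).
* **Optical density.**  ΔOD = −log₁₀(I/Ī) with the channel's temporal mean
  as reference, so mean 10^(−ΔOD) = 1 exactly.
* **Motion correction** has three stages.  (1) *Detection*: 1 s sliding
  windows are flagged when peak-to-peak OD exceeds 0.4 or the window sd
  exceeds 15× the channel's median window sd; flagged windows are padded by
  1 s and merged into segments.  (2) *Wavelet despiking* (Daubechies-2):
  detail coefficients farther than 0.8 × IQR from their level median are
  zeroed.  The decomposition depth is capped at 4 levels (detail bands
  ≈0.3–5 Hz at 10 Hz sampling).  This cap matters: motion spikes are
  sub-second events and live in the shallow levels, whereas outlier-zeroing
  in deeper levels clips the haemodynamic response itself — and clips the
  stronger condition harder, which in simulation inverts planted condition
  differences.  (3) *Spline de-trending*: inside detected segments a
  smoothing spline (csaps-style p = 0.99) is fitted and replaced by the
  straight line joining the boundary trend values, re-levelling the segment.
* **Filtering.**  Zero-phase 3rd-order Butterworth band-pass, 0.03–0.50 Hz,
  applied forward–backward (gain ≥ 0.9 at 0.12 Hz; ≤ 0.1 at 0.005 and
  2.0 Hz given 10 Hz sampling).
* **Beer–Lambert.**  ΔOD_λ = (ε_HbO,λ ΔHbO + ε_HbR,λ ΔHbR)·d·DPF per
  sample, solved as a 2×2 system with d = 2 cm and DPF = 5.1 at both
  wavelengths; extinction coefficients from the standard compiled
  haemoglobin tables (780 nm: 710.0 / 1075.44; 850 nm: 1058.0 / 691.32
  M⁻¹cm⁻¹ for HbO/HbR).
* **Epoching and exclusion.**  Epochs span [−5, 20) s around onsets
  (half-open, 0-based seconds).  A trial is motion-rejected on a channel if
  any artifact segment intersects [onset−5, onset+20); a channel is
  excluded after more than 3 motion-hit trials; a trial is looking-rejected
  when the infant watched the screen strictly less than 40% of it (ties at
  exactly 40% are kept); a participant is included iff at least 31 of 46
  channels remain (exactly 31 is enough) and at least 3 trials per
  condition survive.  A trial "survives" at participant level when it is
  not looking-rejected and carries no artifact on any retained channel.
  The rule engine accepts externally supplied artifact segments (ground
  truth or manual coding) in place of the detector's output, which is how
  the exclusion audit isolates rule application from detector performance.
* **Window means.**  Per trial, the temporal mean inside baseline [−5, 0),
  W1 [5, 10) and W2 [10, 15); then the mean over surviving trials.  No
  baseline subtraction is applied — the baseline window is a level of the
  time factor, consumed by the contrast downstream.  Peak latency is
  computed as a QC metric only.

## Channel-wise statistics

For each channel × chromophore × activation window, the planned simple
contrast forms, per participant,
d = (W − baseline)_bimodal − (W − baseline)_alternating and tests d = 0 as
a 1-df F (the squared paired t; df₂ = n−1 within an age group, complete
cases per channel, so error dfs vary across channels with missingness).
Partial η² = F·df₁/(F·df₁+df₂).  With both age groups, age enters as a
between factor (unweighted-means solution for unequal group sizes) and the
age × contrast interaction is reported.  Post-hoc paired comparisons give
the signed condition difference inside the window; the additivity
interpretation is chromophore-dependent: larger HbO (or more negative HbR)
to the bimodal condition ⇒ super-additive; the reverse ⇒ sub-additive;
non-significant contrasts are labelled none.  Benjamini–Hochberg FDR is
applied over channels within each chromophore × window × age-group family,
and both uncorrected and corrected flags are carried.  No sphericity
correction is needed for 1-df contrasts.

## Decoding

Patterns are per-participant condition-average window means over a channel
subset (all / left / right hemisphere), z-scored within channel across all
infants (sample sd over non-missing entries; constant channels dropped).
Leave-one-participant-out: each fold trains a linear SVM (C = 1, no
tuning — tuning would leak across folds) on the 2(N−1) patterns restricted
to the channels available for the test participant and, by default, for all
training participants (a test-only masking mode zero-fills residual
training gaps; z-scored zero is the channel grand mean).  Accuracy is the
proportion of the 2N pattern predictions that are correct (a stricter
both-patterns-correct per-participant rate is reported alongside, since a
printed accuracy like 0.68 of 40 predictions is not an exact multiple of
1/40 and the original counting unit is ambiguous).

Significance: 1000 permutations (calibration studies use 200), each
independently keeping or swapping every participant's two condition labels
— the participant-level scheme preserves the balanced pairing — and the
inclusive estimator p = (1 + #{perm ≥ obs})/(1 + n_perm), so an observed
accuracy above all 1000 permuted ones gives exactly 1/1001, and ties count
against the observation.  Inside permutation loops the SVM is fitted
through scikit-learn's low-level libsvm binding (same compiled solver as
`SVC`; a test asserts prediction equality) because the estimator-API
overhead would dominate the ~10⁵–10⁶ fits of the calibration studies.

Informative channels: restricted to channels available in ≥ 80% of
participants, the classifier is retrained on the two grand-average
condition patterns; per-channel informativeness is the weight times half
the grand-average condition contrast (invariant under class exchange, so
the positive- and negative-class sets coincide), and the informative set is
the top ceil(30%) of eligible channels, ties at the threshold included.

## Power

Within-factor repeated-measures power uses the noncentral-F convention of
the standard power software: λ = f²·n·m·ε/(1−ρ), df₁ = (m−1)ε,
df₂ = (n−k)(m−1)ε.  The implementation was checked against two independent
anchors of that convention (the classic f = 0.25, m = 4, ρ = 0.5,
power-0.80 ⇒ N = 24 example, and the m = 2 equivalence with the paired t
test at d = 0.5 ⇒ N = 34) and against a 10 000-replicate Monte-Carlo
simulation of the compound-symmetric design (agreement within 0.02).  The
package's default reconstruction of the study's analysis is m = 6 (2
conditions × 3 time windows), ρ = 0.5, ε = 1; at the study's group sizes
(n = 20/22 and pre-pandemic 17/15) with f = 0.25 it yields powers of
0.843/0.882/0.765/0.698.  These sit ≈0.01 below the study's reported
values (0.85/0.89/0.78/0.71); no round parameter set reproduces all four
reported values under this convention (entering the medium effect as
partial η² = 0.06, i.e. f ≈ 0.2526, reproduces three of the four), so the
reported values appear to reflect a slightly larger noncentrality than the
stated f = 0.25 implies.  The reconstruction is therefore documented as
approximate rather than forced to match.

## Calibration studies and problem sizes

The validation harness (also behind `scripts/acceptance.py`) uses cohorts
of n = 20, 46 channels, 240 s sessions (two 2-minute blocks, 6 trials per
condition) at 10 Hz:

* type-I calibration of the contrasts: 50 null cohorts through the full
  signal pipeline, rejection rate pooled over channels × chromophores ×
  windows (target 0.05), plus the pooled t of window-minus-baseline
  differences;
* permutation-p uniformity: 200 null cohorts at 200 permutations each.
  These cohorts are drawn at the window-mean level (i.i.d. normal means),
  which is the exact null of the decoding stage — the decoding path
  consumes only window means, so signal-level synthesis would multiply the
  cost without changing what is calibrated.  The inclusive estimator is
  slightly conservative under ties (discrete accuracies), which the KS
  check tolerates;
* recovery: 20 cohorts with super-additive HbO effects (amplitude 3× the
  white-noise sd) on right-hemisphere channels 24/26/27/29 — label
  accuracy, right- vs left-subset decoding, and informative-set coverage;
* exclusion audit: one attrition-heavy cohort (spikes 2/min, global shifts
  0.2/min, 25% channel dropout, Beta(2, 1.5) looking) with ground-truth
  artifact lists fed to the rule engine.

## Known limitations

* The 0.03 Hz high-pass interacts with the block structure: condition
  effects carry energy near and below the corner (trials of one condition
  recur roughly every 40 s), so window-mean contrasts are attenuated
  (roughly halved in simulation) relative to the unfiltered signal.  This
  is a property of the analysis design, shared with the original pipeline,
  not of the implementation.
* Detector-based trial rejection inherits the mask padding (1 s); counts
  based on detected segments can therefore differ from ground-truth-based
  counts near window boundaries.  The audit separates the two concerns
  deliberately.
* The montage's region assignments and adjacency are a reconstruction from
  the published probe diagram; source/detector ids are schematic.
* The tabular dialect stores one long-format intensity table per
  participant and is meant for testing and interchange, not bulk storage.
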