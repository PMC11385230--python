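# Methods

## Scope and model of the data

`netswitch` analyses intracranial EEG (iEEG) recorded while a subject switches
between externally and internally oriented attention. The signal model behind
every stage is: each bipolar channel carries a 1/f-decaying aperiodic
background plus band-limited oscillatory components whose amplitude envelopes
are modulated by the task state. Two channel groups (in the target
application, the default mode network, DMN, and the dorsal attention network,
DAN) behave antagonistically: when one network activates — high-gamma (HGB,
52–120 Hz) power up, low-frequency (< 30 Hz) power down — the other
deactivates, and the two conditions' band-power curves cross over shortly
after the switch at t = 0 s.

The pipeline estimates (i) relative band power (RBP) over time, (ii) the
strength and timing of the condition difference per channel and band, and
(iii) time-resolved inter-network connectivity, directed (DTF, PDC,
Granger–Geweke) and non-directed (PLV).

## Preprocessing

- **Bipolar referencing.** Adjacent contact pairs on a shank, deepest first;
  a broken contact breaks the adjacency chain (no skip-pairing). The channel
  coordinate is the contact-pair midpoint.
- **Filtering.** Zero-phase 6th-order Butterworth: 0.1 Hz high-pass, then
  48–52 and 98–102 Hz band-stops. The high-pass has transients spanning
  seconds; `filter_chain` therefore pads `sosfiltfilt` with 5/f_c seconds of
  signal (scipy's default padding is orders of magnitude too short and leaks
  broadband edge transients into the record).
- **Epoching.** Half-open [−4, 4) s epochs around each switch event at 512 Hz
  (60 trials per condition); analyses are cropped to ±2.3 s so filter and
  window edge effects stay outside the analysis window.
- **Amplitude rejection.** Samples beyond ±6 SD of the channel's session-wide
  mean, with runs extended by 100 ms margins, are masked (never whole
  trials). The mask maps onto the RBP grid by flagging any 0.5 s analysis
  window containing a masked sample.

## Relative band power

Hann-windowed periodograms slide in 31.25 ms steps; window length is 2 s for
delta (0.1–3 Hz), 1 s for theta (4–7 Hz) and 0.5 s for alpha (8–12), beta
(13–30), low-gamma (31–48) and HGB (52–120 Hz). Power in dB (with a floor of
1e−12 of the median power, minimum 1e−30, so silent fixtures stay finite) is
z-scored per frequency bin and channel against the statistics of the entire
recording session, removing the 1/f background; z-scored bins are averaged
within each band. Bins at 48–52 and 98–102 Hz (inclusive) never enter the HGB
average.

When no continuous session exists (trial-only inputs), the z-score factors are
pooled over all time steps and trials of *both* conditions per channel. This
matters: normalizing each condition with its own factors applies two different
monotone maps and measurably shifts the conditions' crossing times (we
observed a deterministic ~12 % shrink of recovered crossover times before
pooling). Any per-(bin, channel) map shared by the two conditions leaves
crossings invariant.

The Morlet path mirrors the STFT grid (constant-Q, 6 cycles, tapering to 3
cycles below 6 Hz so the wavelet support stays inside the epoch) and is used
as an independent estimator for validation, not as the primary path.

## Condition-difference statistics

- **SNR.** Per (t, band, channel): sample variance (ddof = 1) of the two
  condition means divided by the mean of the two within-condition trial
  variances; summarized as 10·log10 of the time-mean over ±2.3 s (−120 dB
  sentinel for zero numerators). Scale-invariant by construction.
- **Channel screening.** Two-sided Wilcoxon rank-sum (exact below n = 10
  without ties, otherwise normal approximation with tie correction) per time
  step; Benjamini–Hochberg FDR at 0.05 jointly across subjects, time steps,
  bands and channels; then a temporal-continuity screen keeps only runs
  strictly longer than 100 ms (≥ 4 consecutive 31.25 ms steps). FDR precedes
  continuity, matching the order in which the procedure is described.
- **Network level.** Trial-averaged values of the significant channels are
  compared between conditions per time step (rank-sum across channels), FDR
  at 0.001 across networks, bands and time steps.
- **Crossover timing.** Subtract the condition-common mean (the residuals are
  exact mirror images), low-pass both residuals at 1 Hz (zero-phase, 6th
  order), report the first sign change of their difference whose linearly
  interpolated crossing lies in [−0.5, 2.0] s. The estimator is unbiased on
  noise-free logistic transitions to within one 31.25 ms step.

## Directed connectivity

Trials are z-scored in time per channel, then split into four fitting bands
(0.1–30, 31–48, 52–98, 102–120 Hz, skipping the line-noise ranges). In each
500 ms window (125 ms steps, 33 positions over ±2.3 s) an MVAR model of fixed
order equal to the integer bandwidth (29, 17, 46, 18) is fitted by least
squares, pooling all trials of a condition; lagged predictors never cross
trial boundaries.

**Numerical choice that matters:** for band-limited, heavily oversampled
signals the lag design matrix is numerically rank-deficient (condition
numbers ~1e19 were typical). Normal-equation solves then produce meaningless
low-frequency model spectra. The estimator therefore uses SVD-based least
squares with a relative singular-value cutoff of 1e−10 (the minimum-norm
solution); only genuinely under-determined designs (observations < k·p) are
an error. This is invisible for well-conditioned processes (VAR-recovery
tests are unchanged) and is what makes the model-implied band power track the
STFT band power at r ≥ 0.95.

From Ā(f) = I − Σ_l A(l)e^(−i2πfl/fs) and H(f) = Ā(f)⁻¹:
DTF (rows of DTF² sum to 1), PDC on the standard Ā convention (columns of
PDC² sum to 1; this convention yields the identity pattern for A = 0), and
GGC from the full multivariate model's H and Z. Measures are evaluated on a
1 Hz grid, z-scored along the window axis per (pair, frequency, condition),
averaged into the six analysis bands and over all cross-network channel
pairs.

**PLV.** 2 Hz-wide zero-phase band-passes over 0–120 Hz (first bin 0.1–2 Hz),
Hilbert phase on the full epoch, across-trial phase-difference consistency
per pair and time step (decimated to the 31.25 ms grid), bins averaged into
analysis bands by their center frequency. For N independent trials the null
mean is √π/(2√N) ≈ 0.114 at N = 60, which the estimator reproduces.

Across-subject comparisons use rank-sum tests per time step and band with FDR
at 0.001 across time steps and bands; subjects enter connectivity only with
at least five significant channels in each network.

## Synthetic cohort generator

The generator is first-class code: it plants exactly the structure the
analysis assumes and returns the ground truth for recovery scoring.

- Background: FFT-shaped Gaussian noise with PSD ∝ 1/f^β (default β = 1).
- Oscillations: narrow-band-filtered Gaussian noise (not sinusoids), so MVAR
  fitting is well-posed; per band the amplitude envelope follows a logistic
  transition (default width 0.3 s, defined as the 12–88 % rise time) centered
  on the planted crossover time, with opposite condition signs in the two
  groups (antagonism) and an optional per-group lag.
- Coupling: a lagged linear mixing term from the driver group's band-limited
  mean into the driven group's channels, whose direction reverses smoothly at
  t = 0 (logistic, 0.2 s); the direction after the switch is configured per
  condition.
- Artifacts: Poisson-random flat-top pulses (default 8 SD, 50 ms) added to
  the deep contact of a random shank, so they survive bipolar referencing and
  their supra-threshold run matches the planted duration.
- Geometry: two-contact shanks whose bipolar derivation returns the planted
  channel exactly (deep contact = channel + per-shank common mode, shallow =
  common mode); midpoints sit on labeled voxels of a small built-in two-region
  atlas volume, so localization is exercised end-to-end.
- Determinism: one `SeedSequence`-spawned stream per subject; identical
  (config, seed) gives bit-identical cohorts.

Defaults follow the emulated study conditions: 512 Hz, ±4 s trials, 60 trials
per condition, sessions of back-to-back trials (~16 min). The default subject
count is 6 — enough for the across-subject connectivity stage (which requires
at least 5 subjects) at desk scale.

What the generator does **not** emulate: volume conduction and realistic head
geometry, epileptiform spike morphology, behavioral reaction-time structure,
inter-subject heterogeneity of electrode coverage. Passing recovery tests
therefore show that the estimators are correct and well-calibrated for the
assumed signal structure, not that real iEEG satisfies that structure.

An auxiliary "AR mode" (`generate_ar_trials`) builds trials from AR(2)
resonators (one per analysis band) with slow sinusoidal envelope modulation
(depth 0.8, period 3 s), the appropriate ground truth for testing whether
MVAR model spectra track band power.

## Validation benchmarks and problem sizes

`netswitch.validation` (used by `scripts/acceptance.py` and the test suite)
runs three benchmarks at sizes chosen for a desk-scale machine:

1. STFT vs Morlet RBP agreement: one cohort, 10 channels per network, 60
   trials per condition, one planted modulation per band; network-mean curves
   correlated per band and condition.
2. MVAR spectral fidelity: AR-mode trials, 3 channels per group, 60 trials;
   model-implied vs STFT band power.
3. Crossover-lag recovery: HGB crossovers planted at 0.5 s (group A) and
   0.72 s (group B), 10 channels per group, 60 trials, 20 independent seeds;
   only the HGB band group is computed since the claim concerns HGB.

Null-calibration tests (type-I control, PLV null) use reduced channel counts
or epoch lengths; trials per condition stay at 60 throughout, since the trial
count is part of the emulated study conditions.

## Known limitations

- The MVAR truncated-SVD cutoff (1e−10) is a fixed numerical choice; data
  scaled by ~1e8 or more would change the truncation behaviour (inputs are
  z-scored in the connectivity path, so this does not arise in practice).
- Zero-phase IIR transients bound how exactly filtering commutes with
  epoching (~1e−5 relative at 1.5 s margins for the notches); all analyses
  keep ≥ 1.5 s between the crop and the epoch edge.
- The network-level test treats channels as exchangeable units and ignores
  within-subject correlation, as does the procedure it implements.
- EDF export quantizes to 16 bits; the lossless `.npz` sidecar is the
  bit-exact record.
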