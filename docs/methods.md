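# Methods

This note records the models behind `kcmod`, the defaults and why they were
chosen, the numerical decisions, and what the synthetic validation does and
does not establish about real data.

## Recording analysis

**Pipeline.** For each cell–stimulus pair (5–7 trials by default, 6 used
throughout), the classifier:

1. band-passes each trial at 100–1000 Hz (2nd-order Butterworth applied
   forward–backward, so zero phase) and detects spikes as local maxima of
   the filtered trace above an amplitude threshold, with a 5 ms refractory
   separation;
2. averages the raw trials pointwise and smooths the mean with a centered
   50 ms moving average (windows truncated at the edges, never padded);
3. measures the baseline mean and SD of that smoothed mean trace over the
   pre-onset window (1 s for light, 3 s for odor) and takes the signed
   extremum of (smoothed mean − baseline mean) within the response window
   (0–0.5 s post-onset for light, 0.2–3 s for odor), choosing whichever
   direction deviates more; an exact tie goes to the positive direction;
4. assigns the category with fixed precedence
   `Spike` > `Excitatory` (z ≥ +4.2) > `InhibitionOnly` (z ≤ −4.2)
   > `NoResponse`, where z is the peak divided by the baseline SD.

**Decisions that the analysis itself had to fix.**

- *Spike threshold.* Detection "by amplitude" needs a scale; the default is
  5 × a robust noise estimate (1.4826 × MAD) of the band-passed trace,
  estimated on a ~8000-sample stride of the trace. The MAD is insensitive to
  the spikes themselves, so the threshold does not drift with firing rate.
- *Filter-rebound suppression.* A band-passed spike leaves a small rebound
  lobe a few ms after the main peak (a few percent of its height). A
  detection within 10 ms of a more than ~3× larger peak is therefore
  discarded as ringing (`sidelobe_window_s`, `sidelobe_ratio`). Genuine
  doublets at the refractory limit have comparable amplitudes and are kept.
- *The `Spike` category criterion.* The original analysis does not state how
  evoked spiking was separated from spontaneous firing. Default here: the
  trial-summed spike count in the response window must exceed the upper 99%
  Poisson bound of the baseline-window count scaled to the response-window
  duration, and at least 2 evoked spikes are required. Both knobs are in
  `ClassifierConfig`.
- *Baseline SD on the smoothed trace.* The 4.2-SD criterion is applied to
  the same smoothed mean trace from which the peak is read. Computing the SD
  on the raw trace instead would roughly triple the effective threshold at
  these noise settings; self-consistency on the smoothed trace is what makes
  a 4.2-SD cut behave like a visual-impression criterion and is what the
  threshold-recovery study verifies.
- *Smoothing window.* 50 ms — long enough to suppress sample-level noise,
  short enough that a fast light-evoked EPSP (10 ms rise) loses only ~10% of
  its peak. The attenuation is visible in the recovery study as a fitted
  threshold slightly above 1× the reference.

## Exact contingency test

Under fixed margins the table probability is multivariate hypergeometric

    P(T) = (∏ᵢ rᵢ!)(∏ⱼ cⱼ!) / (n! ∏ᵢⱼ tᵢⱼ!)

and the two-sided p-value sums P over all margin-preserving tables with
P(T) ≤ P(observed) — the probability-ordering ("as or less probable")
definition, which for 2×2 tables coincides with the classical two-sided
Fisher test. Tables with two rows or columns are enumerated vectorized over
the free cells of one row; general r×c tables recurse row by row with the
last row forced. Probabilities are accumulated as log-factorials (via
`gammaln`), stable well past n = 120 on 2×4 tables.

- *Tie tolerance.* Ties decided in log space with a relative slack of 1e-9:
  log-factorial sums at n ≈ 120 carry absolute error ~1e-11, so exact
  mathematical ties land within this slack, while genuinely distinct
  probabilities on small tables differ by far more. The test suite checks
  agreement to 1e-10 against an exact-rational-arithmetic oracle on every
  2×2 and 2×3 table with n ≤ 15, where ties are decided without any
  tolerance at all.
- *Budget and fallback.* Enumeration refuses (with a pointer to the Monte
  Carlo estimator) beyond a configurable candidate budget. `exact_test_mc`
  samples margin-fixed tables by Patefield's algorithm (scipy's
  `random_table`) and estimates P(P(T) ≤ P(obs)); it agrees with enumeration
  within 3 Monte-Carlo SEs where both run, and its p-value is floored at
  1/n_draws.

## Conditioning scores

PI = (N_A − N_B)/(N_A + N_B) per frame; frames with no tracked flies on
either side are flagged NaN and excluded from pooling rather than imputed.
Each group's PI is signed so avoidance of its punished stimulus is positive,
and LI(frame) = (PI₁ + PI₂)/2 over the reciprocal pair — identical, under
this sign convention, to half the difference of the raw preferences, so the
choice between the two formulations is immaterial. Visual assays pool over
all valid frames of the 90 s test; olfactory assays average the last 10
samples (10 s at 1 Hz) per group first. Positive LI means conditioned
avoidance of the punished stimulus.

## Synthetic generators

**Membrane voltage.** Holding potential −50 mV plus Ornstein–Uhlenbeck noise
(exact AR(1) discretization, stationary start), τ = 20 ms and SD 1.0 mV by
default — membrane noise is temporally correlated, and white noise would
make the 4.2-SD criterion artificially conservative. Events are
stimulus-locked:

- *Spikes*: Poisson count at the profile's rate over the response window;
  the count is drawn first and the times are placed uniformly in the window
  contracted by (N−1)×5 ms and re-expanded, which keeps the count exactly
  Poisson while enforcing the absolute refractory gap. Each spike is
  rendered as a fixed biphasic template (Gaussian depolarization of ~2 ms
  half-width, default 25 mV, with a shallow fast after-hyperpolarization)
  whose peak time is the ground-truth spike time.
- *EPSP/IPSP*: one difference-of-exponentials kernel each, normalized to the
  stated peak; 10 ms rise / 50 ms decay for fast light-evoked excitation and
  100 ms rise / 500 ms decay for slow odor-evoked inhibition. The source
  recordings report phenomenology, not kinetics; these constants are
  exposed per stimulus in `StimulusResponse`.

Traces are stored single precision (~0.1 µV quantization); the smoothing and
baseline statistics are computed in double precision because the moving
average uses cumulative sums.

**Study profiles.** `study_design()` reproduces the recorded design: 12
γd-like cells (light: 20 Hz evoked spiking + 8 mV EPSP; odor: −4 mV slow
IPSP) and 11 α/β-like cells (light: nothing; odor: 8 Hz spiking + 6 mV
EPSP), 2 light and 5 odor stimuli — 24/22 light-cell and 60/55 odor-cell
pairs. Noise SD, spike amplitudes and PSP kinetics are not reported for the
original recordings; the defaults are plausible stand-ins and everything is
configurable.

**Arena.** Each frame, each of 40 flies independently occupies the
punished-stimulus quadrant pair with probability (1−b)/2 (shifted by δ/2
for an optional intrinsic preference shared by both groups), so the expected
signed PI is exactly b and the reciprocal LI cancels δ. Frames are
independent; real fly trajectories are autocorrelated, which would widen —
but not bias — the LI sampling distribution.

**What the validation does and does not show.** Passing tests establish
that the implementation recovers what the generator put in: specificity
≥95% on event-free pairs, the 50% detection point at 4.2 × the smoothed-mean
baseline SD (±15%), spike precision/recall ≥95% at ±1 ms, decisive exact-test
segregation at the design sizes, and unbiased LI recovery. They do not
certify performance on real recordings, whose noise is neither Gaussian nor
stationary (seal drift, synaptic barrages, movement artifacts) and whose
spikes vary in amplitude within a cell.

## Determinism and problem sizes

All randomness descends from one master seed through named `SeedSequence`
substreams (per pair, per trial, per arena group), so every dataset, call
table and manifest is reproducible bit for bit; `run_pipeline` hashes each
output file into a manifest that contains no timestamps or absolute paths.
The replicate studies use 100 seeded replicates of the full design for the
segregation rates, 200 pairs for specificity, an 8-point amplitude grid ×
40 pairs for threshold recovery, and 100–200 arena experiments per
condition — sizes at which the Monte-Carlo error of each reported rate is
well below the margins being tested.

## Known limitations

- The `Spike`-vs-`Excitatory` boundary is our reconstruction; with sparse
  spontaneous firing it reduces to "≥2 evoked spikes", which may differ from
  the original judgment near the boundary.
- Enumeration cost grows quickly for tables wider than 2×4 or totals beyond
  a few hundred; the Monte Carlo fallback covers that regime.
- The arena generator models redistribution, not locomotion; time-resolved
  LI dynamics (e.g. memory decay across the 90 s test) are outside its
  scope.
- Olfactory T-maze counts are scored by the same PI/LI machinery at 1 Hz for
  120 s; the generator emulates only the quadrant arena, so olfactory
  scoring is validated on constructed series rather than simulated ones.
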