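# Methods

`thetatravel` quantifies traveling theta (~8 Hz) waves recorded along a
linear electrode array spanning the dorsoventral axis of the medial
entorhinal cortex (MEC), and asks two questions of such recordings:

1. How much of the dorsoventral phase shift is *waveform-generated* —
   produced by a spatial gradient in the non-sinusoidal shape of the
   theta cycle rather than by genuine timing differences?
2. After removing the waveform-related component, does the residual
   traveling wave behave like a chain of **weakly coupled oscillators**
   (phase lags locked, so time delays shrink as frequency rises) or like
   **fixed-delay propagation** (time delays constant, so phase lags grow
   with frequency)?

Because every stage of this analysis depends on subtle timing estimates,
the package is built around a synthetic session generator whose ground
truth is exact; all quantitative claims in the test suite are statements
about recovery of configured ground truth.

## The analysis chain

**Preprocessing.** Artifacts are voltage swings larger than 5× the signal
RMS; they are excised together with a 500 ms buffer, iteratively on the
progressively cleaned signal until a pass removes nothing (the iteration
matters: a large artifact inflates the RMS and hides smaller ones).
High-amplitude theta epochs are runs where the 6–12 Hz analytic-signal
envelope of the dorsal-most channel exceeds 400 µV for at least 500 ms,
ignoring dips of ≤ 100 ms.  The criterion is evaluated on one reference
channel and applied session-wide so that cross-channel cycle matching
stays well defined; for synthetic sessions whose theta amplitude differs
from the 600 µV reference the threshold is rescaled proportionally.

**Phase estimation.**  Two estimators with complementary biases:

* *Hilbert method*: zero-phase 4th-order Butterworth to 6–12 Hz, then the
  analytic-signal angle.  Smooth and dense, but blind to waveform
  asymmetry (it sees essentially the fundamental).
* *Waveform method*: zero-phase 4th-order Butterworth to 1–25 Hz; local
  maxima/minima whose like-extremum separation lies in [83, 250] ms
  (4–12 Hz periods) become the 0° and 180° anchors; the 90°/270° anchors
  are the samples closest to the mean of the flanking extremum voltages.
  Continuous phase is piecewise linear between anchors (the interpolation
  rule and the 5-sample strict-extremum neighbourhood are our choices;
  ties break to the earliest sample).  Violations of the separation rule
  break the cycle chain; no cycle is emitted there, and the first cycle
  of each chain has undefined peak/trough spans (they need the previous
  cycle's rising anchor).

Phase convention: peak 0°, falling 90°, trough 180°, rising 270°;
circular differences wrap to (−180°, +180°].

**Asymmetry.**  Per cycle, rise/decay = log10(D_rising/D_falling) and
peak/trough = log10(D_peak/D_trough); channel summaries are medians over
cycles.  Negative rise/decay is a sawtooth with a fast rise.

**Conduction delays.**  For each theta cycle on the dorsal-most channel
and each reference phase (peak/fall/trough/rise), every other channel
contributes its nearest same-phase anchor (searched both directions, no
directional bias, up to half a period away).  The offsets of the
*remaining* channels are regressed on anatomical position by IRLS with
Tukey bisquare weights (c = 4.685, MAD scale, ≤ 50 iterations,
convergence at 10⁻⁶); the slope in ms/mm is the cycle's conduction delay
(positive = ventral lags).  The reference channel's own (0, 0) point is
excluded from the fit: its anchor noise displaces all other offsets in
common, and because the cycle period is measured from the same anchors,
including the pinned point couples delay errors to frequency errors and
biases the delay-vs-frequency slope (measured −1.5 ms/Hz on
constant-frequency data).  Non-converged cycles are dropped.

**Asymmetry correction.**  The waveform-related delay between the
reference and channel *j* on one cycle is
`(D_falling_ref − D_rising_ref) − (D_falling_j − D_rising_j)` (ms), with
the reference first so that a dorsal sawtooth → ventral sinusoid
gradient yields a positive waveform-related delay, the same sign as the
propagation delay.  Its per-cycle robust slope against distance is
subtracted from the same cycle's peak-reference delay (pairing is by
reference event); medians are taken after subtraction — the median of
per-cycle differences is not the difference of medians.

**Mechanism test.**  Per converged cycle: frequency f = 1000/T, absolute
corrected delay a (ms/mm), relative delay r = 100·a/T (% period per mm).
OLS slopes of a and r against f carry 95% confidence intervals;
classification is *coupled* when the a-slope is significantly negative
and the r-slope CI spans zero, *fixed* in the mirrored case, else
*inconclusive*.  Three calibration choices deviate from the naive
recipe, each forced by a measured failure mode:

* T comes from the reference channel's elapsed *Hilbert* phase across
  the cycle (T_eff = Δt·360/Δφ): anchor-time errors cancel to first
  order there, whereas the raw anchor-to-anchor period shares its noise
  with the per-cycle delay estimates and biases the r-vs-f slope
  positive.  The across-channel median period is the fallback where the
  Hilbert phase is undefined.
* T is then smoothed with a ~1 s rolling median: per-oscillator phase
  noise produces genuine cycle-to-cycle frequency fluctuations that do
  not move a coupled chain's delays (those follow the smooth common
  drive), so the raw cycle frequency acts as an error-in-variables
  regressor, attenuating the a-slope and rotating the r-slope positive.
* The CIs are batch-means Student-t intervals (slopes on ~10 contiguous
  batches of cycles, t interval on their mean).  Per-cycle bootstrap
  resampling measured only ~85–88% coverage on ground-truth simulations
  — cycles are serially dependent through the slow frequency modulation
  and the background-noise anchor wander — which drove the
  double-significance classification rule to ~12–15% error per session;
  the batch-means interval restores near-nominal coverage and makes the
  test deterministic.

**Multiunit activity.**  600–3000 Hz zero-phase 4th-order bandpass →
analytic-signal magnitude → 4–12 Hz zero-phase 3rd-order bandpass.  Lags
are the peaks of normalized cross-correlograms against the dorsal-most
channel within ±120 ms (boundary peaks flagged and excluded); the
lag-vs-position OLS slope is the multiunit conduction delay.  Requires
≥ 6 kHz sampling; simulated MUA sessions run at 10 kHz.

**Statistics.**  Medians with 95% percentile-bootstrap CIs over 500
resamples; Wilcoxon signed-rank/rank-sum tests with exact small-sample
nulls (at n = 6 a maximal signed-rank statistic of 21 has two-sided
p = 2/2⁶ = 0.03125); within-subject bootstrap CIs subtract subject means
before resampling subjects.  Pearson correlation only for goodness of
fit of linear regressions.

## The synthetic generator

`SimConfig` defaults are the study conditions: 7 channels at 0.566 mm
spacing, 8 Hz theta at 600 µV with a 26.36 °/mm phase gradient,
rise/decay asymmetry −0.43 (dorsal) → −0.11 (ventral) and peak/trough
0.21 → −0.10 interpolated linearly along the array, 1/f background at
150 µV RMS, optional ≥ 5×RMS square-pulse artifacts.  The common
frequency modulation is a slow Ornstein–Uhlenbeck walk (0.1 Hz
bandwidth) clipped to ±1.5 Hz, so cycle frequencies span ≈ 6.5–9.5 Hz —
parameters with no published reference value (noise level, modulation
amplitude, phase noise 0.5 rad/√s, coupling 20 s⁻¹) were fixed once at
values that make
epoch selection behave like the published inclusion criteria and keep
neighbour phase locking above 0.9.

**Mechanisms.** `coupled` integrates a nearest-neighbour lag-seeking
Kuramoto chain, dθ_i/dt = ω(t) + K/2·[sin(θ_{i−1}−θ_i−Δ) +
sin(θ_{i+1}−θ_i+Δ)] + ξ_i with preferred lag Δ = gradient × spacing
(boundary channels use their single neighbour); its stable state has
ventral channels lagging by Δ per step *in phase*, so time delays scale
as 1/f.  `fixed_delay` evaluates one master phase at t − d·x with d the
gradient converted to time at the base frequency; delays are constant in
time.  `synchronized` uses one phase everywhere, so only the waveform
gradient can create apparent delays — the validation case for the
asymmetry correction.  Coupled integration runs at 500 Hz
(Euler–Maruyama) and interpolates unwrapped phases to the 1 kHz analysis
rate; a failure to phase-lock within 10 s (neighbour MRL < 0.8) is
flagged in the session metadata.

**Waveform synthesis.**  The asymmetry *definition* is the piecewise-
linear time-warp of a cosine (`warp_waveform`), with the
under-determined four-segment split closed by f_rp = D_rise·D_peak
(reducing to ¼ in the symmetric case).  The *emitted* waveform, however,
is a band-limited realization: three harmonics, with coefficients
optimized (deterministic continuation from the cosine) so that the
indices *measured through the actual 1–25 Hz analysis chain* equal the
configured targets, under hard constraints of exactly one maximum and
one minimum per cycle and a slope margin away from the extrema (a
near-flat shoulder would turn the filter's small residue into spurious
extrema and break cycle detection).  This matters because the published
asymmetry indices are themselves properties of filtered data: a warped
cosine carries energy above 25 Hz and its measured rise/decay saturates
near −0.41 no matter how extreme the warp, whereas the band-limited
family attains every configured target to ≤ 0.01.  Each harmonic is
divided by the filter's power gain at that harmonic of the *local*
instantaneous frequency, so the filtered waveform matches the design as
the rhythm speeds up and slows down.

**Waveform registration (the key modelling decision).**  A waveform's
timing is only defined relative to some anchor; the generator registers
each channel's measured peak `D_falling − D_rising` *before* the
oscillator's phase anchor (zero for a symmetric waveform), tracking the
instantaneous frequency.  Under `synchronized`, the apparent peak delay
between two channels then equals exactly the waveform-related delay
that the asymmetry correction computes from measured durations — i.e.
the generator embodies the timing model the correction assumes, which
is precisely what a validity test of the correction's *implementation*
requires.  Two consequences are documented rather than hidden:

* The waveform gradient contributes its full (D_fall − D_rise) span to
  apparent peak delays (≈ 12 ms/mm at the default endpoints) and a
  large share of it to the Hilbert gradient.  Pure phase-gradient
  recovery is therefore validated with a flat asymmetry profile; with
  the full default gradient the combined waveform (≈ 41 ms) plus
  oscillator (≈ 31 ms) offsets at the ventral-most channels exceed half
  a theta period, and the nearest-event matching rule aliases — an
  information-theoretic limit of the matching, not an implementation
  defect.  Published MEC recordings (≈ 13 ms/mm total over ≈ 2.8 mm)
  sit far from this regime.
* No registration can make the waveform contribution vanish from both
  the Hilbert gradient and the peak-delay correction simultaneously
  (the fundamental-phase shift of these waveforms is ≈ ¼ of
  D_fall − D_rise, not 0 or 1 of it).

**Spiking.**  Multiunit spikes are an inhomogeneous Poisson process,
λ_i(t) = rate0·(1 + m·cos(θ_i(t) − 180°)) — maximal at the local theta
trough — realized by thinning; each spike adds a ~1 ms biphasic template
to the broadband trace.

## Validation experiments and problem sizes

The experiments in `thetatravel.validation` (run by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use: 6 coupled
sessions × 300 s for pooled Hilbert-gradient recovery (±10%); one 300 s
synchronized session for asymmetry recovery (endpoints ±0.03); one 240 s
synchronized session for correction validity (corrected delay within
±1 ms/mm of zero while the uncorrected wave exceeds 5 ms/mm); 10 + 10
sessions × 240 s for mechanism discrimination (≥ 19/20); one 120 s
10 kHz session for MUA lag recovery (±15%).  The MUA session length was
set after observing that at 60 s the envelope correlogram's one-period
side peak (≈ 84% of the main peak under the default frequency wander)
occasionally wins within the ±120 ms window.

## What the synthetic tests do and do not show

The generator reproduces the statistical structure the analysis relies
on — graded asymmetry, phase gradients with realistic noise and
frequency wander, trough-locked spiking, artifacts — but not real LFP:
no behavioural state changes, no gamma or harmonics beyond the third,
no volume conduction, no layer structure (the layer-decomposition
routine is validated on constructed pair tables), and the waveform
family is smooth by construction.  Passing tests demonstrate that the
estimators recover known ground truth under the stated conditions and
that the correction and mechanism logic are internally consistent; they
do not certify the physiological interpretation of any particular
recording.

## Numerical details

* Filters are `scipy.signal.butter` designs applied with `sosfiltfilt`
  (zero phase); "4th-order bandpass" means `butter(4, [lo, hi])`.
* Coherence: Welch cross-spectra, 1 s Hann windows, 50% overlap (1 Hz
  resolution), accumulated over artifact-free segments and averaged over
  the 6–12 Hz bins; not restricted to high-theta epochs.  Theta power
  follows the same convention.
* Robust line fits: IRLS bisquare as above; a perfect fit (zero MAD)
  converges immediately; all-zero weights abort without convergence.
* Decimation: zero-phase 8th-order Butterworth at 0.4× the target rate,
  then integer subsampling (requires an integer factor).
* Recording files: interleaved little-endian int16 (`lfp.dat`,
  channel-fastest) with a JSON sidecar; voltages quantized by
  `uv_per_count` and clipped to the int16 range with a warning.
* Seeds: a single session seed drives every stochastic element through
  `numpy.random.default_rng`; pipeline orchestration fans out per-stage
  seeds with `SeedSequence`; all bootstraps are seeded.  Identical
  configs and seeds give byte-identical outputs.

## Known limitations

* The per-cycle frequency estimate and the matching rule degrade when
  total cross-array offsets approach half a period (see the aliasing
  note above); arrays much longer than ~4 mm at strong asymmetry
  gradients would need a matching rule with phase-unwrapped continuity.
* The classification rule inherits the brittleness of double
  significance testing: with honestly calibrated 95% CIs, about one
  session in twenty lands `inconclusive` by chance — the expected
  accuracy of the rule is ~19/20 by construction, so occasional 18/20
  batches at unlucky seeds are the rule's nominal type-I error, not an
  implementation defect.
* Exact rank-test nulls apply only without ties; ties fall back to
  mid-rank/asymptotic behaviour.
* Empirical checks against archived in-vivo recordings (published
  gradient and delay values) require those datasets and are out of
  scope for the synthetic validation.
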