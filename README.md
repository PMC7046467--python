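# thetatravel

Traveling theta-wave analysis for multichannel extracellular recordings
along the dorsoventral axis of the medial entorhinal cortex (MEC) — and
a synthetic LFP/spike generator that makes every stage of the analysis
verifiable against exact ground truth.

The rodent MEC, like the hippocampus, shows an ~8 Hz "theta" rhythm
whose phase shifts steadily with anatomical position: a traveling wave.
Two confounds make such waves hard to interpret. First, the *shape* of
the theta cycle changes along the axis (sawtooth-like dorsally, nearly
sinusoidal ventrally), and a waveform gradient alone produces apparent
phase shifts in an otherwise synchronized rhythm. Second, a genuine
wave can arise from very different physiology: weakly coupled
oscillators keep their phase lags Δφ fixed, so the time delay
Δt = Δφ/(360·f) shrinks as theta frequency f rises, whereas fixed-delay
propagation (a travelling pulse, or delayed excitation from one
pacemaker) keeps Δt fixed so Δφ grows with f.

`thetatravel` implements the full chain needed to untangle this:

* artifact rejection (iterative 5×RMS) and high-amplitude theta epoch
  selection (6–12 Hz envelope > 400 µV for ≥ 500 ms);
* theta phase by the Hilbert method (6–12 Hz analytic signal) and by the
  waveform method (1–25 Hz, peak/fall/trough/rise anchors), with cycle
  segmentation and per-cycle rise/fall/peak/trough durations;
* traveling-wave metrics: cycle-triggered averages, phase-offset
  gradients (deg/mm), phase locking (mean resultant length), theta-band
  coherence, power-vs-distance, along- vs across-layer decomposition;
* cycle-wise waveform-asymmetry indices, log10(D_rising/D_falling) and
  log10(D_peak/D_trough);
* per-cycle conduction delays (ms/mm) from robust (IRLS bisquare)
  regression of same-phase event offsets on electrode position, the
  waveform-related delay (D_falling − D_rising differences between
  electrodes), and asymmetry-corrected residual delays;
* the coupled-oscillator vs fixed-delay mechanism test on corrected
  delays vs cycle frequency;
* multiunit "spiking band" (600–3000 Hz) envelope cross-correlation
  lags, showing whether spiking forms the same wave as the LFP;
* a seeded generator (`SimConfig`/`simulate_session`) producing
  multichannel LFP under coupled, fixed-delay or synchronized dynamics
  with a controllable waveform-asymmetry gradient, 1/f background,
  artifacts and trough-locked multiunit spiking.

It is aimed at electrophysiologists analysing linear-array LFP and at
methodologists studying how waveform shape contaminates phase metrics.

## Worked example

A deliberately treacherous case: a rhythm that is perfectly
*synchronized* across all seven channels but carries the default
waveform-asymmetry gradient (rise/decay −0.43 dorsally → −0.11
ventrally). Everything below is computed from the synthetic recording
alone — the analysis does not see the ground truth.

```python
from thetatravel import SimConfig, ThetaTravelingWave

config = SimConfig(mechanism="synchronized", duration_s=240, seed=42)
model, truth = ThetaTravelingWave.simulate(config)
results = model.fit(min_cycles_mechanism=10**9)  # skip the mechanism test
print(results.summary())
```

```
Traveling theta wave analysis
================================================================
channels: 7   span: 3.396 mm   theta epochs: 236.1 s   artifacts removed: 0.00 %
----------------------------------------------------------------
Hilbert phase gradient    19.52 deg/mm   r2 = 0.9599
phase-locking slope     -0.0006 /mm
coherence slope         -0.0518 /mm
rel. power slope         0.1513 /mm
----------------------------------------------------------------
waveform asymmetry (median log10 ratio, dorsal -> ventral)
  rise/decay  -0.422 -> -0.109
  peak/trough +0.167 -> -0.100
----------------------------------------------------------------
conduction delay (ms/mm, median over cycles)
  peak  12.43   falling   2.50   trough   6.23   rising   9.34
  waveform-related delay   12.22 ms/mm
  asymmetry-corrected       0.02 ms/mm [-0.07, 0.19]
================================================================
```

Read bottom-up: the peak-referenced conduction delay (12.4 ms/mm) and
the Hilbert gradient (19.5 deg/mm) both announce a robust traveling
wave — yet nothing travels here. The waveform method recovers the
configured asymmetry gradient, the waveform-related delay predicted
from the duration differences (12.2 ms/mm) matches the observed delay,
and the asymmetry-corrected residual is 0.02 ms/mm with a CI spanning
zero: the "wave" is entirely waveform-generated, and the correction
says so.

A genuinely coupled-oscillator session (flat waveform this time) shows
the other signature — delays that shrink as frequency rises while the
relative (phase) delay stays put:

```python
config = SimConfig(mechanism="coupled", duration_s=240, seed=42,
                   asym_rd_dorsal=0.0, asym_rd_ventral=0.0,
                   asym_pt_dorsal=0.0, asym_pt_ventral=0.0)
model, truth = ThetaTravelingWave.simulate(config)
results = model.fit()
```

```
Hilbert phase gradient    26.55 deg/mm   r2 = 1.0000   (configured: 26.36)
...
mechanism test over 1816 cycles:
  abs delay vs freq  -1.258 ms/Hz  CI [-1.726, -0.842]
  rel delay vs freq  -0.057 %/Hz   CI [-0.447, +0.303]
  classification: coupled
```

The theoretical slope for a phase-locked chain at Δφ = 26.36 deg/mm is
−Δφ·1000/(360·f²) ≈ −1.14 ms/Hz per mm at 8 Hz; the fitted −1.26 with a
CI excluding zero, alongside a relative-delay slope straddling zero,
classifies the session as coupled.

`results.plot("overview.png")` writes a four-panel figure (offset
gradient, asymmetry profile, delay-by-phase, delay-vs-frequency).

## Command line

```bash
thetatravel simulate  --config sim.yaml --out session/   # + --mua for spikes
thetatravel preprocess --in session/ --out epochs.csv
thetatravel analyze all --in session/ --out results.json
thetatravel report --sessions s1/ --sessions s2/ --out report.json
thetatravel run-all --config sim.yaml --out session/ --seed 1
```

Configs are YAML/JSON mirrors of `SimConfig`; recordings are flat
interleaved int16 (`lfp.dat`) with a JSON sidecar, readable with
`thetatravel.read_recording`. Real 30 kHz acquisitions can be brought to
the 1 kHz analysis rate with `thetatravel.decimate`.

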