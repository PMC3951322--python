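# laminar-ephys

Analysis of evoked field responses recorded along the hippocampal
CA1–dentate gyrus (DG) axis with linear multi-contact probes, for
electrophysiologists studying synaptic transmission and short-term
plasticity in vivo.  The package implements the full quantification chain
for perforant-path–type stimulation experiments:

- **Five-point fEPSP measurement** — amplitude and latency from cursor
  points placed on the averaged response: point 1 before the stimulus
  artifact, points 2–3 bracketing the response onset, points 4–5
  bracketing the peak/trough.  Amplitude = extremum(p4..p5) − mean(p2..p3);
  latency = midpoint(p4, p5) − t(p1).
- **Population-spike (PS) detection** — fast biphasic transients on the
  granule-layer trace, with per-interval PS probability (n out of 20
  sweeps).
- **1-D current-source-density (CSD)** — the second spatial difference
  over neighbouring contacts, CSD(z) = −σ·[φ(z+Δ) − 2φ(z) + φ(z−Δ)]/Δ²,
  with 20-step linear interpolation and self-normalised rendering
  (sources warm, neutral green, sinks cool).
- **Plasticity indices** — input/output curves with half-maximal current,
  paired-pulse percent change at {25, 50, 100, 200, 500, 1000} ms
  (100·(P2 − P1)/P1; positive = facilitation), and per-pulse profiles over
  20-pulse 5 Hz trains.
- **Re-entrance detection** — long-latency (~12–25 ms) secondary
  responses that appear mid-train as activity re-enters the hippocampus
  through entorhinal cortex, called from template-subtracted residuals.
- **A forward simulator** — a 1-D Poisson model (d²φ/dz² = −C/σ) turns
  programmed sink/source catalogues into laminar recordings with known
  ground truth (gains, PS occurrences, re-entrance schedule), so every
  stage of the chain is testable without animal data.

## Worked example

Two programmed excitability phenotypes — a control-like profile with
paired-pulse depression in DG at short intervals, and a hyper-excitable
"AD-like" profile with facilitation — simulated at default noise and run
through segmentation, template measurement and the paired-pulse index
(`examples/04_paired_pulse_profile.py`):

```text
control-like (programmed DG gains: 25 ms x0.80, 50 ms x0.85)
  PPI  25 ms: DG amplitude change -18.6% (SEM 1.2, n=20 pairs)
  PPI  50 ms: DG amplitude change -14.2% (SEM 1.4, n=20 pairs)

ad-like (programmed DG gains: 25 ms x1.25, 50 ms x1.30)
  PPI  25 ms: DG amplitude change +26.1% (SEM 1.5, n=20 pairs)
  PPI  50 ms: DG amplitude change +28.9% (SEM 1.9, n=20 pairs)
```

The recovered percent changes track the programmed gains (0.80 → −20%,
1.30 → +30%) within the noise of 20 repeats, and the depression-vs-
facilitation contrast that separates the two phenotypes is recovered with
the correct sign at both intervals.  `examples/05_train_and_reentrance.py`
shows the train analysis: with re-entrance programmed from pulse 10 at a
15.7 ms peak latency, the detector reports `first pulse 10, latency
15.8 ms` in all three layers.

The other scripts in `examples/` each demonstrate one capability
(simulation, fEPSP measurement, CSD mapping, I/O curves, the full
pipeline).  A thin CLI wraps the same functions:

```bash
laminar-ephys simulate --profile ad-like --kind train --seed 1 --out train.h5
laminar-ephys reentry train.h5
laminar-ephys run-all --seed 7 --out results/
```

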