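# Methods

## Scope

`laminar_ephys` quantifies evoked field responses recorded along the
hippocampal CA1–dentate gyrus (DG) axis with a linear multi-contact probe:
five-point fEPSP amplitude/latency measurement, population-spike (PS)
detection and probability, 1-D current-source-density (CSD) estimation,
input/output (I/O) curves with half-maximal current, paired-pulse and
train short-term-plasticity indices, and detection of long-latency
re-entrant responses.  A forward simulator generates laminar recordings
with programmed ground truth so that every stage can be validated without
animal data.  Group-level inferential statistics (mixed ANOVA, post-hoc
corrections) are out of scope: the package produces the per-session
quantities such analyses consume.

## Forward model

The simulator represents evoked activity as a catalogue of CSD components.
Each component is a Gaussian in depth (centre, SD in µm) and an alpha
function in time, `a(t) = s·e^{1−s}` with `s = (t − onset)/τ`, which peaks
exactly one time constant after onset — the simplest smooth shapes matching
mono/biphasic laminar field components.  Sinks are negative, sources
positive; every component carries return current of exactly the opposite
discrete spatial integral, so the depth integral of the density is zero at
every instant (current conservation, enforced to machine precision).

Potentials follow the 1-D Poisson relation `d²φ/dz² = −C/σ` with spatially
homogeneous conductivity σ, solved on a depth grid at least 4× finer than
the contact spacing, extending 500 µm beyond the probe ends with
zero-potential (far-field) boundaries, and sampled at the contact depths.
This is the exact inverse of the second-spatial-difference estimator used
for analysis, which is what makes forward/inverse round-trip tests
meaningful.

**Return-current placement.** In a bounded 1-D volume conductor a one-sided
sink/source pair has a non-zero dipole moment, and its potential does not
decay — it drapes a linear far field across every other layer, which is an
artefact of collapsing 3-D volume conduction to 1-D.  The simulator
therefore splits each component's return current between
`centre ± paired_return_offset` (`return_fraction`, default 0.5 =
symmetric, zero dipole moment, compact potential).  The DG molecular-layer
sink is the exception: its granule-cell return source is anatomically
one-sided (`return_fraction = 1`), which is also what makes the dentate
response positive-going at the granule-layer contact where it is measured.

**Default catalogue.** CA1 stratum lacunosum-moleculare sink (600 µm,
SD 150 µm, onset 4 ms, τ 2 ms — peak 6 ms), DG molecular-layer sink
(900 µm, SD 150 µm, onset 5.5 ms, peak 7.5 ms, granule source at 1100 µm),
CA1 stratum radiatum sink (300 µm, SD 130 µm, onset 6 ms, peak 8 ms).
Peak densities (2.0 / 4.0 / 1.5 a.u.) and the conductivity calibration
(3×10⁴ a.u.) were chosen once so that contact fEPSPs span ~1–6 mV — the
in vivo scale — with the DG granule-layer response near 1 mV.  Measured
peak latency at a contact reflects the superposition of all components'
fields at that depth, as in real laminar recordings.

## Protocols and excitability profiles

Protocols mirror the experimental battery: an I/O series (pairs at 50 ms
over 50–600 µA; the first pulse of each pair is analysed), paired pulses at
intervals {25, 50, 100, 200, 500, 1000} ms repeated 20 times with 3 s
between pairs, and a single 20-pulse train at 5 Hz.  Stimulus current maps
to response gain through a Hill sigmoid (half point 175 µA, coefficient 2)
normalised to 1 at 200 µA — the paper-free part of the model, since no
amplitude-vs-current calibration is published for this preparation; the
half point sits inside the typical half-maximal range (100–200 µA).  The
repeat count for the I/O series (default 5 in the pipeline config, 1–3 in
tests) is a simulator-scale choice; pairs keep the full 20.

An `ExcitabilityProfile` programs the phenotype: per-interval gains on the
second pulse, twenty per-pulse train gains, a PS threshold, and an optional
re-entrance schedule (first pulse, latency-to-peak).  The built-in
*control-like* profile depresses DG at 25–50 ms (gains 0.80/0.85),
recovers by 200 ms, facilitates over the train (saturating ramp to 1.5)
and, when enabled, re-enters only at pulse 20.  The *ad-like* profile
facilitates at short intervals (1.25/1.30), facilitates modestly over the
train (ramp to 1.2) and develops re-entrance mid-train (default pulse 10,
peak 15.7 ms).  These defaults encode the qualitative fingerprints the
package is designed to separate, not quantitative targets.

Population spikes are modelled additively — a derivative-of-Gaussian
biphasic transient (σ 0.3 ms, ~1–2 ms wide, default 1 mV) injected at the
granule layer 0.5 ms after the DG field peak whenever the scaled DG
amplitude exceeds the profile's threshold.  With multiplicative
trial-to-trial amplitude jitter (`amp_jitter_sd`, default 0 so that
zero-noise runs are fully deterministic), threshold crossing becomes
stochastic; `ps_threshold_for_probability` places the threshold at the
Gaussian quantile that yields a requested per-sweep PS probability.
Recording noise is Gaussian, band-limited to the acquisition band
(0.1 Hz – 6 kHz, with the upper corner capped at 0.45× the sampling rate
since 6 kHz exceeds the 10 kHz Nyquist limit), rescaled to the requested
SD (default 0.05 mV).  A biphasic 0.2 ms stimulus artifact (default 5 mV)
marks each pulse.

## Measurement

Sweeps are cut at −10/+40 ms around each pulse (the window covers the
longest re-entrance latencies plus after-potentials).  A baseline-drift
screen excludes sweeps whose pre-stimulus mean deviates from the session
median by more than a tolerance (default 2 mV) — a quantitative stand-in
for the qualitative "recording became unstable" criterion.

The five-point template is placed automatically on the averaged response:
point 1 is the last pre-stimulus sample; the onset is the first
post-artifact sample departing from baseline by more than 3× the baseline
SD; points 2–3 bracket the onset from below (0.4 ms) so their mean is the
response's local baseline and never rides the rising phase; points 4–5
bracket (±0.4 ms) the requested-polarity extremum searched in 2–30 ms.
Amplitude is the extremum between points 4–5 minus the mean between points
2–3 (sign retained); latency is the centre timestamp of points 4–5 minus
point 1's timestamp.  Latency to onset is deliberately not measured.
Polarity is fixed per layer: CA1sr and CA1slm negative-going, DG
positive-going.  Ties in the extremum search break to the earliest sample.
If no sample clears the onset threshold the result is a "no response"
outcome rather than an error; an inverted response yields a low-confidence
flag.  Two robustness choices matter at short paired-pulse intervals:
baseline statistics use only the last 5 ms before the pulse with a linear
detrend (the previous response's decaying tail otherwise inflates the
threshold), and the extremum search is capped 1 ms below the paired-pulse
interval so the next pulse's artifact can never be selected.

For trains, the template is re-placed on every pulse's own trace because
the response profile changes rapidly along the train.  Paired-pulse
percent change is reported from the measurement on the averaged response
(the trace the cursors are placed on); per-repeat ratios supply the SEM.
Measuring the central value on the average avoids the upward bias a
max-over-window estimator picks up on single noisy sweeps — a property of
the measurement definition, not of this implementation.

**PS detection** high-passes the trace by subtracting a 1 ms moving
average and requires supra-threshold residual excursions of *both*
polarities within 2 ms (a PS is biphasic), with the dominant lobe narrower
than 3 ms at half height.  The threshold is 6× the MAD-based SD of the
pre-stimulus residual, floored at 0.12× the response range inside the
search window; the floor keeps the sharp onset corner of a clean fEPSP
(whose high-pass residual is small relative to the response) from
triggering, and the window-restricted range keeps the stimulus artifact
from inflating the floor.  When any sweep of a set shows a PS, all DG
traces of that set are measured with the transient excised by a 2.1 ms
median filter, so first/second-pulse amplitude ratios remain comparable;
the median filter's bias on the smooth field peak is ≲3% and cancels in
the ratio.  PS probability is reported with its count basis (n out of the
repeat count).

**CSD estimation** is the second spatial difference over neighbouring
contacts (smoothing degree 2), `−σ[φ(z+Δ) − 2φ(z) + φ(z−Δ)]/Δ²`, with
conductivity 1 by default since output is in arbitrary units.  Degrees
above 2 activate a Hamming-weighted pre-smoother across contacts.  Edge
contacts are dropped — no extrapolated density.  Rendering inserts 20
linearly interpolated steps between contacts and maps the map's own
(min, max) affinely onto [−1, 1] (sources warm, neutral light green,
sinks dark green to dark blue); zero coincides with neutral only when the
map is symmetric, which the rendering records.  No temporal filtering is
applied before CSD.

**Re-entrance detection** subtracts from each train pulse's trace the
pulse-1 response scaled by least squares over 1.5–10 ms, smooths the
residual (Gaussian, σ 0.5 ms) and tests, inside the 12–25 ms window, for
an excursion exceeding 3× the residual's noise SD sustained for ≥ 1.5 ms.
The noise SD pools the pre-stimulus residual across all 20 pulses — a
single pulse's 10 ms baseline gives too unstable an estimate for a 1%
false-positive budget.  The call's first pulse is the earliest from which
every later pulse qualifies (re-entrance, once established, persists); the
window brackets all re-entrance latencies this preparation produces
(~14–21 ms) and is configurable.

**Half-maximal current** is the smallest current at which the reference
layer (CA1sr) reaches 50% of its maximal amplitude over the tested range,
by piecewise-linear interpolation between tested currents (optionally the
nearest tested current).  It is invariant to uniform amplitude scaling.

## Validation and problem sizes

The acceptance suite (`tests/test_acceptance.py`, recomputed by
`scripts/acceptance.py`) checks: exact equivalence of the vectorised CSD
estimator with a per-sample loop and its closed forms (zero for linear
profiles, exact constant for quadratics); forward/inverse round-trips on
both probe geometries (16×100 µm, 32×50 µm) with programmed spatial SDs of
at least twice the contact spacing, requiring < 5% relative RMS error and
Pearson r > 0.99; template amplitude within 1% of the forward-model oracle
and latency within one sample of the analytic alpha peak at 10 kHz;
paired-pulse and train percent-change recovery — exact at zero noise
(within 1 percentage point at 25–50 ms, where the preceding response's
tail genuinely overlaps the measurement window), and at default noise the
programmed value falls inside the 95% interval of 100 seeded replicate
estimates per interval, with the control-vs-ad sign contrast at 25/50 ms
recovered in ≥ 95% of replicates; PS probability (programmed 0.6 per
sweep, 20 sweeps, 200 replicate sessions) recovered within the binomial
95% CI with ≤ 1% false positives on 1000 noise-only sweeps; re-entrance
first-pulse recovery ({7, 10, 15, 20}) exact at zero noise and within ±1
pulse at default noise, with ≤ 1% false calls over 200 no-re-entrance
trains; and byte-identical fixed-seed pipeline runs plus bit-exact HDF5
round-trips.  The replicate counts above are the problem sizes the
package's own validation uses; the Monte-Carlo interval is the spread of
the replicate estimates (mean ± 1.96 SD), which absorbs the small residual
estimator bias inherent in extremum-based amplitude measures at finite
noise.

## What the simulator does and does not emulate

It emulates the laminar component structure, protocol timing, gain-based
short-term plasticity, stochastic PS occurrence, mid-train re-entrance,
acquisition-band noise and stimulus artifacts.  It does not emulate
spiking neurons or conductance dynamics (the PS is an additive waveform),
3-D volume conduction, electrode drift or impedance variation, latency
jitter of evoked components, inhibitory after-potentials, or any
dependence of plasticity on stimulation history beyond the programmed
gains.  Passing tests therefore demonstrate that the analysis chain
recovers known ground truth under realistic amplitudes, noise and timing —
not that it is robust to every artefact of real tissue recordings.

## Known limitations

- The 1-D forward model with zero-potential boundaries is exact only for
  the homogeneous-conductivity assumption the estimator itself makes.
- Template placement assumes a single dominant deflection per layer; at
  25 ms intervals residual overlap of the preceding response bounds
  zero-noise recovery at ~1% rather than machine precision.
- The PS detector's floor (0.12× response range) trades sensitivity to
  very small spikes for rejection of sharp response onsets; spikes below
  ~15% of the field response will be missed.
- `exclude_unstable` screens baseline drift only; other instability modes
  (gain changes, movement artefacts) are not modelled or screened.
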