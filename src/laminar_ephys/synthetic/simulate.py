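"""Protocol-level simulator: programmed excitability → laminar recording.

``simulate_protocol`` assembles a continuous multi-channel recording for one
stimulation run (I/O series, paired pulses, or a 20-pulse 5 Hz train).  Every
pulse deposits a scaled copy of the catalogue's forward-modelled contact
waveform; population-spike transients, re-entrant components, band-limited
noise and a brief stimulus artifact are added on top, and the programmed
ground truth travels with the recording so any downstream estimate can be
checked against it.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import signal
from scipy.special import ndtri

from ..core import (
    GroundTruth,
    LaminarRecording,
    ProbeGeometry,
    StimulusProtocol,
    ms_to_samples,
)
from .components import (
    CsdComponent,
    ExcitabilityProfile,
    default_component_catalogue,
    reentry_catalogue,
)
from .forward import unit_contact_waveforms

#: Acquisition-style noise band (Hz).  The upper corner is capped below the
#: Nyquist frequency at simulation time.
NOISE_BAND_HZ = (0.1, 6000.0)

#: Stimulus current (µA) at which protocol gains are defined to be 1 —
#: the typical half-maximal current.
REFERENCE_CURRENT_UA = 200.0

#: Default conductivity (arbitrary units) used by the simulator.  CSD output
#: is declared in arbitrary units, so this constant only sets the overall
#: density-to-potential calibration; its value is chosen so the default
#: catalogue produces fEPSPs of ~1–4 mV at the measurement contacts,
#: matching the in vivo scale.
SIM_CONDUCTIVITY = 3e4


def current_gain(
    current_ua: np.ndarray | float, i50_ua: float = 175.0, hill: float = 2.0
) -> np.ndarray | float:
    """Saturating stimulus-current → response-gain map (Hill form).

    The mapping from current to fEPSP size is a free modelling choice; a
    sigmoid with half point ``i50_ua`` inside the typical half-maximal
    range (100–200 µA) gives a realistic saturating input/output curve.
    """
    c = np.asarray(current_ua, dtype=float)
    g = c**hill / (c**hill + i50_ua**hill)
    return float(g) if np.isscalar(current_ua) else g


def ps_threshold_for_probability(
    mean_amplitude_mv: float, amp_jitter_sd: float, probability: float
) -> float:
    """Threshold (mV) giving a target per-sweep population-spike probability.

    With multiplicative amplitude jitter ~ N(1, amp_jitter_sd), the scaled
    DG amplitude exceeds the returned threshold with the requested
    probability.
    """
    if not 0.0 < probability < 1.0:
        raise ValueError("probability must lie strictly between 0 and 1")
    if amp_jitter_sd <= 0:
        raise ValueError("a stochastic PS requires amp_jitter_sd > 0")
    return mean_amplitude_mv * (1.0 + amp_jitter_sd * ndtri(1.0 - probability))


def band_limited_noise(
    rng: np.random.Generator,
    shape: tuple[int, int],
    sampling_rate: float,
    noise_sd_mv: float,
    band_hz: tuple[float, float] = NOISE_BAND_HZ,
) -> np.ndarray:
    """Gaussian noise band-limited to the acquisition band and rescaled to
    the requested standard deviation."""
    lo, hi = band_hz
    hi = min(hi, 0.45 * sampling_rate)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = x.std()
    if sd > 0:
        x *= noise_sd_mv / sd
    return x


def _ps_waveform(sampling_rate: float, amp_mv: float, sigma_ms: float = 0.3) -> np.ndarray:
    """Fast biphasic transient (derivative of a Gaussian, ~1–2 ms total
    width) used as the additive population-spike model."""
    half = ms_to_samples(4 * sigma_ms, sampling_rate)
    t = (np.arange(-half, half + 1) / sampling_rate) * 1e3
    w = -t * np.exp(-0.5 * (t / sigma_ms) ** 2)
    return w / np.max(np.abs(w)) * amp_mv


def _stim_plan(
    protocol: StimulusProtocol, sampling_rate: float, pre_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pulse onset samples and per-pulse currents for one protocol run."""
    onsets_s: list[float] = []
    currents: list[float] = []
    if protocol.kind == "train":
        period = 1.0 / protocol.train_hz
        for k in range(protocol.train_len):
            onsets_s.append(pre_s + k * period)
            currents.append(float(protocol.currents[0]))
    elif protocol.kind == "paired_pulse":
        ppi_s = float(protocol.ppi_ms) * 1e-3
        t = pre_s
        for _ in range(protocol.n_repeats):
            onsets_s.extend([t, t + ppi_s])
            currents.extend([float(protocol.currents[0])] * 2)
            t += ppi_s + protocol.inter_pair_gap_s
    else:  # io_series: pairs at 50 ms per current level
        t = pre_s
        for c in protocol.currents:
            for _ in range(protocol.n_repeats):
                onsets_s.extend([t, t + 0.050])
                currents.extend([float(c), float(c)])
                t += 0.050 + protocol.inter_pair_gap_s
    onsets = np.round(np.asarray(onsets_s) * sampling_rate).astype(np.int64)
    return onsets, np.asarray(currents)


def _pulse_gains(
    protocol: StimulusProtocol,
    profile: ExcitabilityProfile,
    currents: np.ndarray,
    pulse_index: np.ndarray,
    i50_ua: float,
    hill: float,
) -> np.ndarray:
    """Deterministic per-pulse gain before trial-to-trial jitter."""
    if protocol.kind == "train":
        return np.asarray(profile.train_gain[: pulse_index.size], dtype=float)
    gains = np.ones(pulse_index.size)
    if protocol.kind == "paired_pulse":
        gains[pulse_index == 2] = profile.ppi_gain[int(protocol.ppi_ms)]
    else:  # io_series
        ref = current_gain(REFERENCE_CURRENT_UA, i50_ua, hill)
        gains = np.asarray(current_gain(currents, i50_ua, hill)) / ref
        gains[pulse_index == 2] *= profile.ppi_gain[50]
    return gains


def simulate_protocol(
    profile: ExcitabilityProfile,
    protocol: StimulusProtocol,
    geometry: ProbeGeometry | None = None,
    noise_sd: float = 0.05,
    artifact_amp: float = 5.0,
    seed: int = 0,
    *,
    components: Optional[Sequence[CsdComponent]] = None,
    amp_jitter_sd: float = 0.0,
    conductivity: float = SIM_CONDUCTIVITY,
    sampling_rate: float = 10_000.0,
    pre_s: float = 0.5,
    post_s: float = 0.5,
    window_ms: float = 60.0,
    ps_amp_mv: float = 1.0,
    reentry_amp_scale: float = 0.5,
    i50_ua: float = 175.0,
    hill: float = 2.0,
) -> LaminarRecording:
    """Simulate one full stimulation run as a continuous laminar recording.

    Parameters
    ----------
    profile
        Programmed excitability fingerprint (paired-pulse / train gains,
        population-spike threshold, re-entrance schedule).
    protocol
        Stimulation run to emulate.
    noise_sd
        Standard deviation (mV) of the band-limited recording noise.
    artifact_amp
        Peak (mV) of the brief biphasic stimulus artifact (0.2 ms).
    amp_jitter_sd
        SD of multiplicative trial-to-trial amplitude jitter (default 0:
        fully deterministic responses).
    ps_amp_mv, reentry_amp_scale
        Peak of the injected population-spike transient and the amplitude
        of the re-entrant component relative to the direct one.

    Returns
    -------
    LaminarRecording with programmed ground truth attached.  Identical
    arguments and seed yield a bit-identical recording.
    """
    if geometry is None:
        geometry = ProbeGeometry()
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    if components is None:
        components = default_component_catalogue()
    components = tuple(components)
    rng = np.random.default_rng(seed)

    onsets, currents = _stim_plan(protocol, sampling_rate, pre_s)
    win = ms_to_samples(window_ms, sampling_rate)
    n_samples = int(onsets[-1] + win + round(post_s * sampling_rate))
    n_ch = geometry.n_contacts

    unit = unit_contact_waveforms(
        components, geometry, sampling_rate, window_ms, conductivity
    )
    dg_ch = geometry.layer_channel("DG_granule")
    dg_peak_sample = int(np.argmax(np.abs(unit[dg_ch])))
    dg_unit_amp = float(np.abs(unit[dg_ch, dg_peak_sample]))

    rec_kind_train = protocol.kind == "train"
    unit_reentry = None
    if rec_kind_train and profile.reentry_first_pulse is not None:
        re_cat = reentry_catalogue(components, profile.reentry_latency_ms)
        unit_reentry = unit_contact_waveforms(
            re_cat, geometry, sampling_rate, window_ms, conductivity
        )

    if noise_sd > 0:
        potentials = band_limited_noise(rng, (n_ch, n_samples), sampling_rate, noise_sd)
    else:
        potentials = np.zeros((n_ch, n_samples))

    # temporary recording-free pulse labels (1,2,… within pair/train)
    if rec_kind_train:
        pulse_index = np.arange(1, onsets.size + 1)
    else:
        pulse_index = np.empty(onsets.size, dtype=int)
        pulse_index[0::2] = 1
        pulse_index[1::2] = 2

    gains = _pulse_gains(protocol, profile, currents, pulse_index, i50_ua, hill)
    if amp_jitter_sd > 0:
        jitter = rng.normal(1.0, amp_jitter_sd, size=gains.size)
        gains = gains * np.clip(jitter, 0.05, None)

    ps_wave = _ps_waveform(sampling_rate, ps_amp_mv)
    ps_spatial = np.exp(
        -0.5 * ((geometry.contact_depths_um - geometry.contact_depths_um[dg_ch]) / 75.0) ** 2
    )
    ps_flags = np.zeros(onsets.size, dtype=bool)
    ps_times = np.full(onsets.size, np.nan)
    reentry_flags = np.zeros(onsets.size, dtype=bool)
    art_half = max(ms_to_samples(protocol.pulse_width_ms / 2, sampling_rate), 1)

    for k, (s0, g) in enumerate(zip(onsets, gains)):
        potentials[:, s0 : s0 + win] += g * unit
        if rec_kind_train and profile.reentry_first_pulse is not None:
            if pulse_index[k] >= profile.reentry_first_pulse:
                potentials[:, s0 : s0 + win] += reentry_amp_scale * unit_reentry
                reentry_flags[k] = True
        if g * dg_unit_amp > profile.ps_threshold_mv:
            ps_flags[k] = True
            ps_at = s0 + dg_peak_sample + ms_to_samples(0.5, sampling_rate)
            lo = ps_at - (ps_wave.size // 2)
            potentials[:, lo : lo + ps_wave.size] += np.outer(ps_spatial, ps_wave)
            ps_times[k] = (ps_at - s0) / sampling_rate * 1e3
        if artifact_amp != 0:
            potentials[:, s0 : s0 + art_half] += artifact_amp
            potentials[:, s0 + art_half : s0 + 2 * art_half] -= artifact_amp

    truth = GroundTruth(
        components=components,
        profile=profile,
        pulse_gains=gains,
        ps_flags=ps_flags,
        reentry_flags=reentry_flags,
        unit_evoked=np.asarray(unit),
        unit_reentry=None if unit_reentry is None else reentry_amp_scale * unit_reentry,
        window_ms=window_ms,
        ps_times_ms=ps_times,
    )
    return LaminarRecording(
        potentials=potentials,
        sampling_rate=sampling_rate,
        geometry=geometry,
        stim_times=onsets,
        protocol=protocol,
        pulse_currents=currents,
        ground_truth=truth,
    )
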