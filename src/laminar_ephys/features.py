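"""Five-point evoked-response measurement and population-spike detection.

The measurement scheme mirrors manual cursor placement on an averaged
evoked response: point 1 sits just before the stimulus artifact, points 2–3
bracket the response onset, and points 4–5 bracket the response peak (or
trough).  Amplitude is the extremum between points 4–5 minus the mean
between points 2–3; latency is the centre timestamp of points 4–5 minus the
timestamp of point 1.  Latency to response onset is deliberately not
measured — there is seldom a level period between artifact and response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import medfilt

from .core import LAYER_POLARITY, LAYERS, ms_to_samples
from .io_core import SweepSet, average_sweeps

#: Response-onset threshold, in multiples of the pre-stimulus SD.
ONSET_K = 3.0
#: Extremum search window (ms post-stimulus) for automatic placement.
SEARCH_WINDOW_MS = (2.0, 30.0)
#: Half-width (ms) of the cursor brackets around onset and extremum.
BRACKET_MS = 0.4
#: Length (ms) of the immediate pre-stimulus segment used for baseline
#: statistics.
BASELINE_MS = 5.0
#: Median-filter kernel (ms) used to excise population-spike transients from
#: granule-layer traces before the field response is measured.
PS_EXCISION_MS = 2.1
#: Numerical floor on the onset threshold so noise-free traces still yield
#: a well-defined departure from baseline.
EPS_MV = 1e-9


@dataclass(frozen=True)
class FivePointTemplate:
    """Cursor positions (sample indices into the sweep window).

    ``p1`` — last sample before the stimulus artifact; ``p2``/``p3`` —
    bracket of the response onset; ``p4``/``p5`` — bracket of the response
    peak or trough.  ``low_confidence`` marks templates whose
    requested-polarity extremum did not clear the onset threshold (e.g. a
    polarity-inverted trace).
    """

    p1: int
    p2: int
    p3: int
    p4: int
    p5: int
    polarity: str
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not (self.p1 < self.p2 < self.p3 <= self.p4 < self.p5):
            raise ValueError(
                f"template ordering violated: {self.p1},{self.p2},{self.p3},"
                f"{self.p4},{self.p5}"
            )
        if self.polarity not in ("positive_going", "negative_going"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    def to_dict(self) -> dict:
        """JSON-ready cursor positions, for sidecar export and audit."""
        import dataclasses

        return dataclasses.asdict(self)


def place_template(
    mean_trace: np.ndarray,
    times_ms: np.ndarray,
    polarity: str,
    artifact_end_ms: float = 1.0,
    onset_k: float = ONSET_K,
    search_window_ms: tuple[float, float] = SEARCH_WINDOW_MS,
    bracket_ms: float = BRACKET_MS,
) -> Optional[FivePointTemplate]:
    """Automatic five-point placement on a mean response.

    Returns ``None`` (a "no response" outcome, not an exception) when the
    trace never departs from baseline by more than ``onset_k`` × the
    pre-stimulus SD after the artifact.  When the departure exists but the
    requested-polarity extremum itself stays below threshold (an inverted
    response), the template is returned flagged ``low_confidence``.
    """
    trace = np.asarray(mean_trace, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    dt = times_ms[1] - times_ms[0]
    nb = max(int(round(bracket_ms / dt)), 1)

    pre = times_ms < 0.0
    if not np.any(pre):
        raise ValueError("sweep window contains no pre-stimulus samples")
    # baseline statistics from the immediate pre-stimulus segment only, with
    # a linear detrend for the SD: at short paired-pulse intervals the
    # previous response's decaying tail occupies the early baseline, and
    # using the full window would both offset the reference level and
    # inflate the onset threshold
    imm = pre & (times_ms >= -BASELINE_MS)
    pre_seg = trace[imm if np.any(imm) else pre]
    base_mean = pre_seg.mean()
    x = np.arange(pre_seg.size, dtype=float)
    if pre_seg.size > 2:
        slope, intercept = np.polyfit(x, pre_seg, 1)
        base_sd = (pre_seg - (slope * x + intercept)).std()
    else:
        base_sd = pre_seg.std()
    thresh = max(onset_k * base_sd, EPS_MV)

    p1 = int(np.flatnonzero(pre)[-1])

    post = np.flatnonzero(times_ms >= artifact_end_ms)
    dev = np.abs(trace[post] - base_mean)
    above = np.flatnonzero(dev > thresh)
    if above.size == 0:
        return None
    onset = int(post[above[0]])

    lo, hi = search_window_ms
    search = np.flatnonzero((times_ms >= lo) & (times_ms <= hi))
    seg = trace[search] - base_mean
    # requested-polarity extremum; ties broken by earliest sample
    ext_rel = int(np.argmax(seg) if polarity == "positive_going" else np.argmin(seg))
    ext = int(search[ext_rel])
    ext_dev = seg[ext_rel] if polarity == "positive_going" else -seg[ext_rel]
    low_confidence = ext_dev <= thresh

    n = trace.size
    p4 = max(ext - nb, onset)
    p5 = min(ext + nb, n - 1)
    # onset bracket ends at the departure point: the mean between p2–p3 is
    # the response's local baseline, so it must not ride up the rising phase
    p3 = min(onset, p4)
    p2 = max(onset - nb, p1 + 1)
    # enforce strict ordering in degenerate layouts
    if p3 <= p2:
        p3 = p2 + 1
    if p4 < p3:
        p4 = p3
    if p5 <= p4:
        p5 = p4 + 1
    if p5 >= n:
        p5 = n - 1
        p4 = min(p4, p5 - 1)
        p3 = min(p3, p4)
        p2 = min(p2, p3 - 1)
    return FivePointTemplate(p1, p2, p3, p4, p5, polarity, low_confidence)


def measure_amplitude(trace: np.ndarray, tpl: FivePointTemplate) -> float:
    """Extremum between points 4–5 minus the mean between points 2–3 (mV).

    Sign is retained: troughs yield negative amplitudes.
    """
    trace = np.asarray(trace, dtype=float)
    if tpl.p5 >= trace.size:
        raise IndexError("template indices out of range for this trace")
    baseline = trace[tpl.p2 : tpl.p3 + 1].mean()
    seg = trace[tpl.p4 : tpl.p5 + 1]
    ext = seg.max() if tpl.polarity == "positive_going" else seg.min()
    return float(ext - baseline)


def measure_latency(
    trace: np.ndarray, tpl: FivePointTemplate, times_ms: np.ndarray
) -> float:
    """Centre timestamp of points 4–5 minus the timestamp of point 1 (ms)."""
    if tpl.p5 >= np.asarray(trace).size:
        raise IndexError("template indices out of range for this trace")
    times_ms = np.asarray(times_ms, dtype=float)
    return float((times_ms[tpl.p4] + times_ms[tpl.p5]) / 2.0 - times_ms[tpl.p1])


def detect_ps(
    sweep_trace: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float] = (2.0, 15.0),
    k: float = 6.0,
    smooth_ms: float = 1.0,
    max_width_ms: float = 3.0,
    rel_floor: float = 0.12,
    biphasic_span_ms: float = 2.0,
) -> tuple[bool, Optional[float]]:
    """Detect a population spike on a granule-layer sweep.

    A PS is a fast biphasic transient riding on the smooth field response.
    The trace is high-passed by subtracting a moving-average copy
    (``smooth_ms`` window); a PS is called when, inside ``window_ms``, the
    residual shows supra-threshold excursions of *both* polarities within
    ``biphasic_span_ms`` of each other and the dominant excursion's width
    at half height is below ``max_width_ms``.  The threshold is ``k`` × the
    MAD-based SD of the pre-stimulus residual, floored at ``rel_floor`` ×
    the trace range — the floor keeps the sharp onset corner of a smooth
    noise-free fEPSP (whose high-pass residual is small relative to the
    response) from triggering.

    Returns ``(detected, time_of_peak_ms)``.
    """
    trace = np.asarray(sweep_trace, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    dt = times_ms[1] - times_ms[0]
    w = max(int(round(smooth_ms / dt)), 3)
    resid = trace - uniform_filter1d(trace, size=w, mode="nearest")

    pre = times_ms < 0.0
    r0 = resid[pre]
    mad_sd = 1.4826 * np.median(np.abs(r0 - np.median(r0)))

    lo, hi = window_ms
    inwin = np.flatnonzero((times_ms >= lo) & (times_ms <= hi))
    # floor scales with the response inside the search window (the stimulus
    # artifact outside it must not inflate the reference range)
    floor = rel_floor * float(np.ptp(trace[inwin]))
    thresh = max(k * mad_sd, floor, EPS_MV)
    r = resid[inwin]
    pos = np.flatnonzero(r > thresh)
    neg = np.flatnonzero(r < -thresh)
    if pos.size == 0 or neg.size == 0:
        return False, None
    # both polarity lobes must occur within the biphasic span
    span = int(round(biphasic_span_ms / dt))
    if np.abs(pos[:, None] - neg[None, :]).min() > span:
        return False, None
    mag = np.abs(r)
    cand = np.flatnonzero(mag > thresh)
    peak_rel = int(cand[np.argmax(mag[cand])])
    peak = mag[peak_rel]
    # width at half height of the excursion around the dominant lobe
    half = peak / 2.0
    i = peak_rel
    while i > 0 and mag[i - 1] >= half:
        i -= 1
    j = peak_rel
    while j < mag.size - 1 and mag[j + 1] >= half:
        j += 1
    width_ms = (j - i + 1) * dt
    if width_ms >= max_width_ms:
        return False, None
    return True, float(times_ms[inwin[peak_rel]])


def ps_probability(ps_flags: np.ndarray) -> tuple[float, int, int]:
    """Fraction of sweeps with a population spike, with its count basis.

    Returns ``(probability, n_positive, n_sweeps)`` so the n/20 basis the
    probability was computed from stays attached to the estimate.
    """
    flags = np.asarray(ps_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("ps_probability requires at least one sweep")
    return float(flags.mean()), int(flags.sum()), int(flags.size)


def extract_features(
    sweeps: SweepSet,
    layers: tuple[str, ...] = LAYERS,
    artifact_end_ms: float = 1.0,
    session: str = "",
    ps_kwargs: Optional[dict] = None,
) -> pd.DataFrame:
    """Tidy per-sweep and per-average feature table for one sweep set.

    For each layer and pulse label, a five-point template is placed on the
    mean response over repeats and then applied to every individual sweep
    (the template transfers between sweeps; only the measured values
    change).  DG rows carry a per-sweep population-spike flag detected at
    the granule-layer contact.

    Columns: session, protocol, layer, pulse_index, ppi_ms, current_ua,
    sweep, amplitude_mv, latency_ms, ps_flag, source, low_confidence.
    """
    ps_kwargs = ps_kwargs or {}
    rows: list[dict] = []
    proto = sweeps.protocol
    # keep the extremum search clear of the next pulse's stimulus artifact
    # at short paired-pulse intervals
    search_hi = SEARCH_WINDOW_MS[1]
    if proto.kind == "paired_pulse":
        search_hi = min(search_hi, float(proto.ppi_ms) - 1.0)
    elif proto.kind == "io_series":
        search_hi = min(search_hi, 49.0)
    search_window = (SEARCH_WINDOW_MS[0], search_hi)
    dg_ch = sweeps.geometry.layer_channel("DG_granule")
    ps_flags = np.array(
        [
            detect_ps(sweeps.sweeps[i, dg_ch], sweeps.times_ms, **ps_kwargs)[0]
            for i in range(sweeps.n_sweeps)
        ]
    )
    dt = sweeps.times_ms[1] - sweeps.times_ms[0]
    med_k = int(round(PS_EXCISION_MS / dt)) | 1
    for layer in layers:
        ch = sweeps.geometry.layer_channel(layer)
        polarity = LAYER_POLARITY[layer]
        # population spikes ride on the DG field peak; when any sweep shows
        # one, measure every DG trace with the fast transient excised by a
        # median filter so first/second-pulse ratios stay comparable
        excise = layer == "DG" and bool(ps_flags.any())
        for pidx in np.unique(sweeps.pulse_index):
            sel = np.flatnonzero(sweeps.select(int(pidx)))
            mean_trace = average_sweeps(sweeps, int(pidx))[ch]
            if excise:
                mean_trace = medfilt(mean_trace, med_k)
            tpl = place_template(
                mean_trace,
                sweeps.times_ms,
                polarity,
                artifact_end_ms,
                search_window_ms=search_window,
            )
            common = dict(
                session=session,
                protocol=proto.kind,
                layer=layer,
                pulse_index=int(pidx),
                ppi_ms=proto.ppi_ms if proto.kind == "paired_pulse" else np.nan,
            )
            if tpl is None:
                rows.append(
                    dict(
                        **common,
                        current_ua=np.nan,
                        sweep=-1,
                        amplitude_mv=np.nan,
                        latency_ms=np.nan,
                        ps_flag=False,
                        source="sweep_average",
                        low_confidence=True,
                    )
                )
                continue
            rows.append(
                dict(
                    **common,
                    current_ua=(
                        float(np.mean(sweeps.sweep_currents[sel]))
                        if sweeps.sweep_currents is not None
                        else np.nan
                    ),
                    sweep=-1,
                    amplitude_mv=measure_amplitude(mean_trace, tpl),
                    latency_ms=measure_latency(mean_trace, tpl, sweeps.times_ms),
                    ps_flag=False,
                    source="sweep_average",
                    low_confidence=tpl.low_confidence,
                )
            )
            for si in sel:
                trace = sweeps.sweeps[si, ch]
                if excise:
                    trace = medfilt(trace, med_k)
                ps = bool(ps_flags[si]) if layer == "DG" else False
                rows.append(
                    dict(
                        **common,
                        current_ua=(
                            float(sweeps.sweep_currents[si])
                            if sweeps.sweep_currents is not None
                            else np.nan
                        ),
                        sweep=int(si),
                        amplitude_mv=measure_amplitude(trace, tpl),
                        latency_ms=measure_latency(trace, tpl, sweeps.times_ms),
                        ps_flag=ps,
                        source="per_sweep",
                        low_confidence=tpl.low_confidence,
                    )
                )
    return pd.DataFrame(rows)


def extract_train_features(
    sweeps: SweepSet,
    layers: tuple[str, ...] = LAYERS,
    artifact_end_ms: float = 1.0,
    session: str = "",
) -> pd.DataFrame:
    """Per-pulse feature table for a 20-pulse train.

    A train has a single sweep per pulse and the response profile changes
    rapidly along it, so the template is re-placed on every pulse's own
    trace rather than transferred from an average.
    """
    rows: list[dict] = []
    dg_ch = sweeps.geometry.layer_channel("DG_granule")
    ps_flags = np.array(
        [
            detect_ps(sweeps.sweeps[i, dg_ch], sweeps.times_ms)[0]
            for i in range(sweeps.n_sweeps)
        ]
    )
    dt = sweeps.times_ms[1] - sweeps.times_ms[0]
    med_k = int(round(PS_EXCISION_MS / dt)) | 1
    for layer in layers:
        ch = sweeps.geometry.layer_channel(layer)
        polarity = LAYER_POLARITY[layer]
        excise = layer == "DG" and bool(ps_flags.any())
        for pidx in np.unique(sweeps.pulse_index):
            si = int(np.flatnonzero(sweeps.select(int(pidx)))[0])
            trace = sweeps.sweeps[si, ch]
            if excise:
                trace = medfilt(trace, med_k)
            tpl = place_template(trace, sweeps.times_ms, polarity, artifact_end_ms)
            ps = bool(ps_flags[si]) if layer == "DG" else False
            rows.append(
                dict(
                    session=session,
                    protocol="train",
                    layer=layer,
                    pulse_index=int(pidx),
                    ppi_ms=np.nan,
                    current_ua=(
                        float(sweeps.sweep_currents[si])
                        if sweeps.sweep_currents is not None
                        else np.nan
                    ),
                    sweep=si,
                    amplitude_mv=np.nan if tpl is None else measure_amplitude(trace, tpl),
                    latency_ms=(
                        np.nan
                        if tpl is None
                        else measure_latency(trace, tpl, sweeps.times_ms)
                    ),
                    ps_flag=ps,
                    source="per_sweep",
                    low_confidence=True if tpl is None else tpl.low_confidence,
                )
            )
    return pd.DataFrame(rows)
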