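"""Input/output curves, paired-pulse and train plasticity, re-entrance.

All plasticity indices follow the same normalisation: the second pulse of a
pair (or pulse k of a train) is expressed as a percentage change from the
first pulse, 100 × (value − reference) / reference, so positive values mean
facilitation (or, for latency, a slower response under the raw signed
formula; textual reports phrase latency changes as "% faster").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core import LAYERS
from .io_core import SweepSet

REENTRY_WINDOW_MS = (12.0, 25.0)


@dataclass
class IOCurve:
    """Input/output relation: stimulus current → first-pulse amplitude."""

    currents_ua: np.ndarray
    amplitudes_mv: dict[str, np.ndarray]


@dataclass
class PlasticityCurve:
    """Percentage-change profile over PPIs or train pulses.

    ``data`` is tidy: one row per (layer, measure, condition value) with
    mean, SEM and n across repeats.  ``condition`` names the axis
    ("ppi_ms" or "pulse_index"); ``reference`` names the normalising pulse.
    """

    data: pd.DataFrame
    condition: str
    reference: str


@dataclass
class ReentranceCall:
    """Long-latency re-entrant response call for one layer.

    ``first_pulse`` is the earliest train pulse (1-based) from which a
    qualifying late deflection is sustained through pulse 20, or ``None``
    when no re-entrance is detected.
    """

    layer: str
    first_pulse: Optional[int]
    latency_ms: Optional[float] = None
    amplitude_mv: Optional[float] = None


def percent_change(value: float, reference: float) -> float:
    """100 × (value − reference) / reference; undefined for zero reference."""
    if reference == 0:
        raise ValueError("percent change undefined for zero reference")
    return 100.0 * (value - reference) / reference


def build_io_curve(features: pd.DataFrame) -> IOCurve:
    """Amplitude-vs-current curve from first-pulse measurements.

    Only per-sweep first-pulse rows of an I/O series contribute; second
    pulses are ignored by construction.
    """
    df = features[
        (features["protocol"] == "io_series")
        & (features["source"] == "per_sweep")
        & (features["pulse_index"] == 1)
    ]
    if df.empty:
        raise ValueError("no first-pulse io_series measurements in the table")
    currents = np.sort(df["current_ua"].unique())
    amplitudes: dict[str, np.ndarray] = {}
    for layer, sub in df.groupby("layer"):
        means = sub.groupby("current_ua")["amplitude_mv"].mean()
        if not np.array_equal(np.sort(means.index.values), currents):
            raise ValueError(f"layer {layer} is missing measurements at some currents")
        amplitudes[layer] = means.loc[currents].to_numpy()
    return IOCurve(currents_ua=currents, amplitudes_mv=amplitudes)


def half_maximal_current(
    curve: IOCurve, reference_layer: str = "CA1sr", interpolate: bool = True
) -> float:
    """Smallest current at which the reference layer reaches 50% of its
    maximal amplitude over the tested range.

    Uses piecewise-linear interpolation between tested currents; with
    ``interpolate=False`` the nearest tested current at or above the half
    point is returned instead.  Scale-invariant: uniform scaling of all
    amplitudes leaves the result unchanged.
    """
    if reference_layer not in curve.amplitudes_mv:
        raise ValueError(f"reference layer {reference_layer!r} missing from curve")
    a = np.abs(curve.amplitudes_mv[reference_layer])
    if a.max() <= 0:
        raise ValueError("all-zero I/O curve: half-maximum undefined")
    target = 0.5 * a.max()
    i = int(np.flatnonzero(a >= target)[0])
    c = curve.currents_ua
    if i == 0 or not interpolate:
        return float(c[i])
    frac = (target - a[i - 1]) / (a[i] - a[i - 1])
    return float(c[i - 1] + frac * (c[i] - c[i - 1]))


def _paired_pct(features: pd.DataFrame, layer: str, measure: str, ppi: float) -> np.ndarray:
    sub = features[
        (features["layer"] == layer)
        & (features["source"] == "per_sweep")
        & (features["ppi_ms"] == ppi)
    ]
    p1 = sub[sub["pulse_index"] == 1].sort_values("sweep")[measure].to_numpy()
    p2 = sub[sub["pulse_index"] == 2].sort_values("sweep")[measure].to_numpy()
    if p1.size == 0 or p2.size == 0 or p1.size != p2.size:
        raise ValueError(
            f"PPI {ppi} ms: both pulses must be measured for layer {layer}"
        )
    if np.any(p1 == 0):
        raise ValueError(f"PPI {ppi} ms: zero first-pulse {measure} reference")
    return 100.0 * (p2 - p1) / p1


def paired_pulse_profile(features: pd.DataFrame) -> PlasticityCurve:
    """Percentage change of pulse 2 relative to pulse 1, per paired-pulse
    interval, layer and measure (amplitude and latency).

    The headline ``pct_change_mean`` is measured on the response averaged
    over the repeats (the measurement trace every cursor template is placed
    on); the dispersion (``pct_change_sem``) comes from per-repeat ratios,
    pairing the i-th first pulse with the i-th second pulse.  Measuring the
    central value on the averaged response rather than averaging per-sweep
    extrema avoids the upward noise bias a max-over-window estimator picks
    up on single sweeps.
    """
    df = features[features["protocol"].isin(["paired_pulse"])]
    if df.empty:
        raise ValueError("no paired-pulse rows in the feature table")
    rows = []
    for layer in sorted(df["layer"].unique()):
        for measure in ("amplitude_mv", "latency_ms"):
            for ppi in sorted(df["ppi_ms"].dropna().unique()):
                pct = _paired_pct(df, layer, measure, ppi)
                avg = df[
                    (df["layer"] == layer)
                    & (df["source"] == "sweep_average")
                    & (df["ppi_ms"] == ppi)
                ].set_index("pulse_index")[measure]
                if 1 not in avg.index or 2 not in avg.index:
                    raise ValueError(
                        f"PPI {ppi} ms: sweep-average rows missing for layer {layer}"
                    )
                rows.append(
                    dict(
                        layer=layer,
                        measure=measure,
                        ppi_ms=float(ppi),
                        pct_change_mean=percent_change(avg.loc[2], avg.loc[1]),
                        pct_change_sem=float(
                            pct.std(ddof=1) / np.sqrt(pct.size) if pct.size > 1 else 0.0
                        ),
                        n=int(pct.size),
                    )
                )
    return PlasticityCurve(
        data=pd.DataFrame(rows), condition="ppi_ms", reference="P1"
    )


def train_profile(features: pd.DataFrame, train_len: int = 20) -> PlasticityCurve:
    """Raw per-pulse values and percentage change from pulse 1 over a train."""
    df = features[features["protocol"] == "train"]
    if df.empty:
        raise ValueError("no train rows in the feature table")
    rows = []
    for layer in sorted(df["layer"].unique()):
        sub = df[(df["layer"] == layer) & (df["source"] == "per_sweep")]
        present = set(sub["pulse_index"])
        missing = sorted(set(range(1, train_len + 1)) - present)
        if missing:
            raise ValueError(f"layer {layer}: train pulses missing: {missing}")
        for measure in ("amplitude_mv", "latency_ms"):
            vals = (
                sub.sort_values("pulse_index")
                .groupby("pulse_index")[measure]
                .mean()
                .loc[range(1, train_len + 1)]
                .to_numpy()
            )
            ref = vals[0]
            if ref == 0:
                raise ValueError(f"layer {layer}: zero pulse-1 {measure} reference")
            for k in range(train_len):
                rows.append(
                    dict(
                        layer=layer,
                        measure=measure,
                        pulse_index=k + 1,
                        raw=float(vals[k]),
                        pct_change=float(100.0 * (vals[k] - ref) / ref),
                    )
                )
    return PlasticityCurve(
        data=pd.DataFrame(rows), condition="pulse_index", reference="pulse_1"
    )


def ps_probability_table(features: pd.DataFrame, pulse_index: int = 2) -> pd.DataFrame:
    """Population-spike probability (n out of the repeat count) per PPI."""
    df = features[
        (features["protocol"] == "paired_pulse")
        & (features["source"] == "per_sweep")
        & (features["layer"] == "DG")
        & (features["pulse_index"] == pulse_index)
    ]
    rows = []
    for ppi, sub in df.groupby("ppi_ms"):
        flags = sub["ps_flag"].to_numpy(dtype=bool)
        rows.append(
            dict(
                ppi_ms=float(ppi),
                ps_probability=float(flags.mean()),
                n_ps=int(flags.sum()),
                n_sweeps=int(flags.size),
            )
        )
    return pd.DataFrame(rows)


def detect_reentrance(
    sweeps: SweepSet,
    window_ms: tuple[float, float] = REENTRY_WINDOW_MS,
    k: float = 3.0,
    layers: tuple[str, ...] = LAYERS,
    fit_window_ms: tuple[float, float] = (1.5, 10.0),
    smooth_sd_ms: float = 0.5,
    min_sustain_ms: float = 1.5,
) -> dict[str, ReentranceCall]:
    """Detect long-latency re-entrant components in a 20-pulse train.

    For every pulse, the pulse-1 response (scaled by least squares over the
    early ``fit_window_ms``) is subtracted from the trace at the layer's
    contact; a pulse qualifies when the smoothed residual inside
    ``window_ms`` exceeds ``k`` × the pre-stimulus residual SD continuously
    for at least ``min_sustain_ms`` (the sustain requirement rejects
    single-sample noise excursions).  The call's first pulse is the
    earliest pulse from which every later pulse up to the end of the train
    qualifies — re-entrance, once established, persists.
    """
    lo, hi = window_ms
    if hi > sweeps.times_ms[-1]:
        raise ValueError("re-entrance window exceeds the sweep length")
    t = sweeps.times_ms
    dt = t[1] - t[0]
    sd_samples = max(smooth_sd_ms / dt, 1.0)
    min_run = max(int(round(min_sustain_ms / dt)), 1)
    fit = (t >= fit_window_ms[0]) & (t <= fit_window_ms[1])
    win = (t >= lo) & (t <= hi)
    pre = t < 0.0
    order = np.argsort(sweeps.pulse_index)
    calls: dict[str, ReentranceCall] = {}
    for layer in layers:
        ch = sweeps.geometry.layer_channel(layer)
        traces = sweeps.sweeps[order, ch, :]
        ref = traces[0]
        denom = float(np.dot(ref[fit], ref[fit]))
        scales = (
            traces[:, fit] @ ref[fit] / denom if denom > 0 else np.zeros(traces.shape[0])
        )
        resids = traces - scales[:, None] * ref
        sms = gaussian_filter1d(resids, sd_samples, axis=-1, mode="nearest")
        # session-level noise floor: pool the pre-stimulus residual over all
        # pulses — a single pulse's short baseline gives too unstable an SD
        thresh = max(k * float(sms[:, pre].std()), 1e-9)
        qualifies = np.zeros(traces.shape[0], dtype=bool)
        peak_time = np.full(traces.shape[0], np.nan)
        peak_amp = np.full(traces.shape[0], np.nan)
        for i in range(traces.shape[0]):
            sm = sms[i]
            above = np.abs(sm[win]) > thresh
            # longest run of consecutive supra-threshold samples
            run, best = 0, 0
            for a in above:
                run = run + 1 if a else 0
                best = max(best, run)
            if best >= min_run:
                qualifies[i] = True
                widx = np.flatnonzero(win)
                mag = np.abs(sm[win])
                pk = int(np.argmax(mag))
                peak_time[i] = t[widx[pk]]
                peak_amp[i] = sm[widx[pk]]
        # earliest pulse from which the call is sustained to the last pulse
        first: Optional[int] = None
        sustained = True
        for i in range(traces.shape[0] - 1, -1, -1):
            sustained = sustained and qualifies[i]
            if sustained:
                first = i + 1
            else:
                break
        if first is None:
            calls[layer] = ReentranceCall(layer=layer, first_pulse=None)
        else:
            calls[layer] = ReentranceCall(
                layer=layer,
                first_pulse=first,
                latency_ms=float(peak_time[first - 1]),
                amplitude_mv=float(peak_amp[first - 1]),
            )
    return calls
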