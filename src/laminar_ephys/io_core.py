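"""Recording I/O, sweep segmentation and stability screening.

Continuous recordings are cut into stimulus-locked sweeps (time re-zeroed to
pulse onset), averaged over repeats, and screened for baseline drift.
Recordings round-trip through an HDF5 container bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Optional

import h5py
import numpy as np

from .core import (
    GroundTruth,
    LaminarRecording,
    ProbeGeometry,
    StimulusProtocol,
    ms_to_samples,
)
from .synthetic.components import CsdComponent, ExcitabilityProfile

#: Default sweep window (ms around pulse onset): long enough to contain the
#: longest re-entrance latency (~21 ms) plus after-potentials.
DEFAULT_PRE_MS = 10.0
DEFAULT_POST_MS = 40.0


@dataclass
class SweepSet:
    """Stimulus-locked sweep slices from one recording.

    ``sweeps`` is repeats × channels × window-samples (mV); ``times_ms``
    the common within-sweep time axis with 0 at pulse onset;
    ``pulse_index`` the within-pair/train pulse label of each sweep
    (1-based).
    """

    sweeps: np.ndarray
    times_ms: np.ndarray
    pulse_index: np.ndarray
    protocol: StimulusProtocol
    geometry: ProbeGeometry
    sampling_rate: float
    pre_ms: float
    post_ms: float
    sweep_currents: Optional[np.ndarray] = None
    ground_truth: Optional[GroundTruth] = None

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    def select(self, pulse_index: int) -> np.ndarray:
        """Boolean mask of sweeps belonging to one pulse label."""
        return self.pulse_index == pulse_index

    def subset(self, mask: np.ndarray) -> "SweepSet":
        return dataclasses.replace(
            self,
            sweeps=self.sweeps[mask],
            pulse_index=self.pulse_index[mask],
            sweep_currents=None if self.sweep_currents is None else self.sweep_currents[mask],
        )


@dataclass
class ExclusionReport:
    """Outcome of the baseline-stability screen."""

    kept: np.ndarray
    removed: list[tuple[int, float, str]]
    drift_tol_mv: float
    all_removed: bool = False


def segment_sweeps(
    rec: LaminarRecording,
    pre_ms: float = DEFAULT_PRE_MS,
    post_ms: float = DEFAULT_POST_MS,
) -> SweepSet:
    """Cut one slice per stimulus pulse, time re-zeroed to pulse onset.

    Raises an out-of-range error naming the offending pulse when the
    requested window does not fit inside the recording.
    """
    pre = ms_to_samples(pre_ms, rec.sampling_rate)
    post = ms_to_samples(post_ms, rec.sampling_rate)
    for i, s in enumerate(rec.stim_times):
        if s - pre < 0 or s + post > rec.n_samples:
            raise ValueError(
                f"sweep window [{-pre_ms:g}, {post_ms:g}] ms around pulse {i + 1} "
                f"(sample {int(s)}) exceeds the recording bounds"
            )
    sweeps = np.stack([rec.potentials[:, s - pre : s + post] for s in rec.stim_times])
    times_ms = (np.arange(-pre, post) / rec.sampling_rate) * 1e3
    return SweepSet(
        sweeps=sweeps,
        times_ms=times_ms,
        pulse_index=rec.pulse_indices(),
        protocol=rec.protocol,
        geometry=rec.geometry,
        sampling_rate=rec.sampling_rate,
        pre_ms=pre_ms,
        post_ms=post_ms,
        sweep_currents=rec.pulse_currents,
        ground_truth=rec.ground_truth,
    )


def average_sweeps(s: SweepSet, pulse_index: Optional[int] = None) -> np.ndarray:
    """Pointwise mean trace (channels × window) across matching sweeps."""
    if pulse_index is None:
        sel = np.ones(s.n_sweeps, dtype=bool)
    else:
        sel = s.select(pulse_index)
    if not np.any(sel):
        raise ValueError(f"no sweeps match pulse_index={pulse_index}")
    return s.sweeps[sel].mean(axis=0)


def exclude_unstable(
    s: SweepSet, drift_tol_mv: float
) -> tuple[SweepSet, ExclusionReport]:
    """Drop sweeps whose pre-stimulus baseline drifts from the session median.

    The baseline of each sweep is its mean over channels and pre-stimulus
    samples; sweeps deviating from the median baseline by more than
    ``drift_tol_mv`` are excluded.  This is a quantitative stand-in for the
    qualitative recording-stability criterion applied during acquisition.
    """
    if drift_tol_mv <= 0:
        raise ValueError("drift_tol_mv must be > 0")
    pre_mask = s.times_ms < 0
    baselines = s.sweeps[:, :, pre_mask].mean(axis=(1, 2))
    median = float(np.median(baselines))
    dev = baselines - median
    keep = np.abs(dev) <= drift_tol_mv if math.isfinite(drift_tol_mv) else np.ones(
        s.n_sweeps, dtype=bool
    )
    removed = [
        (int(i), float(dev[i]), f"baseline drift {dev[i]:+.3f} mV > {drift_tol_mv:g} mV")
        for i in np.flatnonzero(~keep)
    ]
    report = ExclusionReport(
        kept=np.flatnonzero(keep),
        removed=removed,
        drift_tol_mv=drift_tol_mv,
        all_removed=not np.any(keep),
    )
    return s.subset(keep), report


# ---------------------------------------------------------------------------
# HDF5 container


def _profile_to_json(p: ExcitabilityProfile) -> str:
    d = dataclasses.asdict(p)
    d["ppi_gain"] = {str(k): v for k, v in d["ppi_gain"].items()}
    d["train_gain"] = list(d["train_gain"])
    return json.dumps(d, sort_keys=True)


def _profile_from_json(s: str) -> ExcitabilityProfile:
    d = json.loads(s)
    d["ppi_gain"] = {int(k): v for k, v in d["ppi_gain"].items()}
    d["train_gain"] = tuple(d["train_gain"])
    if d.get("ps_threshold_mv") is None:
        d["ps_threshold_mv"] = math.inf
    return ExcitabilityProfile(**d)


def save_recording(rec: LaminarRecording, path) -> None:
    """Write a recording (and any attached ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("potentials", data=rec.potentials)
        f.create_dataset("stim_times", data=rec.stim_times.astype(np.int64))
        if rec.pulse_currents is not None:
            f.create_dataset("pulse_currents", data=rec.pulse_currents)
        f.attrs["sampling_rate_hz"] = rec.sampling_rate
        f.attrs["n_contacts"] = rec.geometry.n_contacts
        f.attrs["spacing_um"] = rec.geometry.spacing_um
        f.attrs["depth_of_first_contact_um"] = rec.geometry.depth_of_first_contact_um
        f.attrs["protocol"] = rec.protocol.to_json()
        t = rec.ground_truth
        if t is not None:
            g = f.create_group("truth")
            g.create_dataset("pulse_gains", data=t.pulse_gains)
            g.create_dataset("ps_flags", data=t.ps_flags)
            g.create_dataset("reentry_flags", data=t.reentry_flags)
            g.create_dataset("unit_evoked", data=t.unit_evoked)
            g.create_dataset("ps_times_ms", data=t.ps_times_ms)
            if t.unit_reentry is not None:
                g.create_dataset("unit_reentry", data=t.unit_reentry)
            g.attrs["window_ms"] = t.window_ms
            prof = dataclasses.asdict(t.profile)
            prof["ppi_gain"] = {str(k): v for k, v in prof["ppi_gain"].items()}
            if not math.isfinite(prof["ps_threshold_mv"]):
                prof["ps_threshold_mv"] = None
            g.attrs["profile"] = json.dumps(prof, sort_keys=True)
            g.attrs["components"] = json.dumps(
                [dataclasses.asdict(c) for c in t.components], sort_keys=True
            )


def load_recording(path) -> LaminarRecording:
    """Read a recording written by :func:`save_recording` (bit-exact)."""
    with h5py.File(path, "r") as f:
        geometry = ProbeGeometry(
            n_contacts=int(f.attrs["n_contacts"]),
            spacing_um=float(f.attrs["spacing_um"]),
            depth_of_first_contact_um=float(f.attrs["depth_of_first_contact_um"]),
        )
        protocol = StimulusProtocol.from_json(f.attrs["protocol"])
        truth = None
        if "truth" in f:
            g = f["truth"]
            truth = GroundTruth(
                components=tuple(
                    CsdComponent(**d) for d in json.loads(g.attrs["components"])
                ),
                profile=_profile_from_json(g.attrs["profile"]),
                pulse_gains=g["pulse_gains"][()],
                ps_flags=g["ps_flags"][()].astype(bool),
                reentry_flags=g["reentry_flags"][()].astype(bool),
                unit_evoked=g["unit_evoked"][()],
                unit_reentry=g["unit_reentry"][()] if "unit_reentry" in g else None,
                window_ms=float(g.attrs["window_ms"]),
                ps_times_ms=g["ps_times_ms"][()],
            )
        return LaminarRecording(
            potentials=f["potentials"][()],
            sampling_rate=float(f.attrs["sampling_rate_hz"]),
            geometry=geometry,
            stim_times=f["stim_times"][()],
            protocol=protocol,
            pulse_currents=f["pulse_currents"][()] if "pulse_currents" in f else None,
            ground_truth=truth,
        )
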