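"""Shared domain types for laminar evoked-response analysis.

The package works on multi-channel extracellular recordings made with a
linear silicon probe spanning the hippocampal CA1–dentate gyrus (DG) axis.
Depth is measured in µm along the probe, increasing from the most dorsal
contact (channel 0) downward, and time is measured in ms with t = 0 at
stimulus-pulse onset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

#: Nominal depth (µm along the probe axis) of each named response layer, for
#: the default probe placement used by the simulator.  ``CA1sr`` = stratum
#: radiatum (Schaffer-collateral fEPSP, negative-going), ``CA1slm`` = stratum
#: lacunosum-moleculare (direct entorhinal layer-III input, negative-going),
#: ``DG`` = dentate response measured on the granule-cell side of the
#: molecular-layer sink, where the return current makes it positive-going.
#: ``DG_granule`` is where population spikes ride on the field response.
LAYER_DEPTHS_UM: dict[str, float] = {
    "CA1sr": 300.0,
    "CA1slm": 600.0,
    "DG": 1100.0,
    "DG_granule": 1100.0,
}

#: Expected deflection polarity of the measured field response per layer.
LAYER_POLARITY: dict[str, str] = {
    "CA1sr": "negative_going",
    "CA1slm": "negative_going",
    "DG": "positive_going",
}

LAYERS: tuple[str, ...] = ("CA1sr", "CA1slm", "DG")


class GeometryError(ValueError):
    """Raised when a probe geometry or solver grid violates its contract."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Linear multi-contact probe along the CA1–DG axis.

    Parameters
    ----------
    n_contacts
        Number of recording contacts (16 at 100 µm or 32 at 50 µm in the
        standard configurations).
    spacing_um
        Centre-to-centre contact spacing in µm.
    depth_of_first_contact_um
        Depth of channel 0 (most dorsal contact).
    """

    n_contacts: int = 16
    spacing_um: float = 100.0
    depth_of_first_contact_um: float = 0.0

    def __post_init__(self) -> None:
        if self.n_contacts < 3:
            raise GeometryError("a laminar probe needs at least 3 contacts")
        if self.spacing_um <= 0:
            raise GeometryError("contact spacing must be positive")

    @property
    def contact_depths_um(self) -> np.ndarray:
        return self.depth_of_first_contact_um + self.spacing_um * np.arange(
            self.n_contacts, dtype=float
        )

    @property
    def span_um(self) -> float:
        return self.spacing_um * (self.n_contacts - 1)

    def layer_channel(self, layer: str) -> int:
        """Index of the contact closest to a named layer's nominal depth."""
        depth = LAYER_DEPTHS_UM[layer]
        return int(np.argmin(np.abs(self.contact_depths_um - depth)))


PPI_SET_MS: tuple[int, ...] = (25, 50, 100, 200, 500, 1000)


@dataclass(frozen=True)
class StimulusProtocol:
    """Declarative description of one stimulation run.

    kinds
    -----
    ``io_series``
        Pairs of pulses at a 50 ms interval delivered over an ascending
        range of current intensities (50–600 µA); the first pulse of each
        pair is analysed for the input/output curve.
    ``paired_pulse``
        Pairs at one inter-pulse interval drawn from
        {25, 50, 100, 200, 500, 1000} ms, separated by 3 s and repeated
        (20 times by default).
    ``train``
        A single train of 20 pulses at 5 Hz.
    """

    kind: str
    current_ua: float | tuple[float, ...] = 200.0
    ppi_ms: Optional[float] = None
    n_repeats: int = 20
    train_len: int = 20
    train_hz: float = 5.0
    pulse_width_ms: float = 0.2
    inter_pair_gap_s: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("io_series", "paired_pulse", "train"):
            raise ValueError(f"unknown protocol kind: {self.kind!r}")
        if self.pulse_width_ms <= 0:
            raise ValueError("pulse_width_ms must be positive")
        if self.kind == "paired_pulse":
            if self.ppi_ms is None or self.ppi_ms not in PPI_SET_MS:
                raise ValueError(
                    f"paired_pulse requires ppi_ms in {PPI_SET_MS}, got {self.ppi_ms}"
                )
        if self.kind == "io_series":
            currents = np.atleast_1d(np.asarray(self.current_ua, dtype=float))
            if currents.size < 2 or np.any(np.diff(currents) <= 0):
                raise ValueError("io_series needs ≥ 2 strictly ascending currents")
        if self.kind == "train" and self.train_len < 1:
            raise ValueError("train_len must be ≥ 1")

    @property
    def currents(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.current_ua, dtype=float))

    def to_json(self) -> str:
        d = {
            "kind": self.kind,
            "current_ua": (
                list(self.currents) if self.kind == "io_series" else float(self.currents[0])
            ),
            "ppi_ms": self.ppi_ms,
            "n_repeats": self.n_repeats,
            "train_len": self.train_len,
            "train_hz": self.train_hz,
            "pulse_width_ms": self.pulse_width_ms,
            "inter_pair_gap_s": self.inter_pair_gap_s,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "StimulusProtocol":
        d = json.loads(s)
        cur = d["current_ua"]
        if isinstance(cur, list):
            cur = tuple(cur)
        return cls(
            kind=d["kind"],
            current_ua=cur,
            ppi_ms=d["ppi_ms"],
            n_repeats=d["n_repeats"],
            train_len=d["train_len"],
            train_hz=d["train_hz"],
            pulse_width_ms=d["pulse_width_ms"],
            inter_pair_gap_s=d["inter_pair_gap_s"],
        )


@dataclass
class GroundTruth:
    """Simulator bookkeeping attached to a synthetic recording.

    Everything needed to use the recording as an oracle: the CSD component
    catalogue, the excitability profile, the per-pulse gain actually applied
    (including any per-sweep jitter), per-pulse population-spike and
    re-entrance flags, and the unit (gain = 1) contact waveforms of the
    evoked and re-entrant components.
    """

    components: tuple[Any, ...]
    profile: Any
    pulse_gains: np.ndarray
    ps_flags: np.ndarray
    reentry_flags: np.ndarray
    unit_evoked: np.ndarray  # channels × window samples, mV at gain 1
    unit_reentry: Optional[np.ndarray]  # same shape, or None
    window_ms: float  # length of the unit waveform window
    ps_times_ms: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class LaminarRecording:
    """Continuous multi-channel laminar recording with stimulus events.

    ``potentials`` is channels × samples in mV; ``stim_times`` holds the
    sample index of each pulse onset; ``pulse_currents`` the stimulus
    current (µA) of each pulse.
    """

    potentials: np.ndarray
    sampling_rate: float
    geometry: ProbeGeometry
    stim_times: np.ndarray
    protocol: StimulusProtocol
    pulse_currents: Optional[np.ndarray] = None
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=np.int64)
        if self.potentials.ndim != 2:
            raise ValueError("potentials must be channels × samples")
        if self.potentials.shape[0] != self.geometry.n_contacts:
            raise ValueError("channel count does not match probe geometry")
        if self.stim_times.size:
            if np.any(np.diff(self.stim_times) <= 0):
                raise ValueError("stim_times must be strictly increasing")
            if self.stim_times[0] < 0 or self.stim_times[-1] >= self.n_samples:
                raise ValueError("stim_times outside the sample range")
        if self.pulse_currents is not None:
            self.pulse_currents = np.asarray(self.pulse_currents, dtype=float)
            if self.pulse_currents.shape != self.stim_times.shape:
                raise ValueError("pulse_currents must align with stim_times")

    @property
    def n_channels(self) -> int:
        return self.potentials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.potentials.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def pulse_indices(self) -> np.ndarray:
        """Within-sequence pulse label for every stimulus (1-based).

        Pairs (and I/O pairs) are labelled 1, 2, 1, 2, …; train pulses
        1 … train_len.
        """
        n = self.stim_times.size
        if self.protocol.kind == "train":
            return np.arange(1, n + 1, dtype=int)
        out = np.empty(n, dtype=int)
        out[0::2] = 1
        out[1::2] = 2
        return out


def ms_to_samples(ms: float, sampling_rate: float) -> int:
    return int(round(ms * 1e-3 * sampling_rate))


def samples_to_ms(samples: Sequence[float] | np.ndarray | float, sampling_rate: float):
    return np.asarray(samples, dtype=float) / sampling_rate * 1e3
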