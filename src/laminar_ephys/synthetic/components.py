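"""CSD component catalogue and excitability profiles for the simulator.

The forward model represents each evoked response as a balanced pair of
transmembrane current lobes: a synaptic sink (inward current, negative
density) at the activated dendritic layer and its passive return source at a
fixed depth offset.  Each lobe is a Gaussian in depth and an alpha function
in time, which is the simplest smooth shape matching the mono/biphasic
laminar field components seen with perforant-path stimulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from ..core import PPI_SET_MS


@dataclass(frozen=True)
class CsdComponent:
    """One balanced sink/source pair of the laminar CSD.

    ``peak_density`` is the unsigned peak magnitude of the primary lobe in
    arbitrary units; its sign is set by ``polarity`` (sink → negative).  The
    balancing return current of opposite sign carries exactly the opposite
    spatial integral, distributed between ``center ± paired_return_offset``
    according to ``return_fraction``, so the total density conserves
    current at every instant.
    """

    name: str
    center_depth_um: float
    spatial_sd_um: float
    onset_latency_ms: float
    time_constant_ms: float
    polarity: str  # "sink" | "source"
    peak_density: float
    paired_return_offset_um: float
    #: Share of the return current placed at ``center + paired_return_offset``
    #: (the anatomically observed return); the remainder is mirrored at
    #: ``center − paired_return_offset``.  0.5 = symmetric split (zero dipole
    #: moment, fully compact potential); values near 1 concentrate the return
    #: on the stated side at the cost of a long-range 1-D dipole field.
    return_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.return_fraction <= 1.0:
            raise ValueError("return_fraction must lie in [0, 1]")
        if self.onset_latency_ms < 0:
            raise ValueError("onset_latency_ms must be ≥ 0")
        if self.spatial_sd_um <= 0:
            raise ValueError("spatial_sd_um must be > 0")
        if self.time_constant_ms <= 0:
            raise ValueError("time_constant_ms must be > 0")
        if self.polarity not in ("sink", "source"):
            raise ValueError("polarity must be 'sink' or 'source'")
        if self.paired_return_offset_um == 0:
            raise ValueError("return lobe must be offset from the primary lobe")

    @property
    def sign(self) -> float:
        return -1.0 if self.polarity == "sink" else 1.0

    @property
    def peak_time_ms(self) -> float:
        """Time of peak density: alpha function peaks one time constant
        after onset."""
        return self.onset_latency_ms + self.time_constant_ms


def default_component_catalogue() -> tuple[CsdComponent, ...]:
    """Evoked component catalogue for the default probe placement.

    Emulates the canonical laminar response to perforant-path/subiculum
    stimulation: a CA1 stratum lacunosum-moleculare sink (direct entorhinal
    layer-III input, peak ≈ 6 ms), a DG molecular-layer sink with its
    granule-cell-layer return source (direct layer-II input, peak ≈ 7.5 ms),
    and a later CA1 stratum radiatum sink (tri-synaptic Schaffer input,
    peak ≈ 8 ms) returning at the pyramidal layer.
    """
    return (
        CsdComponent(
            name="CA1slm_sink",
            center_depth_um=600.0,
            spatial_sd_um=150.0,
            onset_latency_ms=4.0,
            time_constant_ms=2.0,
            polarity="sink",
            peak_density=2.0,
            paired_return_offset_um=-250.0,
        ),
        CsdComponent(
            name="DGmol_sink",
            center_depth_um=900.0,
            spatial_sd_um=150.0,
            onset_latency_ms=5.5,
            time_constant_ms=2.0,
            polarity="sink",
            peak_density=4.0,
            paired_return_offset_um=200.0,  # granule-cell source at ~1100 µm
            return_fraction=1.0,  # the granule source is genuinely one-sided
        ),
        CsdComponent(
            name="CA1sr_sink",
            center_depth_um=300.0,
            spatial_sd_um=130.0,
            onset_latency_ms=6.0,
            time_constant_ms=2.0,
            polarity="sink",
            peak_density=1.5,
            paired_return_offset_um=-200.0,
        ),
    )


def reentry_catalogue(
    components: tuple[CsdComponent, ...], reentry_latency_ms: float
) -> tuple[CsdComponent, ...]:
    """Re-entrant copy of a catalogue: same laminar shapes, with each
    component's onset set so its density peaks at ``reentry_latency_ms``.

    Re-entrance is the long-latency (~15–21 ms) secondary activation that
    returns to DG/CA1 through deep-to-superficial entorhinal connectivity
    during repetitive stimulation.
    """
    return tuple(
        replace(
            c,
            name=f"{c.name}_reentry",
            onset_latency_ms=max(reentry_latency_ms - c.time_constant_ms, 0.0),
        )
        for c in components
    )


@dataclass(frozen=True)
class ExcitabilityProfile:
    """Programmed short-term plasticity fingerprint of a simulated subject.

    ``ppi_gain`` maps each paired-pulse interval (ms) to the multiplicative
    gain applied to the second pulse's component amplitudes (< 1 =
    paired-pulse depression, > 1 = facilitation).  ``train_gain`` gives one
    gain per pulse of a 20-pulse 5 Hz train.  A population-spike transient
    is injected on any pulse whose scaled DG amplitude exceeds
    ``ps_threshold_mv``; a re-entrant component appears from
    ``reentry_first_pulse`` (1-based) onward in trains, peaking at
    ``reentry_latency_ms``.
    """

    ppi_gain: dict[int, float]
    train_gain: tuple[float, ...]
    ps_threshold_mv: float = math.inf
    reentry_first_pulse: Optional[int] = None
    reentry_latency_ms: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        if set(self.ppi_gain) != set(PPI_SET_MS):
            raise ValueError(f"ppi_gain must be defined for exactly {PPI_SET_MS}")
        if any(g <= 0 for g in self.ppi_gain.values()):
            raise ValueError("all paired-pulse gains must be > 0")
        if len(self.train_gain) != 20:
            raise ValueError("train_gain must have length 20")
        if any(g <= 0 for g in self.train_gain):
            raise ValueError("all train gains must be > 0")
        if self.reentry_first_pulse is not None:
            if not 1 <= self.reentry_first_pulse <= 20:
                raise ValueError("reentry_first_pulse must lie in 1–20")
            if self.reentry_latency_ms is None:
                raise ValueError("re-entrance requires reentry_latency_ms")
        if self.reentry_latency_ms is not None and not (
            12.0 <= self.reentry_latency_ms <= 25.0
        ):
            raise ValueError("reentry_latency_ms must lie in [12, 25] ms")


def _saturating_ramp(n: int, ceiling: float, tau_pulses: float = 5.0) -> tuple[float, ...]:
    return tuple(
        1.0 + (ceiling - 1.0) * (1.0 - math.exp(-k / tau_pulses)) for k in range(n)
    )


def control_like_profile(
    ps_threshold_mv: float = math.inf,
    reentry: bool = False,
) -> ExcitabilityProfile:
    """Control fingerprint: paired-pulse depression in DG at short
    intervals (25–50 ms) recovering by 200 ms, clear facilitation over the
    train, and re-entrance (when enabled) only by pulse 20."""
    return ExcitabilityProfile(
        ppi_gain={25: 0.80, 50: 0.85, 100: 0.95, 200: 1.00, 500: 1.00, 1000: 1.00},
        train_gain=_saturating_ramp(20, ceiling=1.5),
        ps_threshold_mv=ps_threshold_mv,
        reentry_first_pulse=20 if reentry else None,
        reentry_latency_ms=17.5 if reentry else None,
        label="control-like",
    )


def ad_like_profile(
    ps_threshold_mv: float = math.inf,
    reentry: bool = True,
    reentry_first_pulse: int = 10,
) -> ExcitabilityProfile:
    """Hyper-excitable fingerprint: paired-pulse facilitation at short
    intervals, modest train facilitation, and re-entrance developing
    mid-train (pulse 10 by default) at ~15.7 ms."""
    return ExcitabilityProfile(
        ppi_gain={25: 1.25, 50: 1.30, 100: 1.10, 200: 1.00, 500: 1.00, 1000: 1.00},
        train_gain=_saturating_ramp(20, ceiling=1.2),
        ps_threshold_mv=ps_threshold_mv,
        reentry_first_pulse=reentry_first_pulse if reentry else None,
        reentry_latency_ms=15.7 if reentry else None,
        label="ad-like",
    )
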