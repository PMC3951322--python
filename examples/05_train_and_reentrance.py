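"""20-pulse 5 Hz train: per-pulse facilitation and re-entrance detection.

Simulates a train for a hyper-excitable profile programmed to develop a
long-latency re-entrant response (activity returning through entorhinal
cortex) from pulse 10, then recovers the per-pulse amplitude profile and
the re-entrance call per layer.
"""

from laminar_ephys import (
    ProbeGeometry,
    StimulusProtocol,
    ad_like_profile,
    detect_reentrance,
    extract_train_features,
    segment_sweeps,
    train_profile,
)
from laminar_ephys.synthetic import simulate_protocol

geometry = ProbeGeometry()
profile = ad_like_profile(reentry_first_pulse=10)  # re-entry peaks at 15.7 ms
rec = simulate_protocol(
    profile, StimulusProtocol(kind="train"), geometry, noise_sd=0.05, seed=5
)
sweeps = segment_sweeps(rec)

curve = train_profile(extract_train_features(sweeps))
dg = curve.data[(curve.data["layer"] == "DG")
                & (curve.data["measure"] == "amplitude_mv")]
for pulse in (1, 5, 10, 20):
    row = dg[dg["pulse_index"] == pulse].iloc[0]
    print(f"pulse {pulse:2d}: DG amplitude {row['raw']:+.2f} mV "
          f"({row['pct_change']:+.1f}% vs pulse 1)")

print()
for layer, call in detect_reentrance(sweeps, window_ms=(12.0, 25.0)).items():
    if call.first_pulse is None:
        print(f"{layer:6s}: no re-entrance")
    else:
        print(f"{layer:6s}: re-entrance from pulse {call.first_pulse}, "
              f"latency {call.latency_ms:.1f} ms, "
              f"amplitude {call.amplitude_mv:+.2f} mV")

# The direct response facilitates modestly along the train; from pulse 10 a
# second deflection appears 15–16 ms after each pulse in every layer — the
# programmed re-entrant volley — and the detector reports the pulse at
# which it first becomes sustained.
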