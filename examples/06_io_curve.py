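"""Input/output curve and half-maximal stimulation current.

Simulates an I/O series (pairs at 50 ms over 50–600 uA), builds the
amplitude-vs-current curve from the first pulse of each pair, and finds
the current evoking half of the maximal CA1 stratum radiatum response —
the intensity at which paired-pulse and train protocols are run.
"""

import numpy as np

from laminar_ephys import (
    ProbeGeometry,
    StimulusProtocol,
    build_io_curve,
    control_like_profile,
    extract_features,
    half_maximal_current,
    segment_sweeps,
)
from laminar_ephys.synthetic import simulate_protocol

geometry = ProbeGeometry()
currents = tuple(range(50, 601, 50))
rec = simulate_protocol(
    control_like_profile(),
    StimulusProtocol(kind="io_series", current_ua=currents, n_repeats=3),
    geometry,
    noise_sd=0.05,
    seed=6,
)
curve = build_io_curve(extract_features(segment_sweeps(rec)))

print("current (uA) | CA1sr amplitude (mV)")
for c, a in zip(curve.currents_ua, curve.amplitudes_mv["CA1sr"]):
    bar = "#" * int(round(abs(a) * 4))
    print(f"   {c:6.0f}    | {a:+.2f}  {bar}")

half = half_maximal_current(curve, reference_layer="CA1sr")
print(f"\nhalf-maximal current: {half:.0f} uA "
      f"(50% of the maximal CA1sr fEPSP over the tested range)")

# The curve saturates as the stimulus recruits the whole fibre population;
# the half-max current lands in the 100–200 uA range typical for this
# preparation.
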