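"""Short-term plasticity: paired-pulse profiles of two excitability types.

Simulates paired pulses at 25 and 50 ms for a control-like profile
(paired-pulse depression in DG) and an AD-like hyper-excitable profile
(facilitation), then recovers the percent change of the second response.
"""

from laminar_ephys import (
    ProbeGeometry,
    StimulusProtocol,
    ad_like_profile,
    control_like_profile,
    extract_features,
    paired_pulse_profile,
    segment_sweeps,
)
from laminar_ephys.synthetic import simulate_protocol

geometry = ProbeGeometry()

for name, profile in (("control-like", control_like_profile()),
                      ("ad-like", ad_like_profile())):
    print(f"\n{name} (programmed DG gains: "
          f"25 ms x{profile.ppi_gain[25]:.2f}, 50 ms x{profile.ppi_gain[50]:.2f})")
    for ppi in (25, 50):
        rec = simulate_protocol(
            profile,
            StimulusProtocol(kind="paired_pulse", ppi_ms=ppi, n_repeats=20),
            geometry,
            noise_sd=0.05,
            seed=40 + ppi,
        )
        curve = paired_pulse_profile(extract_features(segment_sweeps(rec)))
        dg = curve.data[(curve.data["layer"] == "DG")
                        & (curve.data["measure"] == "amplitude_mv")]
        row = dg.iloc[0]
        print(f"  PPI {ppi:3d} ms: DG amplitude change "
              f"{row['pct_change_mean']:+.1f}% "
              f"(SEM {row['pct_change_sem']:.1f}, n={row['n']:.0f} pairs)")

# Negative percent change = paired-pulse depression (second response
# smaller), positive = facilitation.  The recovered values track the
# programmed gains: the control dentate depresses at short intervals while
# the hyper-excitable profile facilitates — the core short-interval
# contrast between the two simulated phenotypes.
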