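"""Protocol simulator: determinism, programmed gains, flags, protocol shapes."""

import numpy as np
import pytest

from laminar_ephys import (
    ProbeGeometry,
    StimulusProtocol,
    ad_like_profile,
    control_like_profile,
    extract_features,
    segment_sweeps,
)
from laminar_ephys.synthetic import (
    current_gain,
    ps_threshold_for_probability,
    simulate_protocol,
)


def unity_ppi_profile():
    import dataclasses

    return dataclasses.replace(
        control_like_profile(),
        ppi_gain={25: 1.0, 50: 1.0, 100: 1.0, 200: 1.0, 500: 1.0, 1000: 1.0},
    )


def test_seed_determinism(geometry):
    proto = StimulusProtocol(kind="paired_pulse", ppi_ms=50, n_repeats=3)
    kwargs = dict(noise_sd=0.05, artifact_amp=5.0, seed=99, amp_jitter_sd=0.1)
    a = simulate_protocol(control_like_profile(), proto, geometry, **kwargs)
    b = simulate_protocol(control_like_profile(), proto, geometry, **kwargs)
    assert np.array_equal(a.potentials, b.potentials)
    assert np.array_equal(a.stim_times, b.stim_times)


def test_unit_gain_pair_p2_equals_p1(geometry):
    """With ppi gain 1, no noise and no artifact, the second-pulse sweep is
    sample-for-sample identical to the first."""
    proto = StimulusProtocol(kind="paired_pulse", ppi_ms=50, n_repeats=2)
    rec = simulate_protocol(
        unity_ppi_profile(), proto, geometry, noise_sd=0.0, artifact_amp=0.0, seed=0
    )
    sweeps = segment_sweeps(rec, pre_ms=2.0, post_ms=30.0)
    p1 = sweeps.sweeps[sweeps.select(1)]
    p2 = sweeps.sweeps[sweeps.select(2)]
    # equal up to the (sub-µV) tail of the first response in the second window
    assert np.allclose(p1, p2, atol=1e-6)


def test_reentry_flags_by_construction(geometry):
    prof = ad_like_profile(reentry_first_pulse=10)
    rec = simulate_protocol(
        prof, StimulusProtocol(kind="train"), geometry, noise_sd=0.0, seed=0
    )
    flags = rec.ground_truth.reentry_flags
    assert np.array_equal(np.flatnonzero(flags) + 1, np.arange(10, 21))


def test_io_series_amplitudes_nondecreasing(geometry):
    currents = tuple(range(50, 601, 50))
    proto = StimulusProtocol(kind="io_series", current_ua=currents, n_repeats=1)
    rec = simulate_protocol(
        control_like_profile(), proto, geometry, noise_sd=0.0, artifact_amp=0.0, seed=0
    )
    df = extract_features(segment_sweeps(rec), layers=("CA1sr",))
    p1 = df[(df["source"] == "per_sweep") & (df["pulse_index"] == 1)]
    amps = np.abs(p1.sort_values("current_ua")["amplitude_mv"].to_numpy())
    assert np.all(np.diff(amps) >= -1e-9)


def test_current_gain_is_saturating():
    c = np.linspace(50.0, 600.0, 12)
    g = current_gain(c)
    assert np.all(np.diff(g) > 0)
    assert current_gain(175.0) == pytest.approx(0.5)
    assert g[-1] < 1.0


def test_train_span_matches_protocol(geometry):
    rec = simulate_protocol(
        control_like_profile(),
        StimulusProtocol(kind="train"),
        geometry,
        noise_sd=0.0,
        seed=0,
        pre_s=0.5,
        post_s=0.5,
    )
    span_s = (rec.stim_times[-1] - rec.stim_times[0]) / rec.sampling_rate
    assert span_s == pytest.approx(19 / 5.0)  # 20 pulses at 5 Hz span 3.8 s
    assert rec.duration_s > span_s + 1.0  # pre/post padding present


def test_negative_noise_rejected(geometry):
    with pytest.raises(ValueError):
        simulate_protocol(
            control_like_profile(),
            StimulusProtocol(kind="train"),
            geometry,
            noise_sd=-1.0,
            seed=0,
        )


def test_unknown_protocol_kind_rejected():
    with pytest.raises(ValueError):
        StimulusProtocol(kind="tetanus")


def test_ppi_must_come_from_stated_set():
    with pytest.raises(ValueError):
        StimulusProtocol(kind="paired_pulse", ppi_ms=75)


def test_ps_threshold_quantile():
    from scipy.stats import norm

    thr = ps_threshold_for_probability(2.0, 0.1, 0.6)
    # jitter ~ N(1, 0.1): P(2 * jitter > thr) should be 0.6
    p = 1.0 - norm.cdf((thr / 2.0 - 1.0) / 0.1)
    assert p == pytest.approx(0.6, abs=1e-9)


def test_stochastic_ps_matches_target_probability(geometry):
    """With the threshold placed at the 40th percentile of the jittered
    amplitude, PS injections occur on ~60% of pulses."""
    from laminar_ephys.synthetic import unit_contact_waveforms
    from laminar_ephys.synthetic.simulate import SIM_CONDUCTIVITY
    import dataclasses

    unit = unit_contact_waveforms(
        __import__("laminar_ephys").default_component_catalogue(),
        geometry,
        10_000.0,
        60.0,
        SIM_CONDUCTIVITY,
    )
    a0 = float(np.abs(unit[geometry.layer_channel("DG_granule")]).max())
    prof = dataclasses.replace(
        unity_ppi_profile(), ps_threshold_mv=ps_threshold_for_probability(a0, 0.1, 0.6)
    )
    flags = []
    for seed in range(10):
        rec = simulate_protocol(
            prof,
            StimulusProtocol(kind="paired_pulse", ppi_ms=50, n_repeats=20),
            geometry,
            noise_sd=0.0,
            seed=seed,
            amp_jitter_sd=0.1,
        )
        flags.append(rec.ground_truth.ps_flags)
    rate = np.concatenate(flags).mean()
    assert rate == pytest.approx(0.6, abs=0.06)  # 400 Bernoulli draws
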