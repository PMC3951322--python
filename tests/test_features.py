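"""Five-point template measurement and population-spike detection."""

import numpy as np
import pytest

from laminar_ephys import (
    FivePointTemplate,
    StimulusProtocol,
    control_like_profile,
    detect_ps,
    extract_features,
    measure_amplitude,
    measure_latency,
    place_template,
    ps_probability,
    segment_sweeps,
)
from laminar_ephys.synthetic import alpha_kernel, simulate_protocol


TIMES = np.arange(-100, 400) / 10.0  # 10 kHz, 10 ms pre / 40 ms post


def alpha_trace(onset=5.0, tau=2.0, amp=2.0, sign=1.0):
    return sign * amp * alpha_kernel(TIMES, onset, tau)


class TestTemplatePlacement:
    def test_brackets_analytic_alpha_peak(self):
        tpl = place_template(alpha_trace(), TIMES, "positive_going")
        peak = 7.0  # onset + tau
        assert TIMES[tpl.p4] <= peak <= TIMES[tpl.p5]
        mid = (TIMES[tpl.p4] + TIMES[tpl.p5]) / 2
        assert mid == pytest.approx(peak, abs=0.1)
        assert not tpl.low_confidence

    def test_flat_trace_is_no_response(self):
        assert place_template(np.zeros_like(TIMES), TIMES, "positive_going") is None

    def test_inverted_polarity_flagged_low_confidence(self):
        tpl = place_template(alpha_trace(sign=-1.0), TIMES, "positive_going")
        assert tpl is not None and tpl.low_confidence

    def test_ordering_invariant_enforced(self):
        tpl = place_template(alpha_trace(), TIMES, "positive_going")
        assert tpl.p1 < tpl.p2 < tpl.p3 <= tpl.p4 < tpl.p5
        with pytest.raises(ValueError):
            FivePointTemplate(10, 9, 12, 15, 20, "positive_going")


class TestAmplitude:
    def test_definition_arithmetic(self):
        trace = np.zeros(100)
        trace[20:31] = 0.5  # p2..p3 region
        trace[60:71] = 2.0  # p4..p5 region
        tpl = FivePointTemplate(5, 20, 30, 60, 70, "positive_going")
        assert measure_amplitude(trace, tpl) == pytest.approx(1.5)

    def test_constant_trace_zero(self):
        tpl = FivePointTemplate(5, 20, 30, 60, 70, "positive_going")
        assert measure_amplitude(np.full(100, 3.3), tpl) == 0.0

    def test_trough_sign_retained(self):
        trace = -alpha_trace()
        tpl = place_template(trace, TIMES, "negative_going")
        assert measure_amplitude(trace, tpl) < 0

    def test_offset_invariance(self):
        trace = alpha_trace()
        tpl = place_template(trace, TIMES, "positive_going")
        a0 = measure_amplitude(trace, tpl)
        assert measure_amplitude(trace + 7.5, tpl) == pytest.approx(a0, abs=1e-12)

    def test_scaling_linearity(self):
        trace = alpha_trace()
        tpl = place_template(trace, TIMES, "positive_going")
        assert measure_amplitude(3.0 * trace, tpl) == pytest.approx(
            3.0 * measure_amplitude(trace, tpl)
        )

    def test_out_of_range_template(self):
        tpl = FivePointTemplate(5, 20, 30, 60, 99, "positive_going")
        with pytest.raises(IndexError):
            measure_amplitude(np.zeros(50), tpl)


class TestLatency:
    def test_definition_arithmetic(self):
        # p1 at 0 ms, p4 at 7 ms, p5 at 9 ms -> 8 ms
        times = np.arange(0.0, 20.0, 1.0)
        tpl = FivePointTemplate(0, 2, 4, 7, 9, "positive_going")
        assert measure_latency(np.zeros(20), tpl, times) == pytest.approx(8.0)

    def test_translation_invariance(self):
        times = np.arange(0.0, 20.0, 1.0)
        tpl = FivePointTemplate(0, 2, 4, 7, 9, "positive_going")
        l0 = measure_latency(np.zeros(20), tpl, times)
        assert measure_latency(np.zeros(20), tpl, times + 13.0) == pytest.approx(l0)

    def test_matches_alpha_peak_at_10khz(self):
        trace = alpha_trace(onset=5.5, tau=2.0)
        tpl = place_template(trace, TIMES, "positive_going")
        lat = measure_latency(trace, tpl, TIMES)
        t_p1 = TIMES[tpl.p1]
        assert (lat + t_p1) == pytest.approx(7.5, abs=0.1)  # one sample


class TestPopulationSpike:
    def test_injected_transient_detected_at_injection_time(self, geometry):
        import dataclasses

        from laminar_ephys.synthetic import unit_contact_waveforms
        from laminar_ephys.synthetic.simulate import SIM_CONDUCTIVITY

        import laminar_ephys as le

        unit = unit_contact_waveforms(
            le.default_component_catalogue(), geometry, 10_000.0, 60.0, SIM_CONDUCTIVITY
        )
        a0 = float(np.abs(unit[geometry.layer_channel("DG_granule")]).max())
        prof = dataclasses.replace(
            control_like_profile(), ps_threshold_mv=0.5 * a0
        )  # every pulse crosses
        rec = simulate_protocol(
            prof,
            StimulusProtocol(kind="paired_pulse", ppi_ms=200, n_repeats=3),
            geometry,
            noise_sd=0.05,
            seed=4,
        )
        sweeps = segment_sweeps(rec)
        ch = geometry.layer_channel("DG_granule")
        truth_t = rec.ground_truth.ps_times_ms
        assert np.all(rec.ground_truth.ps_flags)
        for i in range(sweeps.n_sweeps):
            found, t_ps = detect_ps(sweeps.sweeps[i, ch], sweeps.times_ms)
            assert found
            assert abs(t_ps - truth_t[i]) <= 0.5

    def test_smooth_fepsp_not_detected(self):
        found, _ = detect_ps(alpha_trace(), TIMES)
        assert not found

    def test_noise_only_not_detected(self):
        from laminar_ephys.synthetic import band_limited_noise

        hits = 0
        for i in range(50):
            tr = band_limited_noise(np.random.default_rng(i), (1, 500), 10_000.0, 0.05)[0]
            hits += detect_ps(tr, TIMES)[0]
        assert hits == 0


class TestPsProbability:
    @pytest.mark.parametrize("n_pos,expected", [(0, 0.0), (20, 1.0), (12, 0.6)])
    def test_fraction_with_basis(self, n_pos, expected):
        flags = np.zeros(20, dtype=bool)
        flags[:n_pos] = True
        p, k, n = ps_probability(flags)
        assert (p, k, n) == (expected, n_pos, 20)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ps_probability(np.array([], dtype=bool))


def test_per_sweep_equals_average_at_zero_noise(clean_pair_sweeps):
    """With noise off, per-sweep and sweep-average measurements agree."""
    df = extract_features(clean_pair_sweeps)
    for (layer, pidx), grp in df.groupby(["layer", "pulse_index"]):
        avg = grp[grp["source"] == "sweep_average"]["amplitude_mv"].iloc[0]
        per = grp[grp["source"] == "per_sweep"]["amplitude_mv"].to_numpy()
        assert np.allclose(per, avg, atol=1e-9)
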