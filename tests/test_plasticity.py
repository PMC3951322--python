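"""I/O curves, paired-pulse/train indices and re-entrance calls."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from laminar_ephys import (
    IOCurve,
    StimulusProtocol,
    ad_like_profile,
    build_io_curve,
    control_like_profile,
    detect_reentrance,
    extract_features,
    extract_train_features,
    half_maximal_current,
    paired_pulse_profile,
    percent_change,
    segment_sweeps,
    train_profile,
)
from laminar_ephys.synthetic import simulate_protocol


class TestPercentChange:
    def test_identity_is_zero(self):
        assert percent_change(1.7, 1.7) == 0.0

    def test_facilitation_arithmetic(self):
        assert percent_change(1.5, 1.0) == pytest.approx(50.0)

    def test_zero_reference_flagged(self):
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)


class TestHalfMaximalCurrent:
    def test_linear_curve_interpolation(self):
        curve = IOCurve(
            currents_ua=np.array([50.0, 300.0, 600.0]),
            amplitudes_mv={"CA1sr": np.array([0.0, 1.0, 2.0])},
        )
        assert half_maximal_current(curve) == pytest.approx(300.0)

    def test_flat_curve_returns_smallest_current(self):
        curve = IOCurve(
            currents_ua=np.array([50.0, 300.0, 600.0]),
            amplitudes_mv={"CA1sr": np.array([1.0, 1.0, 1.0])},
        )
        assert half_maximal_current(curve) == 50.0

    def test_all_zero_curve_rejected(self):
        curve = IOCurve(
            currents_ua=np.array([50.0, 300.0]),
            amplitudes_mv={"CA1sr": np.array([0.0, 0.0])},
        )
        with pytest.raises(ValueError):
            half_maximal_current(curve)

    def test_invariant_to_uniform_scaling(self):
        a = np.array([0.1, 0.9, 1.6, 2.0])
        c = np.array([50.0, 200.0, 400.0, 600.0])
        h1 = half_maximal_current(IOCurve(c, {"CA1sr": a}))
        h2 = half_maximal_current(IOCurve(c, {"CA1sr": 12.0 * a}))
        assert h1 == pytest.approx(h2)

    def test_sigmoid_half_point_recovered(self, geometry):
        """On a simulated I/O series the recovered half-max lies within one
        current step of the analytic half-point of the programmed sigmoid."""
        from laminar_ephys.synthetic.simulate import current_gain

        currents = tuple(range(50, 601, 50))
        rec = simulate_protocol(
            control_like_profile(),
            StimulusProtocol(kind="io_series", current_ua=currents, n_repeats=1),
            geometry,
            noise_sd=0.0,
            artifact_amp=0.0,
            seed=0,
        )
        curve = build_io_curve(extract_features(segment_sweeps(rec)))
        got = half_maximal_current(curve)
        # analytic: current where the Hill gain reaches half its value at
        # the largest tested current
        g = current_gain(np.asarray(currents, dtype=float))
        target = 0.5 * g[-1]
        analytic = np.interp(target, g, currents)
        assert abs(got - analytic) <= 50.0


class TestIOCurve:
    def _table(self):
        rows = []
        for cur, amp in ((100.0, 1.0), (200.0, 2.0)):
            for pidx, a in ((1, amp), (2, 99.0)):
                rows.append(
                    dict(
                        session="s",
                        protocol="io_series",
                        layer="CA1sr",
                        pulse_index=pidx,
                        ppi_ms=np.nan,
                        current_ua=cur,
                        sweep=0,
                        amplitude_mv=a,
                        latency_ms=8.0,
                        ps_flag=False,
                        source="per_sweep",
                        low_confidence=False,
                    )
                )
        return pd.DataFrame(rows)

    def test_reproduces_pairs_and_ignores_p2(self):
        curve = build_io_curve(self._table())
        assert np.array_equal(curve.currents_ua, [100.0, 200.0])
        assert np.array_equal(curve.amplitudes_mv["CA1sr"], [1.0, 2.0])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            build_io_curve(self._table().iloc[0:0])


class TestPairedPulseProfile:
    def test_unit_gains_give_flat_zero_profile(self, geometry):
        prof = dataclasses.replace(
            control_like_profile(),
            ppi_gain={k: 1.0 for k in (25, 50, 100, 200, 500, 1000)},
        )
        rec = simulate_protocol(
            prof,
            StimulusProtocol(kind="paired_pulse", ppi_ms=200, n_repeats=3),
            geometry,
            noise_sd=0.0,
            artifact_amp=0.0,
            seed=0,
        )
        curve = paired_pulse_profile(extract_features(segment_sweeps(rec)))
        assert np.allclose(curve.data["pct_change_mean"], 0.0, atol=1e-9)

    def test_programmed_depression_recovered_exactly(self, geometry):
        """ppi_gain 0.8 at 25 ms, noise off: DG percent change is −20%."""
        rec = simulate_protocol(
            control_like_profile(),  # gain 0.80 at 25 ms
            StimulusProtocol(kind="paired_pulse", ppi_ms=25, n_repeats=3),
            geometry,
            noise_sd=0.0,
            artifact_amp=0.0,
            seed=0,
        )
        curve = paired_pulse_profile(extract_features(segment_sweeps(rec)))
        dg = curve.data[
            (curve.data["layer"] == "DG") & (curve.data["measure"] == "amplitude_mv")
        ]
        assert dg["pct_change_mean"].iloc[0] == pytest.approx(-20.0, abs=0.5)

    def test_facilitation_sign_at_short_intervals(self, geometry):
        rec = simulate_protocol(
            ad_like_profile(),
            StimulusProtocol(kind="paired_pulse", ppi_ms=50, n_repeats=20),
            geometry,
            noise_sd=0.05,
            seed=1,
        )
        curve = paired_pulse_profile(extract_features(segment_sweeps(rec)))
        dg = curve.data[
            (curve.data["layer"] == "DG") & (curve.data["measure"] == "amplitude_mv")
        ]
        assert dg["pct_change_mean"].iloc[0] > 0


class TestTrainProfile:
    def test_constant_gain_flat_profile(self, geometry):
        prof = dataclasses.replace(control_like_profile(), train_gain=(1.0,) * 20)
        rec = simulate_protocol(
            prof,
            StimulusProtocol(kind="train"),
            geometry,
            noise_sd=0.0,
            artifact_amp=0.0,
            seed=0,
        )
        curve = train_profile(extract_train_features(segment_sweeps(rec)))
        amp = curve.data[curve.data["measure"] == "amplitude_mv"]
        assert np.allclose(amp["pct_change"], 0.0, atol=1e-9)
        for layer, grp in amp.groupby("layer"):
            assert np.allclose(grp["raw"], grp["raw"].iloc[0], atol=1e-9)

    def test_linear_ramp_doubles_by_pulse_20(self, geometry):
        ramp = tuple(1.0 + k / 19.0 for k in range(20))  # 1.0 -> 2.0
        prof = dataclasses.replace(control_like_profile(), train_gain=ramp)
        rec = simulate_protocol(
            prof,
            StimulusProtocol(kind="train"),
            geometry,
            noise_sd=0.0,
            artifact_amp=0.0,
            seed=0,
        )
        curve = train_profile(extract_train_features(segment_sweeps(rec)))
        dg = curve.data[
            (curve.data["layer"] == "DG")
            & (curve.data["measure"] == "amplitude_mv")
            & (curve.data["pulse_index"] == 20)
        ]
        assert dg["pct_change"].iloc[0] == pytest.approx(100.0, abs=1e-6)

    def test_missing_pulses_listed(self):
        df = pd.DataFrame(
            dict(
                session="s",
                protocol="train",
                layer="DG",
                pulse_index=[1, 2, 3],
                ppi_ms=np.nan,
                current_ua=200.0,
                sweep=[0, 1, 2],
                amplitude_mv=[1.0, 1.1, 1.2],
                latency_ms=[8.0, 8.0, 8.0],
                ps_flag=False,
                source="per_sweep",
                low_confidence=False,
            )
        )
        with pytest.raises(ValueError, match=r"missing.*4"):
            train_profile(df)


class TestReentrance:
    def test_boundary_first_pulse_20(self, geometry):
        prof = ad_like_profile(reentry_first_pulse=20)
        rec = simulate_protocol(
            prof, StimulusProtocol(kind="train"), geometry, noise_sd=0.0, seed=0
        )
        calls = detect_reentrance(segment_sweeps(rec))
        assert all(c.first_pulse == 20 for c in calls.values())

    def test_latency_matches_programmed(self, geometry):
        prof = ad_like_profile(reentry_first_pulse=10)  # peaks at 15.7 ms
        rec = simulate_protocol(
            prof, StimulusProtocol(kind="train"), geometry, noise_sd=0.0, seed=0
        )
        calls = detect_reentrance(segment_sweeps(rec))
        for call in calls.values():
            assert call.first_pulse == 10
            assert call.latency_ms == pytest.approx(15.7, abs=1.0)

    def test_no_programmed_reentry_no_call(self, geometry):
        rec = simulate_protocol(
            control_like_profile(),
            StimulusProtocol(kind="train"),
            geometry,
            noise_sd=0.05,
            seed=8,
        )
        calls = detect_reentrance(segment_sweeps(rec))
        assert all(c.first_pulse is None for c in calls.values())

    def test_window_exceeding_sweep_rejected(self, geometry):
        rec = simulate_protocol(
            control_like_profile(),
            StimulusProtocol(kind="train"),
            geometry,
            noise_sd=0.0,
            seed=0,
        )
        sweeps = segment_sweeps(rec, post_ms=20.0)
        with pytest.raises(ValueError):
            detect_reentrance(sweeps, window_ms=(12.0, 25.0))
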