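"""CSD estimator: closed forms, loop-oracle equivalence, rendering contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laminar_ephys import (
    estimate_csd,
    interpolate_csd,
    normalize_for_rendering,
)


def naive_csd(potentials, spacing, conductivity=1.0):
    """Per-sample, per-channel loop oracle for the second spatial difference."""
    phi = np.atleast_2d(potentials)
    n_ch, n_t = phi.shape
    out = np.zeros((n_ch - 2, n_t))
    for z in range(1, n_ch - 1):
        for t in range(n_t):
            out[z - 1, t] = (
                -conductivity
                * (phi[z + 1, t] - 2.0 * phi[z, t] + phi[z - 1, t])
                / spacing**2
            )
    return out


def test_linear_depth_profile_gives_zero_density():
    z = np.arange(8.0)
    phi = np.outer(3.0 * z + 1.0, np.ones(5))
    est = estimate_csd(phi, spacing_um=1.0)
    assert np.allclose(est.density, 0.0, atol=1e-12)


def test_quadratic_profile_gives_exact_constant():
    z = np.arange(8.0)
    phi = np.outer(z**2, np.ones(3))
    est = estimate_csd(phi, spacing_um=1.0, conductivity=1.0)
    assert np.allclose(est.density, -2.0, atol=1e-12)


@pytest.mark.parametrize("n_ch", [4, 6, 8])
def test_matches_naive_loop_exactly(n_ch, rng):
    phi = rng.normal(size=(n_ch, 17))
    est = estimate_csd(phi, spacing_um=50.0, conductivity=2.0)
    assert np.array_equal(est.density, naive_csd(phi, 50.0, 2.0))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(-3, 3), st.floats(-3, 3))
def test_linearity(seed, a, b):
    rng = np.random.default_rng(seed)
    p1, p2 = rng.normal(size=(2, 6, 9))
    lhs = estimate_csd(a * p1 + b * p2, 25.0).density
    rhs = a * estimate_csd(p1, 25.0).density + b * estimate_csd(p2, 25.0).density
    assert np.allclose(lhs, rhs, atol=1e-9)


def test_interpolation_inserts_linear_steps():
    est = estimate_csd(np.zeros((4, 1)), spacing_um=1.0)
    est.density = np.array([[0.0], [21.0]])
    est.depths_um = np.array([1.0, 2.0])
    interpolate_csd(est, steps=20)
    assert np.allclose(est.interp_density[:, 0], np.arange(22.0))


def test_interpolation_preserves_nodes_and_extrema(rng):
    phi = rng.normal(size=(8, 12))
    est = interpolate_csd(estimate_csd(phi, 50.0), steps=20)
    # values at original channel depths unchanged
    assert np.allclose(est.interp_density[::21], est.density)
    # linear interpolation cannot overshoot
    assert est.interp_density.max() == pytest.approx(est.density.max())
    assert est.interp_density.min() == pytest.approx(est.density.min())


def test_constant_map_interpolates_constant():
    est = estimate_csd(np.zeros((5, 4)), 1.0)
    est.density = np.full((3, 4), 2.5)
    interpolate_csd(est)
    assert np.allclose(est.interp_density, 2.5, atol=1e-12)


def test_rendering_symmetric_map_keeps_zero_neutral():
    est = estimate_csd(np.zeros((5, 3)), 1.0)
    est.density = np.array([[-4.0, 0.0, 4.0]] * 3)
    r = normalize_for_rendering(est, use_interp=False)
    assert r.symmetric
    assert np.allclose(r.grid[:, 1], 0.0)


def test_rendering_constant_map_all_neutral():
    est = estimate_csd(np.zeros((5, 3)), 1.0)
    est.density = np.full((3, 3), 1.7)
    r = normalize_for_rendering(est, use_interp=False)
    assert np.all(r.grid == 0.0)


def test_rendering_scale_invariance(rng):
    phi = rng.normal(size=(6, 10))
    est1 = estimate_csd(phi, 50.0)
    est2 = estimate_csd(10.0 * phi, 50.0)
    r1 = normalize_for_rendering(est1, use_interp=False)
    r2 = normalize_for_rendering(est2, use_interp=False)
    assert np.allclose(r1.grid, r2.grid, atol=1e-12)


def test_input_validation(rng):
    with pytest.raises(ValueError):
        estimate_csd(np.zeros((2, 5)), 1.0)
    bad = np.zeros((4, 5))
    bad[1, 1] = np.nan
    with pytest.raises(ValueError):
        estimate_csd(bad, 1.0)
    with pytest.raises(ValueError):
        estimate_csd(np.zeros((4, 5)), 1.0, smoothing_degree=1)
    with pytest.raises(ValueError):
        interpolate_csd(estimate_csd(np.zeros((5, 2)), 1.0), steps=0)


def test_csd_hdf5_roundtrip(tmp_path, rng):
    from laminar_ephys import load_csd, save_csd

    est = interpolate_csd(estimate_csd(rng.normal(size=(8, 15)), 50.0), steps=20)
    path = tmp_path / "map.h5"
    save_csd(est, path)
    back = load_csd(path)
    assert np.array_equal(back.density, est.density)
    assert np.array_equal(back.interp_density, est.interp_density)
    assert back.spacing_um == est.spacing_um
    assert back.smoothing_degree == est.smoothing_degree


def test_halving_spacing_reduces_roundtrip_error(geometry, geometry32):
    """Discretisation convergence: the 32-contact/50 µm probe estimates the
    same programmed field with smaller RMS error than 16/100 µm."""
    from laminar_ephys import CsdComponent
    from laminar_ephys.synthetic import build_evoked_density, forward_grid, solve_forward

    comps = (CsdComponent("w", 700.0, 220.0, 5.0, 2.0, "sink", 2.0, 330.0),)
    t = np.arange(0.0, 15.0, 0.25)
    errs = {}
    for geo in (geometry, geometry32):
        z = forward_grid(geo, step_um=12.5)
        density = build_evoked_density(comps, 1.0, t, z)
        phi = solve_forward(density, z, geo)
        est = estimate_csd(phi, geo.spacing_um, depths_um=geo.contact_depths_um)
        idx = np.searchsorted(z, geo.contact_depths_um[1:-1])
        truth = density[idx]
        errs[geo.spacing_um] = np.sqrt(np.mean((est.density - truth) ** 2) / np.mean(truth**2))
    assert errs[50.0] < errs[100.0]
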