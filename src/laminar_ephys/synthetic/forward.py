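"""1-D Poisson forward model: programmed CSD → laminar potentials.

In one dimension, with currents running parallel to the probe and spatially
homogeneous tissue conductivity σ, the extracellular potential obeys

    d²φ/dz² = −C(z, t) / σ

where C is the current source density (sinks negative).  The solver
discretises this relation on a fine depth grid with zero-potential
(far-field) boundaries well beyond the probe ends and samples the solution
at the contact depths.  It is the exact inverse of the second-spatial-
difference CSD estimator used on real recordings, which makes simulated
recordings usable as an oracle for the whole analysis chain.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.linalg import solveh_banded

from ..core import GeometryError, ProbeGeometry
from .components import CsdComponent

#: Minimum margin (µm) the solver grid must extend beyond the outermost
#: contacts for the zero-potential boundary to act as a far field.
GRID_MARGIN_UM = 500.0
#: Solver grid must be at least this many times finer than contact spacing.
GRID_REFINEMENT = 4


def alpha_kernel(t_ms: np.ndarray, onset_ms: float, tau_ms: float) -> np.ndarray:
    """Normalised alpha function: 0 before onset, unit peak at
    ``onset_ms + tau_ms``."""
    s = (np.asarray(t_ms, dtype=float) - onset_ms) / tau_ms
    out = np.where(s > 0, s * np.exp(1.0 - s), 0.0)
    return out


def forward_grid(geometry: ProbeGeometry, step_um: float | None = None) -> np.ndarray:
    """Fine depth grid for the Poisson solver: ``GRID_REFINEMENT``× finer
    than the contact spacing and extending ``GRID_MARGIN_UM`` past both
    probe ends.  The grid is aligned with the contacts."""
    if step_um is None:
        step_um = geometry.spacing_um / GRID_REFINEMENT
    depths = geometry.contact_depths_um
    lo = depths[0] - GRID_MARGIN_UM
    hi = depths[-1] + GRID_MARGIN_UM
    n = int(round((hi - lo) / step_um)) + 1
    return lo + step_um * np.arange(n)


def build_evoked_density(
    components: Sequence[CsdComponent],
    gain: float,
    t_ms: np.ndarray,
    z_um: np.ndarray,
) -> np.ndarray:
    """Sum the catalogue into a depth × time density grid.

    Each component contributes a Gaussian-in-depth, alpha-in-time primary
    lobe scaled to ``peak_density × gain`` plus opposite-sign return lobes
    carrying exactly the opposite discrete spatial integral, so the column
    sum over depth is zero at every time sample to machine precision
    (current conservation).  The return current is split between
    ``center ± paired_return_offset`` — the larger share at the stated
    offset (the anatomically observed return, e.g. the granule-cell source
    of the DG molecular sink), the remainder mirrored on the opposite side.
    A one-sided return would leave a net dipole moment, and in a bounded
    1-D volume conductor a dipole's potential does not decay: it would
    drape a linear far field across every other layer.  Splitting the
    return keeps each component's potential compact, as 3-D volume
    conduction does in tissue.
    """
    if len(components) == 0:
        raise ValueError("component catalogue must be non-empty")
    if gain <= 0:
        raise ValueError("gain must be > 0")
    z = np.asarray(z_um, dtype=float)
    t = np.asarray(t_ms, dtype=float)
    density = np.zeros((z.size, t.size))
    for c in components:
        primary = np.exp(-0.5 * ((z - c.center_depth_um) / c.spatial_sd_um) ** 2)
        near = np.exp(
            -0.5 * ((z - c.center_depth_um - c.paired_return_offset_um) / c.spatial_sd_um) ** 2
        )
        far = np.exp(
            -0.5 * ((z - c.center_depth_um + c.paired_return_offset_um) / c.spatial_sd_um) ** 2
        )
        # equalise discrete integrals, then scale so the primary lobe peaks
        # at peak_density
        primary /= primary.sum()
        f = c.return_fraction
        ret = f * near / near.sum() + (1.0 - f) * far / far.sum()
        pair = primary - ret
        pair *= c.sign * c.peak_density * gain / primary.max()
        density += pair[:, None] * alpha_kernel(t, c.onset_latency_ms, c.time_constant_ms)
    return density


def solve_forward(
    csd_profile: np.ndarray,
    z_um: np.ndarray,
    geometry: ProbeGeometry,
    conductivity: float = 1.0,
) -> np.ndarray:
    """Solve the 1-D Poisson relation for contact potentials.

    Parameters
    ----------
    csd_profile
        depth × time density grid on the fine grid ``z_um`` (sinks
        negative, arbitrary units).
    z_um
        Uniform fine depth grid; must be ≥ ``GRID_REFINEMENT``× finer than
        the contact spacing and extend ≥ ``GRID_MARGIN_UM`` beyond the
        outermost contacts.
    conductivity
        Homogeneous tissue conductivity (> 0); output is in the same
        arbitrary scale as the input density divided by this factor.

    Returns
    -------
    channels × time potential matrix sampled at the contact depths, with
    zero-potential boundary conditions at the grid edges.
    """
    z = np.asarray(z_um, dtype=float)
    C = np.asarray(csd_profile, dtype=float)
    if C.ndim != 2 or C.shape[0] != z.size:
        raise ValueError("csd_profile must be depth × time on the given grid")
    if not np.all(np.isfinite(C)):
        raise ValueError("csd_profile contains non-finite densities")
    if conductivity <= 0:
        raise ValueError("conductivity must be > 0")
    steps = np.diff(z)
    h = steps[0]
    if not np.allclose(steps, h):
        raise GeometryError("solver grid must be uniform")
    if h > geometry.spacing_um / GRID_REFINEMENT + 1e-9:
        raise GeometryError(
            f"solver grid step {h:g} µm coarser than spacing/{GRID_REFINEMENT}"
        )
    depths = geometry.contact_depths_um
    if z[0] > depths[0] - GRID_MARGIN_UM + 1e-9 or z[-1] < depths[-1] + GRID_MARGIN_UM - 1e-9:
        raise GeometryError(
            f"solver grid must extend ≥ {GRID_MARGIN_UM:g} µm beyond the probe ends"
        )

    # interior unknowns; Dirichlet φ = 0 at both grid edges
    n = z.size - 2
    rhs = C[1:-1, :] * (h * h / conductivity)
    # positive-definite tridiagonal (−A)φ = rhs with A the second difference
    ab = np.zeros((2, n))
    ab[0, 1:] = -1.0
    ab[1, :] = 2.0
    phi_int = solveh_banded(ab, rhs, lower=False)
    phi = np.zeros_like(C)
    phi[1:-1, :] = phi_int

    # linear interpolation at contact depths (exact when contacts sit on
    # grid nodes, which forward_grid guarantees)
    idx = np.clip(np.searchsorted(z, depths, side="right") - 1, 0, z.size - 2)
    frac = (depths - z[idx]) / h
    return (1.0 - frac)[:, None] * phi[idx, :] + frac[:, None] * phi[idx + 1, :]


@lru_cache(maxsize=32)
def unit_contact_waveforms(
    components: tuple[CsdComponent, ...],
    geometry: ProbeGeometry,
    sampling_rate: float,
    window_ms: float,
    conductivity: float = 1.0,
) -> np.ndarray:
    """Contact potentials (channels × window samples) evoked by one pulse of
    the catalogue at unit gain.  Cached: the forward model is linear, so
    scaled copies of this waveform serve every pulse of a protocol."""
    n = int(round(window_ms * 1e-3 * sampling_rate))
    t_ms = np.arange(n) / sampling_rate * 1e3
    z = forward_grid(geometry)
    density = build_evoked_density(components, 1.0, t_ms, z)
    w = solve_forward(density, z, geometry, conductivity)
    w.setflags(write=False)
    return w
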