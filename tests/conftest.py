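"""Shared fixtures: the study-condition phantom and derived tracking products.

Heavy objects (phantom fields, flow maps, particle sets) are session-scoped
so the validation experiment is assembled once and reused across tests.
"""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from voltrack import (
    GridGeometry,
    SolverOptions,
    TimeAxis,
    VelocityField,
    compute_flowmap,
    default_phantom_spec,
    generate_field,
    make_volume_function,
    trace_particles,
    track_volume,
)
from voltrack.particles import ReleaseSpec
from voltrack.segments import diastolic_timepoints, transmitral_flow_curve

PHANTOM_SEED = 2024


@pytest.fixture(scope="session")
def phantom32():
    """Study-condition phantom: 32^3, 25 frames, noise sigma = 0.02*VENC."""
    spec = default_phantom_spec(n=32, n_frames=25, noise_sigma=0.02, seed=PHANTOM_SEED)
    corrupted, truth, meta = generate_field(spec)
    return {"spec": spec, "corrupted": corrupted, "truth": truth, "meta": meta}


@pytest.fixture(scope="session")
def phantom_tracking(phantom32):
    """Flow map from inflow onset + tracked transvalvular plane + timepoints."""
    corrupted = phantom32["corrupted"]
    meta = phantom32["meta"]
    vp = meta["valve_plane"]
    times, flow = transmitral_flow_curve(
        corrupted, vp["point"], (0, 0, -1), meta["flow_disc_radius"]
    )
    t_mid, t_end = diastolic_timepoints(times, flow)
    t0 = meta["t0_inflow"]
    qt = times[times >= t0 - 1e-9]
    fm = compute_flowmap(corrupted, t0, qt, SolverOptions(scheme="high_resolution"))
    f = make_volume_function("plane", point=vp["point"], normal=vp["normal"])
    tv = track_volume(fm, f)
    return {
        "fm": fm, "tv": tv, "f": f, "t0": t0, "t_mid": t_mid, "t_end": t_end,
        "times": times, "flow": flow,
    }


@pytest.fixture(scope="session")
def phantom_particles(phantom32, phantom_tracking):
    """1000 particles released every 20 ms during inflow (the paper protocol)."""
    meta = phantom32["meta"]
    tr = phantom_tracking
    rel = ReleaseSpec(
        kind="cylinder", params=meta["seed_region"],
        t_start=tr["t0"], t_stop=tr["t_end"] - 1e-9, cadence=0.020,
    )
    rng = np.random.default_rng(PHANTOM_SEED + 1)
    seeds, rts = rel.sample(1000, rng)
    ps = trace_particles(
        phantom32["corrupted"], seeds, rts, t_end=tr["t_end"], f=tr["f"]
    )
    return {"particles": ps, "release_spec": rel}


def random_divergence_free_field(n=16, n_frames=3, seed=0, spacing=3.0, speed=0.3):
    """Smooth random solenoidal field: discrete curl of filtered noise.

    Central-difference curl of any sampled potential has exactly zero
    central-difference divergence, so these fields exercise the maximum
    principle of the advection scheme under realistic incompressible flow.
    """
    rng = np.random.default_rng(seed)
    grid = GridGeometry(shape=(n, n, n), spacing=(spacing,) * 3)
    data = np.empty((n_frames, 3, n, n, n))
    for k in range(n_frames):
        A = gaussian_filter(rng.normal(size=(3, n + 2, n + 2, n + 2)), sigma=2.5, axes=(1, 2, 3))

        def d(arr, axis):
            return (np.roll(arr, -1, axis) - np.roll(arr, 1, axis)) / (2.0 * spacing)

        ux = d(A[2], 1) - d(A[1], 2)
        uy = d(A[0], 2) - d(A[2], 0)
        uz = d(A[1], 0) - d(A[0], 1)
        u = np.stack([c[1:-1, 1:-1, 1:-1] for c in (ux, uy, uz)])
        u *= speed / max(np.abs(u).max(), 1e-12)
        data[k] = u
    times = TimeAxis(times=np.linspace(0.0, 0.2 * (n_frames - 1), n_frames))
    return VelocityField(grid=grid, time=times, data=data, venc=1.0)
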