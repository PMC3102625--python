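"""Independent pathline integration: fixed-step fourth-order Runge-Kutta.

This module is the validation reference for the flow-map solver and shares
no numerical machinery with it: velocity is interpolated trilinearly in
space and linearly in time (the same model the reference tracer of the
original validation used), and material points are advanced with classic
RK4.  Particles that leave the imaged volume are frozen at their last inside
position and flagged inactive, so the validation denominator stays
well-defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ParameterError
from .field import VelocityField
from .volumes import VolumeFunction

__all__ = ["ParticleSet", "ReleaseSpec", "sample_velocity", "trace_particles"]


# ----------------------------------------------------------------------------
# Velocity sampling
# ----------------------------------------------------------------------------


def _time_blend(field: VelocityField, t: float):
    """Frame pair and weight for linear time interpolation (cyclic-aware)."""
    times = field.time.times
    if field.time.cyclic:
        period = field.time.period
        t = times[0] + math.fmod(t - times[0], period)
        if t < times[0]:
            t += period
        if t > times[-1]:
            w = (t - times[-1]) / (period - (times[-1] - times[0]))
            return times.size - 1, 0, w
    t = min(max(t, times[0]), times[-1])
    k = int(np.searchsorted(times, t, side="right") - 1)
    k = min(max(k, 0), times.size - 2)
    w = (t - times[k]) / (times[k + 1] - times[k])
    return k, k + 1, w


def sample_velocity(field: VelocityField, points, t: float):
    """Velocity in m/s at world points (N, 3) and time t.

    Trilinear in space, linear in time.  Points outside the voxel-centre
    hull get the zero vector and are flagged: returns ``(vel, outside)``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    k0, k1, w = _time_blend(field, t)
    frame = field.data[k0] if w == 0.0 else (1.0 - w) * field.data[k0] + w * field.data[k1]
    idx = field.grid.world_to_voxel(pts)
    nmax = np.asarray(field.grid.shape, dtype=float) - 1.0
    outside = np.any((idx < 0) | (idx > nmax), axis=1)
    coords = idx.T
    vel = np.stack(
        [map_coordinates(frame[c], coords, order=1, mode="constant", cval=0.0)
         for c in range(3)],
        axis=1,
    )
    vel[outside] = 0.0
    return vel, outside


# ----------------------------------------------------------------------------
# Particle containers
# ----------------------------------------------------------------------------


@dataclass
class ParticleSet:
    """Pathline states for a batch of released particles.

    positions has shape (n_times, n_particles, 3), NaN before a particle's
    release time; inactive (out-of-domain) particles retain their last inside
    position.  ``release_inside`` is the release-side label (sign of the
    volume function f at the seed), when a volume function was supplied.
    """

    release_positions: np.ndarray
    release_times: np.ndarray
    times: np.ndarray
    positions: np.ndarray
    active: np.ndarray
    ever_left: np.ndarray
    release_inside: np.ndarray | None = None

    @property
    def n_particles(self) -> int:
        return self.release_positions.shape[0]

    def position_at(self, t: float) -> np.ndarray:
        """Positions (N, 3) linearly interpolated between stored times.

        NaN for particles not yet released at t.
        """
        ts = self.times
        t = min(max(t, ts[0]), ts[-1])
        k = int(np.searchsorted(ts, t, side="right") - 1)
        k = min(max(k, 0), ts.size - 1)
        if ts[k] == t or k == ts.size - 1:
            pos = self.positions[k].copy()
        else:
            w = (t - ts[k]) / (ts[k + 1] - ts[k])
            pos = (1.0 - w) * self.positions[k] + w * self.positions[k + 1]
            # particles released in (ts[k], t]: snap to seed (no earlier sample)
            just = (self.release_times > ts[k]) & (self.release_times <= t)
            pos[just] = self.release_positions[just]
        return pos

    def to_frame(self):
        """Long-format DataFrame (particle_id, time_s, x_mm, y_mm, z_mm, active)."""
        import pandas as pd

        nt, n = self.positions.shape[:2]
        return pd.DataFrame(
            {
                "particle_id": np.tile(np.arange(n), nt),
                "time_s": np.repeat(self.times, n),
                "x_mm": self.positions[:, :, 0].ravel(),
                "y_mm": self.positions[:, :, 1].ravel(),
                "z_mm": self.positions[:, :, 2].ravel(),
                "active": self.active.ravel(),
            }
        )


@dataclass
class ReleaseSpec:
    """Where and when validation particles are released.

    kind='cylinder': params center (mm), radius (mm), half_height (mm), axis
    fixed to z.  kind='box': params lo, hi (mm corners).  kind='points':
    params points (n, 3) used verbatim (cycled if more are requested).
    Releases occur every ``cadence`` seconds in [t_start, t_stop]; particles
    are assigned to release instants round-robin, matching a tracer that
    injects a fixed bolus per instant.
    """

    kind: str
    params: dict
    t_start: float
    t_stop: float
    cadence: float = 0.020

    def release_instants(self) -> np.ndarray:
        n = int(np.floor((self.t_stop - self.t_start) / self.cadence + 1e-9)) + 1
        return self.t_start + self.cadence * np.arange(n)

    def sample(self, n: int, rng: np.random.Generator):
        """Draw n seeds + release times; returns (seeds (n,3), times (n,))."""
        instants = self.release_instants()
        rel = instants[np.arange(n) % instants.size]
        if self.kind == "cylinder":
            c = np.asarray(self.params["center"], dtype=float)
            r = float(self.params["radius"])
            hh = float(self.params["half_height"])
            u = rng.uniform(0.0, 1.0, n)
            th = rng.uniform(0.0, 2.0 * np.pi, n)
            rad = r * np.sqrt(u)
            seeds = np.stack(
                [c[0] + rad * np.cos(th), c[1] + rad * np.sin(th),
                 c[2] + rng.uniform(-hh, hh, n)], axis=1,
            )
        elif self.kind == "box":
            lo = np.asarray(self.params["lo"], dtype=float)
            hi = np.asarray(self.params["hi"], dtype=float)
            seeds = rng.uniform(lo, hi, size=(n, 3))
        elif self.kind == "points":
            pts = np.asarray(self.params["points"], dtype=float)
            seeds = pts[np.arange(n) % len(pts)]
        else:
            raise ParameterError(f"unknown release kind {self.kind!r}")
        order = np.argsort(rel, kind="stable")
        return seeds[order], rel[order]


# ----------------------------------------------------------------------------
# Integration
# ----------------------------------------------------------------------------


def trace_particles(
    field: VelocityField,
    seeds,
    release_times,
    t_end: float,
    dt: float | None = None,
    f: VolumeFunction | None = None,
) -> ParticleSet:
    """Classic RK4 pathlines through the space-time interpolated field.

    Positions are stored at every frame time in the traced window, at every
    release instant and at ``t_end``.  ``dt`` defaults to one tenth of the
    mean frame interval.  ``f``, if given, records each particle's release
    side (f <= 0 -> inside).
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    n = seeds.shape[0]
    rel = np.broadcast_to(np.asarray(release_times, dtype=float), (n,)).copy()
    if np.any(rel > t_end):
        raise ParameterError("all release times must be <= t_end")
    if dt is None:
        dt = field.time.mean_interval / 10.0
    if dt <= 0:
        raise ParameterError(f"dt must be positive, got {dt}")

    ft = field.time.times
    t_min = float(rel.min())
    store = np.unique(
        np.concatenate([ft[(ft >= t_min) & (ft <= t_end)], np.unique(rel), [t_end]])
    )
    nt = store.size
    positions = np.full((nt, n, 3), np.nan)
    active = np.zeros((nt, n), dtype=bool)
    ever_left = np.zeros(n, dtype=bool)

    nmax = np.asarray(field.grid.shape, dtype=float) - 1.0

    def inside(p):
        idx = field.grid.world_to_voxel(p)
        return np.all((idx >= 0) & (idx <= nmax), axis=1)

    def vel_mm(p, t):
        v, _ = sample_velocity(field, p, t)
        return v * 1000.0

    for t_r in np.unique(rel):
        gidx = np.flatnonzero(rel == t_r)
        p = seeds[gidx].copy()
        alive = inside(p)
        ever_left[gidx[~alive]] = True
        k_start = int(np.searchsorted(store, t_r))
        positions[k_start, gidx] = p
        active[k_start, gidx] = alive
        for k in range(k_start, nt - 1):
            ta, tb = store[k], store[k + 1]
            nstep = max(1, int(np.ceil((tb - ta) / dt - 1e-12)))
            h = (tb - ta) / nstep
            live = np.flatnonzero(alive)  # group-local indices
            q = p[live]
            t = ta
            for _ in range(nstep):
                k1 = vel_mm(q, t)
                k2 = vel_mm(q + 0.5 * h * k1, t + 0.5 * h)
                k3 = vel_mm(q + 0.5 * h * k2, t + 0.5 * h)
                k4 = vel_mm(q + h * k3, t + h)
                q_new = q + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                left = ~inside(q_new)
                q_new[left] = q[left]  # freeze at last inside position
                p[live] = q_new
                if left.any():
                    alive[live[left]] = False
                    ever_left[gidx[live[left]]] = True
                    live = live[~left]
                    q = q_new[~left]
                else:
                    q = q_new
                t += h
            positions[k + 1, gidx] = p
            active[k + 1, gidx] = alive

    release_inside = None
    if f is not None:
        release_inside = np.asarray(f(seeds) <= 0.0)
    return ParticleSet(
        release_positions=seeds,
        release_times=rel,
        times=store,
        positions=positions,
        active=active,
        ever_left=ever_left,
        release_inside=release_inside,
    )
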