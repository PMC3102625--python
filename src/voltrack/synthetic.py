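"""Analytic, time-resolved velocity fields with known flow maps.

These fields stand in for non-deposited in-vivo 4D phase-contrast data.  The
analytic kinds (uniform, rotation, shear, Lamb-Oseen vortex) admit closed-form
material transport and serve as oracles for the flow-map solver and the
pathline integrator.  The ``pulsatile_vortex_phantom`` emulates diastolic
left-ventricular inflow: a biphasic (E/A-wave) jet through a transvalvular
plane that rolls up into a toroidal recirculation inside a chamber.  The
phantom velocity is the *discrete curl* (central differences) of a sampled
vector potential, so its central-difference divergence vanishes to rounding
error -- exact incompressibility at the discrete level, which the
volume-conservation tests rely on.

A measurement-chain simulator corrupts the truth field in the fixed order
truth -> + first-order polynomial background offset -> wrap at VENC ->
+ Gaussian noise, mirroring eddy-current offsets, phase aliasing and thermal
noise of phase-contrast velocity mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import GeometryError, ParameterError
from .field import GridGeometry, TimeAxis, VelocityField

__all__ = [
    "Corruption",
    "SyntheticFlowSpec",
    "generate_field",
    "oracle_position",
    "discrete_divergence",
    "default_phantom_spec",
]

_ANALYTIC_KINDS = ("uniform", "rotation", "shear", "lamb_oseen")
_KINDS = _ANALYTIC_KINDS + ("pulsatile_vortex_phantom",)


@dataclass
class Corruption:
    """Measurement-chain parameters.

    background: per-component first-order polynomial coefficients, shape
    (3, 4) = (c0 [m/s], cx, cy, cz [m/s per mm]), applied to every frame.
    wrap: alias velocities into (-venc, venc] modulo 2*venc.
    noise_sigma: additive white Gaussian noise SD in m/s.
    """

    background: np.ndarray | None = None
    wrap: bool = False
    noise_sigma: float = 0.0
    seed: int = 0


@dataclass
class SyntheticFlowSpec:
    """Recipe for one synthetic dataset: flow kind + params + grid/time."""

    kind: str
    params: dict
    grid: GridGeometry
    time: TimeAxis
    venc: float = 1.0
    corruption: Corruption = dc_field(default_factory=Corruption)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown flow kind {self.kind!r}; expected one of {_KINDS}")

    @property
    def oracle_available(self) -> bool:
        return self.kind in _ANALYTIC_KINDS


# ----------------------------------------------------------------------------
# Analytic velocity fields (world mm coordinates, m/s output)
# ----------------------------------------------------------------------------


def _velocity_analytic(spec: SyntheticFlowSpec, xyz: np.ndarray, t: float) -> np.ndarray:
    """Velocity (3, ...) in m/s at world points ``xyz`` of shape (3, ...)."""
    p = spec.params
    x, y, z = xyz
    if spec.kind == "uniform":
        c = np.asarray(p["velocity"], dtype=float)  # m/s
        return np.stack([np.full_like(x, c[0]), np.full_like(x, c[1]), np.full_like(x, c[2])])
    if spec.kind == "rotation":
        # rigid rotation about a z-parallel axis through `center`; omega rad/s
        omega = float(p["omega"])
        cx, cy = np.asarray(p["center"], dtype=float)[:2]
        # u = omega x r, r in mm -> mm/s -> m/s
        ux = -omega * (y - cy) / 1000.0
        uy = omega * (x - cx) / 1000.0
        return np.stack([ux, uy, np.zeros_like(x)])
    if spec.kind == "shear":
        # u_x = rate * (y - cy), rate in 1/s, y in mm -> m/s
        rate = float(p["rate"])
        cy = float(p.get("center_y", 0.0))
        return np.stack([rate * (y - cy) / 1000.0, np.zeros_like(x), np.zeros_like(x)])
    if spec.kind == "lamb_oseen":
        return _lamb_oseen_velocity(p, x, y, t)
    raise ParameterError(f"no closed-form velocity for kind {spec.kind!r}")


def _lamb_oseen_core2(p, t: float) -> float:
    r0 = float(p.get("core_radius", 5.0))  # mm
    nu = float(p.get("nu", 0.0))  # mm^2/s
    return r0 * r0 + 4.0 * nu * t


def _lamb_oseen_velocity(p, x, y, t):
    """Azimuthal Lamb-Oseen vortex about a z-parallel axis; m/s output."""
    gamma = float(p["circulation"])  # mm^2/s
    cx, cy = np.asarray(p["center"], dtype=float)[:2]
    dx, dy = x - cx, y - cy
    r2 = dx * dx + dy * dy
    rc2 = _lamb_oseen_core2(p, t)
    with np.errstate(divide="ignore", invalid="ignore"):
        # u_theta / r, finite at r = 0 (-> gamma/(2 pi rc^2))
        fac = gamma / (2.0 * np.pi) * np.where(
            r2 > 1e-30, (1.0 - np.exp(-r2 / rc2)) / np.where(r2 > 1e-30, r2, 1.0), 1.0 / rc2
        )
    return np.stack([-fac * dy / 1000.0, fac * dx / 1000.0, np.zeros_like(x)])


# ----------------------------------------------------------------------------
# Pulsatile vortex phantom
# ----------------------------------------------------------------------------


def _phantom_geometry(spec: SyntheticFlowSpec) -> dict:
    """Resolve phantom geometry (mm) from fractional parameters."""
    p = spec.params
    g = spec.grid
    ext = np.asarray(g.shape) * g.spacing  # physical extent per axis, mm
    Lz = ext[2]
    cx = g.origin[0] + (g.shape[0] - 1) * g.spacing[0] / 2.0
    cy = g.origin[1] + (g.shape[1] - 1) * g.spacing[1] / 2.0
    z0 = g.origin[2]
    geom = {
        "center_xy": (cx, cy),
        "R": float(p.get("core_radius_frac", 0.18)) * Lz,  # jet core scale, mm
        "z_lo": z0 + float(p.get("z_lo_frac", 0.08)) * Lz,
        "z_hi": z0 + float(p.get("z_hi_frac", 0.92)) * Lz,
        "z_valve": z0 + float(p.get("valve_frac", 0.62)) * Lz,
        "Lz": Lz,
        "z0": z0,
    }
    if geom["R"] <= 0 or geom["z_hi"] <= geom["z_lo"]:
        raise GeometryError("phantom geometry does not fit the grid")
    if not (geom["z_lo"] < geom["z_valve"] < geom["z_hi"]):
        raise GeometryError("valve plane must lie inside the active flow region")
    return geom


def _phantom_waveform(spec: SyntheticFlowSpec, t) -> np.ndarray:
    """Dimensionless biphasic diastolic waveform a(t); peak ~1 at the E wave."""
    p = spec.params
    t = np.asarray(t, dtype=float)
    tE = float(p.get("e_time", 0.40))
    tA = float(p.get("a_time", 0.90))
    sE = float(p.get("e_width", 0.055))
    sA = float(p.get("a_width", 0.045))
    rA = float(p.get("a_rel_amplitude", 0.5))
    t_open = float(p.get("open_time", 0.30))
    ramp = float(p.get("open_ramp", 0.06))
    s = np.clip((t - t_open) / ramp, 0.0, 1.0)
    gate = s * s * (3.0 - 2.0 * s)  # smoothstep valve opening
    return gate * (np.exp(-0.5 * ((t - tE) / sE) ** 2) + rA * np.exp(-0.5 * ((t - tA) / sA) ** 2))


def _phantom_s(spec, r, z, geom):
    """Scalar profile s(r, z): A_phi = r * s; Gaussian core x smooth z-bump."""
    R = geom["R"]
    z_lo, z_hi = geom["z_lo"], geom["z_hi"]
    w = np.where(
        (z > z_lo) & (z < z_hi),
        np.sin(np.pi * np.clip((z - z_lo) / (z_hi - z_lo), 0.0, 1.0)) ** 2,
        0.0,
    )
    return np.exp(-0.5 * (r / R) ** 2) * w


def _phantom_unit_curl(spec: SyntheticFlowSpec, geom: dict) -> np.ndarray:
    """Discrete curl (central differences) of the unit-amplitude potential.

    Returns (3, nx, ny, nz) in potential units per mm; multiplying by the
    calibrated amplitude and a(t) yields mm/s.
    """
    g = spec.grid
    nx, ny, nz = g.shape
    # sample the potential on a one-voxel-padded lattice so central
    # differences are valid at every grid voxel
    ii = np.arange(-1, nx + 1, dtype=float)
    jj = np.arange(-1, ny + 1, dtype=float)
    kk = np.arange(-1, nz + 1, dtype=float)
    X = g.origin[0] + ii * g.spacing[0]
    Y = g.origin[1] + jj * g.spacing[1]
    Z = g.origin[2] + kk * g.spacing[2]
    x, y, z = np.meshgrid(X, Y, Z, indexing="ij")
    cx, cy = geom["center_xy"]
    r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    s = _phantom_s(spec, r, z, geom)
    Ax = -(y - cy) * s
    Ay = (x - cx) * s
    dx, dy, dz = g.spacing

    def d(arr, axis, h):
        return (np.roll(arr, -1, axis) - np.roll(arr, 1, axis)) / (2.0 * h)

    # u = curl(A) with A = (Ax, Ay, 0)
    ux = -d(Ay, 2, dz)
    uy = d(Ax, 2, dz)
    uz = d(Ay, 0, dx) - d(Ax, 1, dy)
    core = (slice(1, -1),) * 3
    return np.stack([ux[core], uy[core], uz[core]])


def _phantom_analytic_scales(spec: SyntheticFlowSpec, geom: dict) -> dict:
    """Closed-form peak speed and valve-plane flux of the unit potential.

    With A_phi = r s(r, z):  u_z = s (2 - r^2/R^2),  u_r = -r ds/dz, and the
    flux through a disc of radius b in the plane z is 2 pi b^2 s(b, z).
    Evaluated on a fine (r, z) lattice; grid-independent, used to calibrate
    the velocity amplitude and to report ground-truth peak flows.
    """
    R = geom["R"]
    z_lo, z_hi = geom["z_lo"], geom["z_hi"]
    r = np.linspace(1e-6, 4 * R, 600)
    z = np.linspace(z_lo, z_hi, 600)
    rr, zz = np.meshgrid(r, z, indexing="ij")
    s = _phantom_s(spec, rr, zz, geom)
    uz = s * (2.0 - (rr / R) ** 2)
    dz = z[1] - z[0]
    dsdz = np.gradient(s, dz, axis=1)
    ur = -rr * dsdz
    umax = float(np.max(np.sqrt(uz**2 + ur**2)))
    b = np.sqrt(2.0) * R  # radius of maximum cumulative flux
    s_b = _phantom_s(spec, np.array(b), np.array(geom["z_valve"]), geom)
    flux_unit = float(2.0 * np.pi * b * b * s_b)  # mm^3/s per unit amplitude per mm/s... (units folded below)
    return {"umax_unit": umax, "flux_unit": flux_unit, "flux_radius": b}


def _phantom_meta(spec: SyntheticFlowSpec) -> dict:
    geom = _phantom_geometry(spec)
    scales = _phantom_analytic_scales(spec, geom)
    p = spec.params
    e_speed = float(p.get("e_peak_speed", 0.6))  # m/s
    # negative amplitude: the core jet points toward the apex (-z)
    amp = -e_speed * 1000.0 / scales["umax_unit"]  # mm/s per unit potential
    times = spec.time.times
    a = _phantom_waveform(spec, times)
    # inflow onset: first frame with meaningful inflow
    on = times[a > 0.02]
    t0_inflow = float(on[0]) if on.size else float(times[0])
    cx, cy = geom["center_xy"]
    # ground-truth peak flows on the frame grid (what a frame-sampled curve sees)
    q_frames = _phantom_waveform(spec, times) * abs(amp) * scales["flux_unit"] / 1000.0  # mL/s
    tE, tA = float(p.get("e_time", 0.40)), float(p.get("a_time", 0.90))
    mid = 0.5 * (tE + tA)
    qE = float(np.max(q_frames[times <= mid])) if np.any(times <= mid) else 0.0
    qA = float(np.max(q_frames[times > mid])) if np.any(times > mid) else 0.0
    R = geom["R"]
    Lz = geom["Lz"]
    return {
        "geometry": geom,
        "amplitude_mm_per_s": amp,
        "t0_inflow": t0_inflow,
        "valve_plane": {"point": (cx, cy, geom["z_valve"]), "normal": (0.0, 0.0, -1.0)},
        "flow_disc_radius": scales["flux_radius"],
        "peak_flows_mL_s": {"E": qE, "A": qA},
        "ea_times": {"E": tE, "A": tA},
        "seed_region": {
            "kind": "cylinder",
            "center": (cx, cy, geom["z_valve"] + 0.11 * Lz),
            "radius": 0.8 * R,
            "half_height": 0.05 * Lz,
        },
        "landmarks": {
            "apex": (cx, cy, geom["z_lo"]),
            "base_center": (cx, cy, geom["z_valve"]),
            "septal_ref": (1.0, 0.0, 0.0),
        },
        "lumen": {"radius": 2.0 * R, "z_range": (geom["z_lo"], geom["z_valve"])},
    }


def phantom_lumen_mask(spec: SyntheticFlowSpec, meta: dict | None = None) -> np.ndarray:
    """Cylindrical chamber-lumen mask (apex-to-valve) for segment analysis."""
    meta = meta if meta is not None else _phantom_meta(spec)
    g = spec.grid
    xyz = g.voxel_centers()
    cx, cy = meta["geometry"]["center_xy"]
    r = np.sqrt((xyz[0] - cx) ** 2 + (xyz[1] - cy) ** 2)
    zlo, zhi = meta["lumen"]["z_range"]
    return (r <= meta["lumen"]["radius"]) & (xyz[2] >= zlo) & (xyz[2] <= zhi)


# ----------------------------------------------------------------------------
# Field generation and measurement chain
# ----------------------------------------------------------------------------


def generate_field(spec: SyntheticFlowSpec):
    """Sample the truth field and apply the measurement chain.

    Returns ``(corrupted, truth, meta)``: two :class:`VelocityField` objects
    on the spec's grid/time axis and a metadata dict with the ground truth of
    the corruption (background coefficients, wrapped-voxel mask, noise seed)
    plus phantom geometry when applicable.
    """
    g = spec.grid
    nt = spec.time.n_frames
    data = np.empty((nt, 3) + g.shape, dtype=np.float64)
    meta: dict = {"kind": spec.kind}
    if spec.kind == "pulsatile_vortex_phantom":
        pm = _phantom_meta(spec)
        meta.update(pm)
        geom = pm["geometry"]
        u_unit = _phantom_unit_curl(spec, geom)  # potential units / mm
        a = _phantom_waveform(spec, spec.time.times)
        for k in range(nt):
            data[k] = u_unit * (pm["amplitude_mm_per_s"] * a[k] / 1000.0)  # m/s
    else:
        xyz = g.voxel_centers()
        for k, t in enumerate(spec.time.times):
            data[k] = _velocity_analytic(spec, xyz, float(t))
    truth = VelocityField(grid=g, time=spec.time, data=data, venc=spec.venc)

    corr = spec.corruption
    out = truth.data.copy()
    rng = np.random.default_rng(corr.seed)
    if corr.background is not None:
        bg = np.asarray(corr.background, dtype=float).reshape(3, 4)
        xyz = g.voxel_centers()
        offset = (
            bg[:, 0][:, None, None, None]
            + bg[:, 1][:, None, None, None] * xyz[0]
            + bg[:, 2][:, None, None, None] * xyz[1]
            + bg[:, 3][:, None, None, None] * xyz[2]
        )
        out = out + offset[None]
        meta["background"] = bg
    else:
        meta["background"] = np.zeros((3, 4))
    if corr.wrap:
        venc = spec.venc
        wrapped = np.mod(out + venc, 2.0 * venc) - venc
        meta["wrapped_mask"] = ~np.isclose(wrapped, out)
        out = wrapped
    else:
        meta["wrapped_mask"] = np.zeros_like(out, dtype=bool)
    if corr.noise_sigma > 0:
        out = out + rng.normal(0.0, corr.noise_sigma, size=out.shape)
    meta["noise_sigma"] = corr.noise_sigma
    meta["noise_seed"] = corr.seed
    corrupted = VelocityField(grid=g, time=spec.time, data=out, venc=spec.venc)
    return corrupted, truth, meta


def discrete_divergence(field: VelocityField, frame: int = 0) -> np.ndarray:
    """Central-difference divergence of one frame, 1/s, interior voxels.

    Returns an array of shape (nx-2, ny-2, nz-2).
    """
    u = field.frame(frame) * 1000.0  # mm/s
    sp = field.grid.spacing
    c = (slice(1, -1),) * 3

    def d(arr, axis, h):
        sl_p = [slice(1, -1)] * 3
        sl_m = [slice(1, -1)] * 3
        sl_p[axis] = slice(2, None)
        sl_m[axis] = slice(0, -2)
        return (arr[tuple(sl_p)] - arr[tuple(sl_m)]) / (2.0 * h)

    return d(u[0], 0, sp[0]) + d(u[1], 1, sp[1]) + d(u[2], 2, sp[2])


# ----------------------------------------------------------------------------
# Closed-form transport oracles
# ----------------------------------------------------------------------------


def oracle_position(spec: SyntheticFlowSpec, x0, t_from: float, t_to: float) -> np.ndarray:
    """Exact position at ``t_to`` of the material point at ``x0`` at ``t_from``.

    Closed forms exist for uniform, rotation, shear and lamb_oseen; for the
    phantom use a fine-step reference integration instead.  ``x0`` may be a
    single point (3,) or an array (..., 3); mm in, mm out.
    """
    if not spec.oracle_available:
        raise ParameterError(
            f"kind {spec.kind!r} has no closed-form flow map; "
            "use a high-accuracy particle trace as reference"
        )
    x0 = np.asarray(x0, dtype=float)
    single = x0.ndim == 1
    pts = np.atleast_2d(x0)
    dt = t_to - t_from
    p = spec.params
    if spec.kind == "uniform":
        c = np.asarray(p["velocity"], dtype=float) * 1000.0  # mm/s
        out = pts + c * dt
    elif spec.kind == "rotation":
        omega = float(p["omega"])
        cx, cy = np.asarray(p["center"], dtype=float)[:2]
        ang = omega * dt
        ca, sa = np.cos(ang), np.sin(ang)
        dx, dy = pts[:, 0] - cx, pts[:, 1] - cy
        out = np.stack(
            [cx + ca * dx - sa * dy, cy + sa * dx + ca * dy, pts[:, 2]], axis=1
        )
    elif spec.kind == "shear":
        rate = float(p["rate"])
        cy = float(p.get("center_y", 0.0))
        out = pts.copy()
        out[:, 0] = pts[:, 0] + rate * (pts[:, 1] - cy) * dt
    elif spec.kind == "lamb_oseen":
        out = _lamb_oseen_transport(p, pts, t_from, t_to)
    if single:
        return out[0]
    return out


def _lamb_oseen_transport(p, pts, t_from, t_to):
    """Radius-preserving azimuthal transport; angle by 1-D time quadrature."""
    gamma = float(p["circulation"])
    cx, cy = np.asarray(p["center"], dtype=float)[:2]
    dx, dy = pts[:, 0] - cx, pts[:, 1] - cy
    r2 = dx * dx + dy * dy

    def angular_rate(t, _y):
        rc2 = _lamb_oseen_core2(p, t)
        with np.errstate(divide="ignore", invalid="ignore"):
            om = gamma / (2.0 * np.pi) * np.where(
                r2 > 1e-30, (1.0 - np.exp(-r2 / rc2)) / np.where(r2 > 1e-30, r2, 1.0), 1.0 / rc2
            )
        return om

    sol = solve_ivp(
        angular_rate,
        (t_from, t_to),
        np.zeros(pts.shape[0]),
        rtol=1e-11,
        atol=1e-12,
        dense_output=False,
    )
    dtheta = sol.y[:, -1]
    ca, sa = np.cos(dtheta), np.sin(dtheta)
    out = pts.copy()
    out[:, 0] = cx + ca * dx - sa * dy
    out[:, 1] = cy + sa * dx + ca * dy
    return out


# ----------------------------------------------------------------------------
# Convenience constructors
# ----------------------------------------------------------------------------


def default_phantom_spec(
    n: int = 32,
    n_frames: int = 25,
    cycle: float = 1.0,
    spacing: float | None = None,
    venc: float = 1.0,
    noise_sigma: float = 0.0,
    wrap: bool = False,
    e_peak_speed: float = 0.6,
    seed: int = 0,
    background=None,
) -> SyntheticFlowSpec:
    """Study-condition phantom: 32^3 grid of 3 mm voxels (96 mm chamber),
    25 frames over a 1.0 s cycle (40 ms temporal resolution), VENC 1.0 m/s,
    E peak at 0.40 s (0.6 m/s), A peak at 0.90 s at half amplitude.

    ``spacing`` defaults to 96/n mm so the physical chamber is grid-size
    independent (refinement refines, not enlarges).
    """
    if spacing is None:
        spacing = 96.0 / n
    grid = GridGeometry(shape=(n, n, n), spacing=(spacing,) * 3)
    times = TimeAxis(times=np.arange(n_frames) * (cycle / n_frames), cyclic=True)
    return SyntheticFlowSpec(
        kind="pulsatile_vortex_phantom",
        params={"e_peak_speed": e_peak_speed},
        grid=grid,
        time=times,
        venc=venc,
        corruption=Corruption(
            background=background, wrap=wrap, noise_sigma=noise_sigma, seed=seed
        ),
    )
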