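"""Velocity-field data model and on-disk formats.

Conventions used throughout the package:

* Voxel arrays are indexed ``[ix, iy, iz]`` (axis 0 of the spatial block is the
  first voxel axis).  Velocity data is stored as one array of shape
  ``(n_frames, 3, nx, ny, nz)``; the component axis holds physical
  *world-axis* velocity components in m/s.
* World coordinates are in millimetres, voxel-centre convention: the centre of
  voxel ``i`` sits at ``origin + axes @ (i * spacing)``.
* Time is in seconds, ``t = 0`` at the start of systole for cardiac data.
* Unit conversions (m/s -> mm/s) happen inside integrators, never in storage.

Supported formats: a self-describing HDF5 or NPZ container (one file), or
three single-component 4D NIfTI files plus a JSON sidecar carrying frame
times and the velocity-encoding limit (VENC).  The NIfTI affine is the single
source of geometry; the container stores the affine redundantly and loading
verifies its consistency with spacing/origin/axes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .errors import DataValidationError, FormatError, MetadataError

__all__ = [
    "GridGeometry",
    "TimeAxis",
    "VelocityField",
    "load_velocity",
    "save_velocity",
]


def _as_vec3(x, name):
    a = np.asarray(x, dtype=float).reshape(-1)
    if a.size != 3:
        raise DataValidationError(f"{name} must have 3 entries, got {a.size}")
    return a


@dataclass(frozen=True)
class GridGeometry:
    """Regular 3D grid: voxel counts, spacing (mm), world origin (mm), axes.

    ``axes`` is a 3x3 matrix whose *columns* are the world-space unit vectors
    of the voxel axes (orthonormal).  The world position of voxel index
    ``(i, j, k)`` is ``origin + axes @ ([i, j, k] * spacing)``.
    """

    shape: tuple
    spacing: np.ndarray
    origin: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = dc_field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise DataValidationError(f"grid shape must be 3 positive ints, got {self.shape}")
        object.__setattr__(self, "spacing", _as_vec3(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _as_vec3(self.origin, "origin"))
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        object.__setattr__(self, "axes", axes)
        if np.any(self.spacing <= 0):
            raise DataValidationError(f"spacing must be positive, got {self.spacing}")
        if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-9):
            raise DataValidationError("axes columns must be orthonormal")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (NIfTI style, voxel centres)."""
        A = np.eye(4)
        A[:3, :3] = self.axes @ np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    def voxel_to_world(self, idx) -> np.ndarray:
        """Map (fractional) voxel indices, shape (..., 3), to world mm."""
        idx = np.asarray(idx, dtype=float)
        return (idx * self.spacing) @ self.axes.T + self.origin

    def world_to_voxel(self, x) -> np.ndarray:
        """Map world-mm points, shape (..., 3), to fractional voxel indices."""
        x = np.asarray(x, dtype=float)
        return ((x - self.origin) @ self.axes) / self.spacing

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centres, shape (3, nx, ny, nz), mm."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n, dtype=float) for n in self.shape], indexing="ij"),
            axis=-1,
        )
        return np.moveaxis(self.voxel_to_world(idx), -1, 0)

    @classmethod
    def from_affine(cls, affine, shape) -> "GridGeometry":
        A = np.asarray(affine, dtype=float)
        M = A[:3, :3]
        spacing = np.linalg.norm(M, axis=0)
        axes = M / spacing
        return cls(shape=tuple(shape), spacing=spacing, origin=A[:3, 3], axes=axes)


@dataclass(frozen=True)
class TimeAxis:
    """Strictly increasing frame times in seconds; optionally cyclic.

    For retrospectively gated cardiac data covering one R-R interval the
    sequence wraps; the period is ``times[-1] - times[0] + mean frame
    interval`` (the gap from the last frame back to the first).
    """

    times: np.ndarray
    cyclic: bool = False

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).reshape(-1)
        object.__setattr__(self, "times", t)
        if t.size < 2:
            raise DataValidationError("time axis needs at least 2 frames")
        if np.any(np.diff(t) <= 0):
            raise DataValidationError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def mean_interval(self) -> float:
        return float(np.mean(np.diff(self.times)))

    @property
    def period(self) -> float:
        """Cycle duration (s); only meaningful when cyclic."""
        return float(self.times[-1] - self.times[0] + self.mean_interval)


@dataclass
class VelocityField:
    """A measured or synthetic 3D+t, three-component velocity field.

    ``data`` has shape ``(n_frames, 3, nx, ny, nz)`` in m/s, world-axis
    aligned components.  ``venc`` is the velocity-encoding limit in m/s:
    measured values alias modulo ``2*venc``.  ``mask`` (optional) marks the
    imaged blood/tissue region.
    """

    grid: GridGeometry
    time: TimeAxis
    data: np.ndarray
    venc: float
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = (self.time.n_frames, 3) + self.grid.shape
        if self.data.shape != expected:
            raise DataValidationError(
                f"velocity data shape {self.data.shape} != expected {expected}"
            )
        if not (np.isscalar(self.venc) or np.ndim(self.venc) == 0) or not self.venc > 0:
            raise MetadataError(f"venc must be a positive scalar, got {self.venc!r}")
        self.venc = float(self.venc)
        bad = ~np.isfinite(self.data)
        if bad.any():
            first = tuple(int(i) for i in np.argwhere(bad)[0])
            raise DataValidationError(
                f"non-finite velocity at (frame, component, ix, iy, iz) = {first}"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.grid.shape:
                raise DataValidationError(
                    f"mask shape {self.mask.shape} != grid shape {self.grid.shape}"
                )

    @property
    def n_frames(self) -> int:
        return self.time.n_frames

    def frame(self, k: int) -> np.ndarray:
        """Velocity components of frame ``k``, shape (3, nx, ny, nz), m/s."""
        return self.data[k]

    def speed(self) -> np.ndarray:
        """Speed per frame, shape (n_frames, nx, ny, nz), m/s."""
        return np.sqrt(np.sum(self.data**2, axis=1))

    def copy_with(self, data=None) -> "VelocityField":
        return VelocityField(
            grid=self.grid,
            time=self.time,
            data=self.data.copy() if data is None else data,
            venc=self.venc,
            mask=None if self.mask is None else self.mask.copy(),
        )


# ----------------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------------

_COMPONENT_SUFFIXES = ("vx", "vy", "vz")


def save_velocity(field: VelocityField, path, format: str = "container", dtype=np.float64):
    """Write a velocity field to disk; lossless round trip at stored precision.

    format='container': single HDF5 file (datasets /vx,/vy,/vz,/times,/venc,
    /spacing,/origin,/axes,/affine[, /mask]).  format='npz': same keys in one
    NumPy archive.  format='nifti': three 4D NIfTI files ``<base>_vx.nii.gz``
    etc. with identical affines plus a ``<base>.json`` sidecar (times, venc).
    Returns the primary path written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "container":
        with h5py.File(path, "w") as h5:
            for c, name in enumerate(_COMPONENT_SUFFIXES):
                h5.create_dataset(name, data=field.data[:, c].astype(dtype))
            h5.create_dataset("times", data=field.time.times)
            h5.create_dataset("venc", data=field.venc)
            h5.create_dataset("spacing", data=field.grid.spacing)
            h5.create_dataset("origin", data=field.grid.origin)
            h5.create_dataset("axes", data=field.grid.axes)
            h5.create_dataset("affine", data=field.grid.affine)
            h5.attrs["cyclic"] = bool(field.time.cyclic)
            if field.mask is not None:
                h5.create_dataset("mask", data=field.mask.astype(np.uint8))
        return path
    if format == "npz":
        payload = {
            name: field.data[:, c].astype(dtype)
            for c, name in enumerate(_COMPONENT_SUFFIXES)
        }
        payload.update(
            times=field.time.times,
            venc=np.float64(field.venc),
            spacing=field.grid.spacing,
            origin=field.grid.origin,
            axes=field.grid.axes,
            affine=field.grid.affine,
            cyclic=np.bool_(field.time.cyclic),
        )
        if field.mask is not None:
            payload["mask"] = field.mask.astype(np.uint8)
        np.savez(path, **payload)
        return path
    if format == "nifti":
        base = _nifti_base(path)
        affine = field.grid.affine
        for c, name in enumerate(_COMPONENT_SUFFIXES):
            vol = np.moveaxis(field.data[:, c].astype(dtype), 0, -1)  # (nx,ny,nz,nt)
            img = nib.Nifti1Image(vol, affine)
            nib.save(img, f"{base}_{name}.nii.gz")
        if field.mask is not None:
            nib.save(nib.Nifti1Image(field.mask.astype(np.uint8), affine), f"{base}_mask.nii.gz")
        sidecar = {
            "times": field.time.times.tolist(),
            "venc": field.venc,
            "cyclic": bool(field.time.cyclic),
        }
        Path(f"{base}.json").write_text(json.dumps(sidecar, indent=1))
        return Path(f"{base}_vx.nii.gz")
    raise FormatError(f"unknown format {format!r} (expected container|npz|nifti)")


def _nifti_base(path) -> str:
    s = str(path)
    for suf in (".nii.gz", ".nii"):
        if s.endswith(suf):
            return s[: -len(suf)]
    return s


def load_velocity(source, times=None, venc=None, cyclic=None, mask=None) -> "VelocityField":
    """Read a velocity field written by :func:`save_velocity`.

    ``source`` is a container path (.h5/.hdf5/.npz), a NIfTI base path, or a
    sequence of three single-component NIfTI paths.  ``times``/``venc``
    override (or supply, for NIfTI without sidecar) the metadata.
    """
    if isinstance(source, (list, tuple)):
        return _load_nifti(list(source), times, venc, cyclic, mask)
    p = Path(source)
    s = str(p)
    if s.endswith((".h5", ".hdf5")):
        return _load_h5(p, times, venc, cyclic)
    if s.endswith(".npz"):
        return _load_npz(p, times, venc, cyclic)
    # NIfTI base or single component file
    base = _nifti_base(s)
    for b in (base, base.rsplit("_", 1)[0]):
        paths = [f"{b}_{c}.nii.gz" for c in _COMPONENT_SUFFIXES]
        if all(os.path.exists(q) for q in paths):
            return _load_nifti(paths, times, venc, cyclic, mask)
        paths = [f"{b}_{c}.nii" for c in _COMPONENT_SUFFIXES]
        if all(os.path.exists(q) for q in paths):
            return _load_nifti(paths, times, venc, cyclic, mask)
    raise FormatError(f"cannot locate a velocity dataset at {source!r}")


def _finish(grid, times, cyclic, data, venc, mask):
    if times is None:
        raise MetadataError("frame times missing: supply times= or a sidecar/container")
    if venc is None:
        raise MetadataError("venc missing: supply venc= or a sidecar/container")
    taxis = TimeAxis(times=np.asarray(times, dtype=float), cyclic=bool(cyclic))
    return VelocityField(grid=grid, time=taxis, data=data, venc=float(venc), mask=mask)


def _load_h5(path, times, venc, cyclic):
    with h5py.File(path, "r") as h5:
        comps = [np.asarray(h5[name], dtype=np.float64) for name in _COMPONENT_SUFFIXES]
        if not (comps[0].shape == comps[1].shape == comps[2].shape):
            raise FormatError(
                f"component shapes differ: {[c.shape for c in comps]}"
            )
        grid = GridGeometry(
            shape=comps[0].shape[1:],
            spacing=np.asarray(h5["spacing"]),
            origin=np.asarray(h5["origin"]),
            axes=np.asarray(h5["axes"]),
        )
        if "affine" in h5 and not np.allclose(np.asarray(h5["affine"]), grid.affine, atol=1e-6):
            raise FormatError("container affine inconsistent with spacing/origin/axes")
        t = np.asarray(h5["times"]) if times is None else times
        v = float(np.asarray(h5["venc"])) if venc is None else venc
        cyc = bool(h5.attrs.get("cyclic", False)) if cyclic is None else cyclic
        msk = np.asarray(h5["mask"]).astype(bool) if "mask" in h5 else None
    data = np.stack(comps, axis=1)
    return _finish(grid, t, cyc, data, v, msk)


def _load_npz(path, times, venc, cyclic):
    with np.load(path) as z:
        comps = [np.asarray(z[name], dtype=np.float64) for name in _COMPONENT_SUFFIXES]
        if not (comps[0].shape == comps[1].shape == comps[2].shape):
            raise FormatError(f"component shapes differ: {[c.shape for c in comps]}")
        grid = GridGeometry(
            shape=comps[0].shape[1:], spacing=z["spacing"], origin=z["origin"], axes=z["axes"]
        )
        if "affine" in z and not np.allclose(z["affine"], grid.affine, atol=1e-6):
            raise FormatError("container affine inconsistent with spacing/origin/axes")
        t = z["times"] if times is None else times
        v = float(z["venc"]) if venc is None else venc
        cyc = bool(z["cyclic"]) if cyclic is None and "cyclic" in z else bool(cyclic or False)
        msk = z["mask"].astype(bool) if "mask" in z else None
    data = np.stack(comps, axis=1)
    return _finish(grid, t, cyc, data, v, msk)


def _load_nifti(paths, times, venc, cyclic, mask):
    if len(paths) != 3:
        raise FormatError(f"expected 3 component NIfTI files, got {len(paths)}")
    imgs = [nib.as_closest_canonical(nib.load(p)) for p in paths]
    shapes = [img.shape for img in imgs]
    if len(set(shapes)) != 1:
        raise FormatError(f"component shapes differ: {shapes}")
    aff0 = imgs[0].affine
    for img, p in zip(imgs[1:], paths[1:]):
        if not np.allclose(img.affine, aff0, atol=1e-6):
            raise FormatError(f"component affine of {p} differs from first component")
    vols = [np.asarray(img.get_fdata(), dtype=np.float64) for img in imgs]
    if vols[0].ndim == 3:
        vols = [v[..., None] for v in vols]
    if vols[0].ndim != 4:
        raise FormatError(f"expected 4D component volumes, got ndim={vols[0].ndim}")
    data = np.stack([np.moveaxis(v, -1, 0) for v in vols], axis=1)  # (nt,3,nx,ny,nz)
    grid = GridGeometry.from_affine(aff0, vols[0].shape[:3])
    if times is None or venc is None:
        sidecar = Path(_nifti_base(paths[0]).rsplit("_", 1)[0] + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            times = meta.get("times") if times is None else times
            venc = meta.get("venc") if venc is None else venc
            cyclic = meta.get("cyclic", False) if cyclic is None else cyclic
    msk = None
    if mask is not None:
        msk = np.asarray(nib.as_closest_canonical(nib.load(mask)).get_fdata()).astype(bool)
    return _finish(grid, times, bool(cyclic or False), data, venc, msk)
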