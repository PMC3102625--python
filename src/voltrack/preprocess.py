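"""Velocity corrections: polynomial background subtraction, phase unwrapping.

Phase-contrast velocity maps carry two characteristic artefacts.  Eddy
currents leave a slowly varying spurious velocity offset, modelled here (per
frame and per component) as a first-order polynomial v_bg(x) = c0 + cx*x +
cy*y + cz*z fitted by ordinary least squares over stationary-tissue voxels
and subtracted.  Velocities beyond the encoding limit alias modulo 2*VENC;
unwrapping shifts affected values by integer multiples of 2*VENC so the
result is temporally and spatially consistent while remaining congruent to
the input modulo 2*VENC at every voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataValidationError, DegenerateGeometryError, DiagnosticError
from .field import VelocityField

__all__ = [
    "BackgroundModel",
    "UnwrapReport",
    "detect_stationary",
    "fit_background",
    "subtract_background",
    "unwrap_velocity",
]


@dataclass
class BackgroundModel:
    """First-order background fit per frame and component.

    coefficients: shape (n_frames, 3, 4) = (c0 [m/s], cx, cy, cz [m/s/mm]);
    residual_rms: shape (n_frames, 3) in m/s over the stationary mask.
    """

    coefficients: np.ndarray
    stationary_mask: np.ndarray
    residual_rms: np.ndarray
    grid_shape: tuple
    pooled_time: bool = False

    def predict(self, grid) -> np.ndarray:
        """Background field (n_frames, 3, nx, ny, nz) in m/s on ``grid``."""
        xyz = grid.voxel_centers()
        c = self.coefficients  # (nt, 3, 4)
        return (
            c[:, :, 0, None, None, None]
            + c[:, :, 1, None, None, None] * xyz[0]
            + c[:, :, 2, None, None, None] * xyz[1]
            + c[:, :, 3, None, None, None] * xyz[2]
        )


def detect_stationary(field: VelocityField, threshold: float = 0.03) -> np.ndarray:
    """Heuristic stationary-tissue mask from temporal speed statistics.

    A voxel is stationary when both the temporal standard deviation and the
    temporal mean of its speed fall below ``threshold`` (m/s).  Restricted to
    ``field.mask`` when present.  Raises if no voxel qualifies.
    """
    if field.n_frames < 2:
        raise DataValidationError("stationary detection needs at least 2 frames")
    speed = field.speed()  # (nt, nx, ny, nz)
    mask = (speed.std(axis=0) < threshold) & (speed.mean(axis=0) < threshold)
    if field.mask is not None:
        mask &= field.mask
    if not mask.any():
        raise DiagnosticError(
            f"no stationary voxels at threshold {threshold} m/s; "
            "raise the threshold or supply a mask"
        )
    return mask


def _design_matrix(grid, mask):
    xyz = grid.voxel_centers()
    X = np.column_stack(
        [np.ones(int(mask.sum())), xyz[0][mask], xyz[1][mask], xyz[2][mask]]
    )
    return X


def fit_background(
    field: VelocityField, stationary_mask: np.ndarray, pool_time: bool = False
) -> BackgroundModel:
    """OLS fit of the first-order background over stationary voxels.

    Independent fits per frame and component by default (eddy-current
    offsets vary over the cycle); ``pool_time`` fits one polynomial per
    component on all frames jointly.
    """
    mask = np.asarray(stationary_mask).astype(bool)
    if mask.shape != field.grid.shape:
        raise DataValidationError(
            f"stationary mask shape {mask.shape} != grid shape {field.grid.shape}"
        )
    nvox = int(mask.sum())
    if nvox < 16:
        raise DegenerateGeometryError(
            f"need >= 16 stationary voxels for a stable fit, got {nvox}"
        )
    X = _design_matrix(field.grid, mask)
    if np.linalg.matrix_rank(X) < 4:
        raise DegenerateGeometryError(
            "stationary voxels are coplanar/collinear; background fit is rank-deficient"
        )
    nt = field.n_frames
    coeffs = np.empty((nt, 3, 4))
    rms = np.empty((nt, 3))
    if pool_time:
        for c in range(3):
            y = field.data[:, c][:, mask].ravel()
            Xp = np.tile(X, (nt, 1))
            beta, *_ = np.linalg.lstsq(Xp, y, rcond=None)
            coeffs[:, c] = beta
        for k in range(nt):
            for c in range(3):
                r = field.data[k, c][mask] - X @ coeffs[k, c]
                rms[k, c] = np.sqrt(np.mean(r**2))
    else:
        for k in range(nt):
            for c in range(3):
                y = field.data[k, c][mask]
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                coeffs[k, c] = beta
                r = y - X @ beta
                rms[k, c] = np.sqrt(np.mean(r**2))
    return BackgroundModel(
        coefficients=coeffs,
        stationary_mask=mask,
        residual_rms=rms,
        grid_shape=field.grid.shape,
        pooled_time=pool_time,
    )


def subtract_background(field: VelocityField, model: BackgroundModel) -> VelocityField:
    """Subtract the fitted background polynomial from every frame/component."""
    if tuple(model.grid_shape) != tuple(field.grid.shape):
        raise DataValidationError(
            f"background model grid {model.grid_shape} != field grid {field.grid.shape}"
        )
    bg = model.predict(field.grid)
    if bg.shape != field.data.shape:
        raise DataValidationError("background model frame count does not match field")
    return field.copy_with(data=field.data - bg)


@dataclass
class UnwrapReport:
    """Bookkeeping of the aliasing correction.

    ``shifts`` holds the integer wrap count k applied per value (the
    correction added was k * 2 * venc); n_corrected counts nonzero entries.
    """

    n_corrected: int
    shifts: np.ndarray
    n_spatial_iterations: int = 0


def unwrap_velocity(
    field: VelocityField, max_spatial_iter: int = 20
) -> tuple[VelocityField, UnwrapReport]:
    """Correct phase-aliasing wraps by integer multiples of 2*VENC.

    Two passes per component: (1) a temporal sweep starting from the frame
    of minimum global speed (assumed wrap-free), shifting each voxel so the
    frame-to-frame jump is below VENC; (2) an iterated spatial pass shifting
    voxels that differ from their 6-neighbour mean by more than VENC.  Double
    wraps are handled by the integer rounding in both rules.  The output is
    congruent to the input modulo 2*VENC at every voxel-frame-component.
    """
    v = field.data.copy()
    venc = field.venc
    two = 2.0 * venc
    nt = field.n_frames
    shifts = np.zeros_like(v, dtype=np.int16)

    if nt >= 2:
        k0 = int(np.argmin(np.sqrt((v**2).sum(axis=1)).mean(axis=(1, 2, 3))))
        for k in range(k0 + 1, nt):
            n = np.rint((v[k] - v[k - 1]) / two).astype(np.int16)
            v[k] -= two * n
            shifts[k] -= n
        for k in range(k0 - 1, -1, -1):
            n = np.rint((v[k] - v[k + 1]) / two).astype(np.int16)
            v[k] -= two * n
            shifts[k] -= n

    n_iter = 0
    for _ in range(max_spatial_iter):
        nb = _neighbor_mean(v)
        n = np.where(np.abs(v - nb) > venc, np.rint((v - nb) / two), 0.0).astype(np.int16)
        if not np.any(n):
            break
        v -= two * n
        shifts -= n
        n_iter += 1

    report = UnwrapReport(
        n_corrected=int(np.count_nonzero(shifts)),
        shifts=shifts,
        n_spatial_iterations=n_iter,
    )
    return field.copy_with(data=v), report


def _neighbor_mean(v: np.ndarray) -> np.ndarray:
    """Mean of the 6 spatial neighbours (edge-replicated) per voxel."""
    out = np.zeros_like(v)
    for axis in (2, 3, 4):
        pad = [(0, 0)] * v.ndim
        pad[axis] = (1, 1)
        p = np.pad(v, pad, mode="edge")
        sl_lo = [slice(None)] * v.ndim
        sl_hi = [slice(None)] * v.ndim
        sl_lo[axis] = slice(0, -2)
        sl_hi[axis] = slice(2, None)
        out += p[tuple(sl_lo)] + p[tuple(sl_hi)]
    return out / 6.0
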