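"""Spherical-conductor forward fields and equivalent current dipole fits.

The head is modelled as a homogeneous conducting sphere.  For a current
dipole inside such a sphere, the *radial* component of the external
magnetic field has the closed form

    B_r(r) = C * (r_q x Q) . r_hat / |r - r_q|^3

(r_q: dipole position, Q: dipole moment, r: sensor position relative to
the sphere center), and is independent of volume currents.  Sensors are
treated as radial magnetometers, so this single expression is the whole
forward model.  Two classical silences follow directly: a dipole at the
sphere center, and a purely radial dipole moment, both produce zero
field everywhere.

All positions are in mm in a right-handed frame with the origin at the
sphere center, +x = right hemisphere, -y = posterior.  Fitted positions
live in this synthetic head frame, not true MNI space, but the
x > 0 = right convention matches the anatomical one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "HeadModel",
    "DipoleFit",
    "forward_radial",
    "fit_ecd",
    "dx_contrast",
    "kde_diff",
    "KdeDiff",
]

#: Fraction of the sphere radius beyond which candidate positions are penalized.
_INTERIOR_FRACTION = 0.97


@dataclass(frozen=True)
class HeadModel:
    """Spherical conductor plus the sensor array measuring it."""

    array: "SensorArray"  # noqa: F821 -- riftkit.synthmeg.SensorArray
    sphere_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sphere_radius: float = 90.0

    def __post_init__(self) -> None:
        center = np.asarray(self.sphere_center, dtype=float)
        object.__setattr__(self, "sphere_center", center)
        d = np.linalg.norm(self.array.positions - center, axis=1)
        if np.any(d <= self.sphere_radius):
            raise ValueError("all sensors must lie outside the conductor sphere")


@dataclass(frozen=True)
class DipoleFit:
    """A fitted equivalent current dipole.

    ``position`` in mm, ``moment`` a tangential 3-vector in arbitrary
    units, ``r_squared`` the explained variance of the topography.
    """

    position: np.ndarray
    moment: np.ndarray
    r_squared: float
    converged: bool

    @property
    def x(self) -> float:
        return float(self.position[0])


def forward_radial(
    position: Sequence[float], moment: Sequence[float], model: HeadModel
) -> np.ndarray:
    """Radial magnetic field of a current dipole at each sensor.

    Linear in ``moment``.  Raises if the dipole lies on or outside the
    conductor sphere.
    """
    pos = np.asarray(position, dtype=float)
    q = np.asarray(moment, dtype=float)
    r_q = pos - model.sphere_center
    if np.linalg.norm(r_q) >= model.sphere_radius:
        raise ValueError("dipole position must lie strictly inside the sphere")
    sensors = model.array.positions - model.sphere_center
    r_hat = sensors / np.linalg.norm(sensors, axis=1, keepdims=True)
    d = sensors - r_q
    d3 = np.linalg.norm(d, axis=1) ** 3
    return (r_hat @ np.cross(r_q, q)) / d3


def _tangential_basis(r_q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal vectors perpendicular to the radial direction."""
    n = np.linalg.norm(r_q)
    if n < 1e-9:
        return np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    rad = r_q / n
    helper = np.array([0.0, 0.0, 1.0])
    if abs(rad @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(rad, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(rad, e1)
    return e1, e2


def _residual_at(pos: np.ndarray, topo: np.ndarray, model: HeadModel):
    """Least-squares residual with the moment solved linearly at `pos`."""
    r_q = pos - model.sphere_center
    e1, e2 = _tangential_basis(r_q)
    gain = np.column_stack(
        [forward_radial(pos, e1, model), forward_radial(pos, e2, model)]
    )
    coef, _, _, _ = np.linalg.lstsq(gain, topo, rcond=None)
    resid = topo - gain @ coef
    moment = coef[0] * e1 + coef[1] * e2
    return float(resid @ resid), moment


def fit_ecd(
    topography: np.ndarray,
    model: HeadModel,
    start: Sequence[float] = (0.0, -88.0, -9.0),
    n_restarts: int = 5,
    seed: int = 0,
    xatol: float = 1e-3,
    maxiter: int = 800,
) -> DipoleFit:
    """Fit a single equivalent current dipole to a sensor topography.

    Nonlinear search over position (Nelder-Mead, convergence tolerance
    ``xatol`` mm) with the moment solved linearly at every candidate
    position; positions are kept inside the sphere by a quadratic
    penalty.  ``n_restarts`` seeded restarts, jittered around ``start``
    (10 mm s.d.), guard against local minima.  The default start is the
    central calcarine sulcus, (0, -88, -9) mm.
    """
    topo = np.asarray(topography, dtype=float)
    if topo.ndim != 1 or len(topo) < 6:
        raise ValueError("topography must be a vector over >= 6 channels")
    if not np.any(topo):
        raise ValueError("topography is identically zero")

    ss_total = float(topo @ topo)
    r_max = _INTERIOR_FRACTION * model.sphere_radius
    center = model.sphere_center

    def objective(pos: np.ndarray) -> float:
        r = np.linalg.norm(pos - center)
        if r >= r_max:
            # pull back inside; evaluate at the clipped position
            clipped = center + (pos - center) * (r_max * 0.999 / r)
            resid, _ = _residual_at(clipped, topo, model)
            return resid + ss_total * (r - r_max) ** 2
        resid, _ = _residual_at(pos, topo, model)
        return resid

    rng = np.random.default_rng(seed)
    starts = [np.asarray(start, dtype=float)]
    for _ in range(max(0, n_restarts - 1)):
        cand = starts[0] + rng.normal(0.0, 10.0, size=3)
        r = np.linalg.norm(cand - center)
        if r >= r_max:
            cand = center + (cand - center) * (0.9 * r_max / r)
        starts.append(cand)

    best = None
    for p0 in starts:
        res = minimize(
            objective,
            p0,
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": 1e-12 * max(ss_total, 1e-300),
                     "maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res

    pos = best.x
    r = np.linalg.norm(pos - center)
    if r >= r_max:
        pos = center + (pos - center) * (r_max * 0.999 / r)
    resid, moment = _residual_at(pos, topo, model)
    r2 = 1.0 - resid / ss_total
    return DipoleFit(
        position=pos,
        moment=moment,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        converged=bool(best.success),
    )


def dx_contrast(fits_left_stim, fits_right_stim):
    """Left/right displacement of paired dipole fits.

    ``dx = x(left-stimulus fit) - x(right-stimulus fit)`` per
    participant.  With successful orthogonal-phase disentangling and
    contralateral visual projection, the left-stimulus fit lands in the
    right hemisphere (x > 0) and vice versa, so dx is positive.

    Returns a ``(table, summary)`` pair; the hierarchical Bayesian test
    of the contrast is delegated to
    :func:`riftkit.inference.fit_hier_linear` on the returned table.
    """
    import pandas as pd

    if len(fits_left_stim) != len(fits_right_stim):
        raise ValueError("paired fit lists must have equal length")
    if not fits_left_stim:
        raise ValueError("empty fit lists")
    x_l = np.array([f.x for f in fits_left_stim])
    x_r = np.array([f.x for f in fits_right_stim])
    table = pd.DataFrame(
        {
            "participant": np.arange(len(x_l)),
            "x_left_stim": x_l,
            "x_right_stim": x_r,
            "dx": x_l - x_r,
        }
    )
    summary = {
        "mean_dx": float(table["dx"].mean()),
        "sd_dx": float(table["dx"].std(ddof=1)) if len(table) > 1 else 0.0,
        "n": int(len(table)),
        "frac_contralateral": float(np.mean((x_l > 0) & (x_r < 0))),
    }
    return table, summary


@dataclass(frozen=True)
class KdeDiff:
    """Signed kernel-density difference on a 3D lattice."""

    grid: np.ndarray        # (n_voxels, 3) mm
    density_a: np.ndarray   # normalized: sum * voxel_volume == 1
    density_b: np.ndarray
    diff: np.ndarray
    voxel_volume: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x": self.grid[:, 0],
                "y": self.grid[:, 1],
                "z": self.grid[:, 2],
                "density_a": self.density_a,
                "density_b": self.density_b,
                "diff": self.diff,
            }
        )


def _kde_on_grid(points: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    d2 = ((grid[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * bandwidth**2)).sum(axis=1)


def kde_diff(
    positions_a,
    positions_b,
    grid: np.ndarray | None = None,
    bandwidth: float = 15.0,
    grid_step: float = 5.0,
) -> KdeDiff:
    """Difference of two isotropic-Gaussian kernel densities of dipole positions.

    Each set's density uses a Gaussian kernel with isotropic s.d.
    ``bandwidth`` mm and is normalized discretely so that
    ``sum(density) * voxel_volume == 1`` on the lattice (default 5 mm
    spacing, covering both sets plus 3 bandwidths of margin).
    """
    a = np.atleast_2d(np.asarray(positions_a, dtype=float))
    b = np.atleast_2d(np.asarray(positions_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both position sets must be non-empty")

    if grid is None:
        allp = np.vstack([a, b])
        lo = np.floor((allp.min(axis=0) - 3 * bandwidth) / grid_step) * grid_step
        hi = np.ceil((allp.max(axis=0) + 3 * bandwidth) / grid_step) * grid_step
        axes = [np.arange(lo[i], hi[i] + grid_step / 2, grid_step) for i in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    else:
        grid = np.asarray(grid, dtype=float)

    voxel_volume = float(grid_step**3)
    dens_a = _kde_on_grid(a, grid, bandwidth)
    dens_b = _kde_on_grid(b, grid, bandwidth)
    dens_a /= dens_a.sum() * voxel_volume
    dens_b /= dens_b.sum() * voxel_volume
    return KdeDiff(
        grid=grid,
        density_a=dens_a,
        density_b=dens_b,
        diff=dens_a - dens_b,
        voxel_volume=voxel_volume,
    )
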