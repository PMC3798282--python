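"""Meridian contours of axisymmetric cells and their differential geometry.

An axisymmetric cell surface is represented by its meridian: an ordered
sequence of points ``(z, rho)`` running from the tip apex (s = 0, rho = 0)
toward the cell base, where ``s`` is arc length along the meridian, ``z``
the coordinate along the symmetry axis (the tip points toward +z) and
``rho`` the distance from the axis.

The derived geometry is the angle ``phi`` between the symmetry axis and the
outward surface normal (phi(0) = 0 at the apex, phi = pi/2 on a cylinder),
and the two principal curvatures: meridional ``kappa_s = dphi/ds`` and
circumferential ``kappa_theta = sin(phi)/rho`` with the symmetric limit
``kappa_theta(0) = kappa_s(0)`` at the apex.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from ._derivatives import deriv5_mirrored

__all__ = [
    "MeridianContour",
    "ShellGeometry",
    "InvalidContourError",
    "hemisphere_cap_contour",
    "cone_cap_contour",
]


class InvalidContourError(ValueError):
    """Raised when a point sequence cannot represent a valid meridian."""


@dataclass(frozen=True)
class ShellGeometry:
    """Pointwise surface geometry of a meridian contour."""

    phi: np.ndarray
    kappa_s: np.ndarray
    kappa_theta: np.ndarray


@dataclass
class MeridianContour:
    """Discretized tip-to-base meridian with uniform arc-length spacing.

    Parameters
    ----------
    z, rho : arrays of point coordinates in micrometres, tip first.
    spacing : target inter-point arc length in micrometres.
    """

    z: np.ndarray
    rho: np.ndarray
    spacing: float
    _geometry: ShellGeometry | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.z.shape != self.rho.shape or self.z.ndim != 1:
            raise InvalidContourError("z and rho must be 1-D arrays of equal length")
        if self.z.size < 7:
            raise InvalidContourError("contour needs at least 7 points")
        if abs(self.rho[0]) > 1e-12:
            raise InvalidContourError("rho must vanish at the tip (s = 0)")
        if np.any(self.rho[1:] <= 0):
            raise InvalidContourError("rho must be positive away from the tip")
        seg = np.hypot(np.diff(self.z), np.diff(self.rho))
        if np.any(seg <= 0):
            raise InvalidContourError("arc length must be strictly increasing")

    # -- basic quantities -------------------------------------------------
    @property
    def n_points(self) -> int:
        return self.z.size

    @property
    def s(self) -> np.ndarray:
        """Cumulative arc length per point (exact polyline arc)."""
        seg = np.hypot(np.diff(self.z), np.diff(self.rho))
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def arc_length(self) -> float:
        return float(self.s[-1])

    @property
    def uniform_spacing(self) -> float:
        """Actual mean spacing (uniform after resegmentation)."""
        return self.arc_length / (self.n_points - 1)

    def points(self) -> np.ndarray:
        """(n, 2) array of (z, rho) pairs."""
        return np.column_stack([self.z, self.rho])

    # -- resegmentation ---------------------------------------------------
    def resegment(self, spacing: float | None = None) -> "MeridianContour":
        """Return a copy sampled at uniform arc-length spacing.

        Cubic-spline interpolation with parity-correct end conditions at
        the apex (z even, rho odd in arc length) avoids the systematic
        inward erosion that repeated linear resegmentation produces on
        convex regions.
        """
        target = self.spacing if spacing is None else spacing
        z, rho, h = _resegment_arrays(self.z, self.rho, target)
        return MeridianContour(z, rho, target)

    # -- geometry ---------------------------------------------------------
    def geometry(self) -> ShellGeometry:
        """phi, kappa_s, kappa_theta at every point (five-point stencils)."""
        if self._geometry is None:
            h = self.uniform_spacing
            seg = np.hypot(np.diff(self.z), np.diff(self.rho))
            if np.max(np.abs(seg - h)) > 0.1 * h:
                raise InvalidContourError(
                    "spacing not uniform within 10%; resegment first"
                )
            zp = deriv5_mirrored(self.z, h, +1)
            rp = deriv5_mirrored(self.rho, h, -1)
            phi = np.arctan2(-zp, rp)
            kappa_s = deriv5_mirrored(phi, h, -1)
            kappa_theta = np.empty_like(kappa_s)
            kappa_theta[0] = kappa_s[0]
            kappa_theta[1:] = np.sin(phi[1:]) / self.rho[1:]
            self._geometry = ShellGeometry(phi, kappa_s, kappa_theta)
        return self._geometry

    def tip_curvature(self, n_fit: int = 14) -> float:
        """Apex curvature from an even quartic fit z(rho^2) near the tip.

        More robust than the raw stencil value, which is noisy at the
        resolution limit when the apex is sharp.
        """
        m = min(n_fit, self.n_points)
        r2 = self.rho[:m] ** 2
        a = np.column_stack([np.ones(m), r2, r2 * r2])
        coef, *_ = np.linalg.lstsq(a, self.z[:m], rcond=None)
        return float(-2.0 * coef[1])


def _resegment_arrays(
    z: np.ndarray, rho: np.ndarray, target: float
) -> tuple[np.ndarray, np.ndarray, float]:
    seg = np.hypot(np.diff(z), np.diff(rho))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(round(total / target)), 7)
    s_new = np.linspace(0.0, total, n + 1)
    # z is even about the apex -> clamped first derivative 0; rho is odd
    # -> vanishing second derivative.
    cs_z = CubicSpline(s, z, bc_type=((1, 0.0), "natural"))
    cs_r = CubicSpline(s, rho, bc_type=((2, 0.0), "natural"))
    z_new = cs_z(s_new)
    r_new = cs_r(s_new)
    r_new[0] = 0.0
    # guard against spline undershoot next to the apex
    np.maximum(r_new[1:], 1e-12, out=r_new[1:])
    return z_new, r_new, total / n


# -- initial-contour factories -------------------------------------------

def hemisphere_cap_contour(
    radius: float, spacing: float, total_arc: float
) -> MeridianContour:
    """Hemispherical cap of given radius joined to a cylinder of the same
    radius, extended to ``total_arc`` of meridional arc length."""
    cap_arc = np.pi / 2 * radius
    if total_arc <= cap_arc:
        raise ValueError("total_arc must exceed the cap arc length")
    n_cap = max(int(cap_arc / spacing), 8)
    a = np.linspace(0.0, cap_arc, n_cap)
    z = -radius * (1.0 - np.cos(a / radius))
    rho = radius * np.sin(a / radius)
    n_cyl = int(np.ceil((total_arc - cap_arc) / spacing))
    z_cyl = z[-1] - np.arange(1, n_cyl + 1) * spacing
    z = np.concatenate([z, z_cyl])
    rho = np.concatenate([rho, np.full(n_cyl, radius)])
    zz, rr, _ = _resegment_arrays(z, rho, spacing)
    return MeridianContour(zz, rr, spacing)


def cone_cap_contour(
    radius: float, spacing: float, total_arc: float, sharpness: float = 1.4
) -> MeridianContour:
    """Pointed (parabolic-nose) cap flaring to ``radius``; used to test
    that the steady state is independent of the initial contour."""
    t = np.linspace(0.0, 1.0, 80)
    z = -sharpness * radius * t
    rho = radius * np.sqrt(t)
    rho[0] = 0.0
    arc = np.hypot(np.diff(z), np.diff(rho)).sum()
    n_cyl = int(np.ceil((total_arc - arc) / spacing))
    z_cyl = z[-1] - np.arange(1, n_cyl + 1) * spacing
    z = np.concatenate([z, z_cyl])
    rho = np.concatenate([rho, np.full(n_cyl, radius)])
    zz, rr, _ = _resegment_arrays(z, rho, spacing)
    return MeridianContour(zz, rr, spacing)
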