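"""Thin-shell mechanics of the turgid cell wall.

The wall is a thin elastic shell of thickness ``delta`` inflated by turgor
pressure ``P``.  For an axisymmetric membrane the stresses balancing the
pressure are fixed by geometry alone:

    sigma_s     = P / (2 delta kappa_theta)
    sigma_theta = (P / (delta kappa_theta)) (1 - kappa_s / (2 kappa_theta))

which satisfy the normal balance kappa_s sigma_s + kappa_theta sigma_theta
= P / delta pointwise.  Plane-stress Hooke relations give the in-plane
strains, and the local expansion rates are the product of strain and the
signal-directed remodeling rate:

    xi_i = G_max Lambda(s) eps_i ,   i in {s, theta}.

Surface velocities (v_n, v_t) follow from the kinematic relations

    xi_s     = dv_t/ds + v_n kappa_s
    xi_theta = v_t cos(phi)/rho + v_n kappa_theta

with v_t(0) = 0 imposed by axisymmetry; eliminating v_n yields a
first-order linear ODE for v_t solved with an integrating factor.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_simpson

from .contour import MeridianContour, ShellGeometry
from .signal import GrowthSignal, InvalidSignalError

__all__ = [
    "WallMaterial",
    "ShellState",
    "ConcaveGeometryError",
    "shell_stresses",
    "wall_strains",
    "expansion_rates",
    "surface_velocities",
    "shell_state",
]


class ConcaveGeometryError(ValueError):
    """kappa_theta <= 0 somewhere: the membrane stress balance is invalid."""


@dataclass(frozen=True)
class WallMaterial:
    """Mechanical parameters of the cell wall.

    P : turgor pressure (MPa); E : Young's modulus (MPa);
    delta : wall thickness (um); nu : Poisson ratio of inserted material;
    g_max : remodeling rate at the tip (1/s).
    """

    P: float = 0.85
    E: float = 101.0
    delta: float = 0.2
    nu: float = 0.5
    g_max: float = 1.0

    def __post_init__(self) -> None:
        if min(self.P, self.E, self.delta, self.g_max) <= 0:
            raise ValueError("P, E, delta and g_max must be positive")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")

    @property
    def lumped_rate(self) -> float:
        """G_max P / (E delta), the only rate constant of the tip model (1/s/um^-1... 1/(s um))."""
        return self.g_max * self.P / (self.E * self.delta)


@dataclass(frozen=True)
class ShellState:
    """Stresses, strains, expansion rates and velocities on the contour."""

    sigma_s: np.ndarray
    sigma_theta: np.ndarray
    eps_s: np.ndarray
    eps_theta: np.ndarray
    xi_s: np.ndarray
    xi_theta: np.ndarray
    v_n: np.ndarray
    v_t: np.ndarray


def shell_stresses(
    geom: ShellGeometry, material: WallMaterial
) -> tuple[np.ndarray, np.ndarray]:
    """Meridional and hoop stress (MPa) balancing turgor pressure."""
    kt = geom.kappa_theta
    if np.any(kt <= 0):
        raise ConcaveGeometryError("kappa_theta must be positive everywhere")
    p_over_d = material.P / material.delta
    sigma_s = p_over_d / (2.0 * kt)
    sigma_theta = (p_over_d / kt) * (1.0 - geom.kappa_s / (2.0 * kt))
    return sigma_s, sigma_theta


def wall_strains(
    sigma_s: np.ndarray, sigma_theta: np.ndarray, material: WallMaterial
) -> tuple[np.ndarray, np.ndarray]:
    """Plane-stress Hooke strains of the pressurized wall."""
    eps_s = (sigma_s - material.nu * sigma_theta) / material.E
    eps_theta = (sigma_theta - material.nu * sigma_s) / material.E
    return eps_s, eps_theta


def expansion_rates(
    eps_s: np.ndarray,
    eps_theta: np.ndarray,
    lam: np.ndarray,
    material: WallMaterial,
) -> tuple[np.ndarray, np.ndarray]:
    """xi_i = G_max Lambda eps_i (1/s); zero wherever the signal is zero."""
    if np.any(lam < 0):
        raise InvalidSignalError("Lambda must be non-negative")
    g = material.g_max * lam
    return g * eps_s, g * eps_theta


def surface_velocities(
    xi_s: np.ndarray,
    xi_theta: np.ndarray,
    geom: ShellGeometry,
    rho: np.ndarray,
    h: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the kinematic relations for (v_n, v_t) on a uniform grid.

    Integrating factor form: d/ds (v_t / sin phi) = (xi_s - xi_theta
    kappa_s / kappa_theta) / sin phi, v_t(0) = 0; then v_n = (rho
    xi_theta - v_t cos phi) / sin phi with the apex limit v_n(0) =
    xi_theta(0)/kappa_theta(0).
    """
    phi, ks, kt = geom.phi, geom.kappa_s, geom.kappa_theta
    sp = np.sin(phi)
    if np.any(sp[1:] <= 0):
        raise ValueError("sin(phi) vanished away from the tip (flat region)")
    n = xi_s.size
    g = np.empty(n)
    g[1:] = (xi_s[1:] - xi_theta[1:] * ks[1:] / kt[1:]) / sp[1:]
    # apex limit: the integrand vanishes at s=0 (xi_s = xi_theta and
    # kappa_s = kappa_theta there); extrapolate quadratically for accuracy
    g[0] = 3.0 * g[1] - 3.0 * g[2] + g[3]
    integral = cumulative_simpson(g, dx=h, initial=0.0)
    v_t = sp * integral
    v_n = np.empty(n)
    v_n[0] = xi_theta[0] / kt[0]
    v_n[1:] = (rho[1:] * xi_theta[1:] - v_t[1:] * np.cos(phi[1:])) / sp[1:]
    return v_n, v_t


def shell_state(
    contour: MeridianContour, signal: GrowthSignal, material: WallMaterial
) -> ShellState:
    """Full mechanical state of a contour under a growth signal."""
    geom = contour.geometry()
    sigma_s, sigma_theta = shell_stresses(geom, material)
    eps_s, eps_theta = wall_strains(sigma_s, sigma_theta, material)
    lam = signal(contour.s)
    xi_s, xi_theta = expansion_rates(eps_s, eps_theta, lam, material)
    v_n, v_t = surface_velocities(
        xi_s, xi_theta, geom, contour.rho, contour.uniform_spacing
    )
    frozen = lam <= 0.0
    v_n = np.where(frozen, 0.0, v_n)
    v_t = np.where(frozen, 0.0, v_t)
    return ShellState(sigma_s, sigma_theta, eps_s, eps_theta, xi_s, xi_theta, v_n, v_t)
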