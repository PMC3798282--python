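"""Time evolution of the meridian contour and steady-state tip analysis.

Every point of the contour moves with the wall-material velocity
``v = v_n n + v_t t`` for a time step chosen adaptively: the displacement
per step is kept well below the grid spacing, and below a curvature-
relaxation limit proportional to h^2 (the normal velocity depends on
curvature, so an explicit scheme has a diffusive stability bound).  After
each step the contour is resegmented to uniform spacing, adding points as
it lengthens; material where the signal has decayed to zero is pinned.

The steady state is detected in the co-moving tip frame: the radial
profile rho(s) over s < 4 sigma is compared every 0.1 sigma of tip
advance; the shape is steady when the maximum change drops below an
advance-normalized tolerance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString

from .contour import (
    MeridianContour,
    hemisphere_cap_contour,
)
from .mechanics import WallMaterial, shell_state
from .signal import FWHM_PER_SIGMA, GrowthSignal

__all__ = [
    "TipMetrics",
    "TransitionResult",
    "SelfIntersectionError",
    "ConvergenceError",
    "evolve_contour",
    "steady_state_tip",
    "measure_diameter",
    "diameter_signal_ratio_sweep",
    "bluntness_sweep",
    "growth_velocity_prefactor",
    "infer_gmax",
    "diameter_transition",
    "assemble_whole_cell",
    "revolution_volume",
    "membrane_turnover_estimate",
]

#: default safety factors of the adaptive time step
CFL_DISPLACEMENT = 0.1
CFL_CURVATURE = 0.5


class SelfIntersectionError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, contour: MeridianContour | None = None):
        super().__init__(msg)
        self.contour = contour


@dataclass(frozen=True)
class TipMetrics:
    """Derived quantities of a steady-state growing tip.

    diameter : steady cylinder diameter w (um)
    tip_curvature_radius : 1/kappa_s at the apex (um)
    u : diameter / FWHM of the signal
    alpha : diameter / sigma of the signal (= 2 sqrt(2 ln 2) u for a
        Gaussian)
    v_growth : tip advance speed (um/s)
    prefactor_C : dimensionless constant in v = C G_max P r / (E delta)
    """

    diameter: float
    tip_curvature_radius: float
    u: float
    alpha: float
    v_growth: float
    prefactor_C: float


@dataclass(frozen=True)
class TransitionResult:
    """Outcome of an instantaneous signal-width change experiment."""

    w_init: float
    w_final: float
    transition_length: float
    equilibration_extension: float

    @property
    def extension_per_diameter(self) -> float:
        wref = 0.5 * (self.w_init + self.w_final)
        return self.equilibration_extension / wref


# ---------------------------------------------------------------------------
# low-level stepping


def _step(
    contour: MeridianContour,
    signal: GrowthSignal,
    material: WallMaterial,
    dt: float | None,
) -> tuple[MeridianContour, float]:
    """Advance one step; returns the new contour and the dt used."""
    state = shell_state(contour, signal, material)
    geom = contour.geometry()
    phi = geom.phi
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    vz = state.v_n * cos_p - state.v_t * sin_p
    vr = state.v_n * sin_p + state.v_t * cos_p
    if not np.any(vz) and not np.any(vr):
        # fully pinned contour: avoid resegmentation round-off drift
        return contour, (dt if dt is not None else 0.0)
    if dt is None:
        h = contour.uniform_spacing
        vmax = max(float(np.max(np.hypot(vz, vr))), 1e-300)
        kmax = max(float(np.max(np.abs(geom.kappa_s))), 1e-300)
        dt = min(CFL_DISPLACEMENT * h / vmax, CFL_CURVATURE * h * h * kmax / vmax)
    z = contour.z + vz * dt
    rho = contour.rho + vr * dt
    new = MeridianContour(z, rho, contour.spacing).resegment()
    return new, dt


def _check_simple(contour: MeridianContour) -> None:
    if not LineString(contour.points()).is_simple:
        raise SelfIntersectionError(
            f"contour self-intersected (n={contour.n_points}, "
            f"tip z={contour.z[0]:.4f})"
        )


def evolve_contour(
    contour: MeridianContour,
    signal: GrowthSignal,
    material: WallMaterial,
    dt: float | None,
    n_steps: int,
    record_every: int | None = None,
    check_every: int = 200,
) -> list[MeridianContour]:
    """Evolve for ``n_steps`` steps of size ``dt`` (adaptive if None).

    Returns the recorded trajectory (always includes the initial and
    final contours).  Raises :class:`SelfIntersectionError` if the contour
    crosses itself.
    """
    traj = [contour]
    for i in range(n_steps):
        contour, _ = _step(contour, signal, material, dt)
        if check_every and (i + 1) % check_every == 0:
            _check_simple(contour)
        if record_every and (i + 1) % record_every == 0:
            traj.append(contour)
    if traj[-1] is not contour:
        traj.append(contour)
    return traj


# ---------------------------------------------------------------------------
# steady state


def measure_diameter(
    contour: MeridianContour, phi_tol: float = 1e-3, window: float | None = None
) -> float:
    """Diameter of the cylindrical projection nearest the tip.

    Averages 2 rho over the first contiguous arc window (default one
    quarter of the contour) whose normal is within ``phi_tol`` of pi/2.
    Using the *first* such window keeps the measurement inside freshly
    grown wall even when the far, pinned part of the contour still has the
    radius of the initial condition.
    """
    geom = contour.geometry()
    s = contour.s
    idx = np.flatnonzero(np.abs(geom.phi - np.pi / 2) < phi_tol)
    if idx.size == 0:
        raise ConvergenceError("no cylindrical region found", contour)
    if window is None:
        window = 0.125 * contour.arc_length
    sel = idx[s[idx] <= s[idx[0]] + window]
    return float(2.0 * np.mean(contour.rho[sel]))


def steady_state_tip(
    signal: GrowthSignal,
    material: WallMaterial,
    init_contour: MeridianContour | None = None,
    tolerance: float = 1e-4,
    spacing: float | None = None,
    min_advance: float | None = None,
    max_advance: float | None = None,
    measure_advance: float | None = None,
) -> tuple[MeridianContour, TipMetrics]:
    """Evolve to the steady growing-tip shape and measure it.

    ``tolerance`` is the maximum allowed pointwise change of rho(s) (in
    units of sigma) per 0.1 sigma of tip advance, assessed over
    s < 4 sigma.  All length scales default to fractions of the signal
    width, so runs at different sigma are exact rescalings of each other.
    """
    sig = signal.sigma
    if spacing is None:
        spacing = sig / 40.0
    if min_advance is None:
        min_advance = 6.0 * sig
    if max_advance is None:
        max_advance = 40.0 * sig
    if measure_advance is None:
        measure_advance = 2.0 * sig
    if init_contour is None:
        init_contour = hemisphere_cap_contour(1.2 * sig, spacing, 8.0 * sig)
    contour = init_contour.resegment(spacing)

    z_start = contour.z[0]
    s_grid = np.linspace(0.0, 4.0 * sig, 200)
    prev_prof: np.ndarray | None = None
    last_check = contour.z[0]
    converged_at: float | None = None
    tip_track: list[tuple[float, float]] = []
    t = 0.0
    while True:
        contour, dt = _step(contour, signal, material, None)
        t += dt
        adv = contour.z[0] - z_start
        if converged_at is not None:
            tip_track.append((t, contour.z[0]))
            if adv - converged_at >= measure_advance:
                break
        elif contour.z[0] - last_check >= 0.1 * sig:
            last_check = contour.z[0]
            prof = np.interp(s_grid, contour.s, contour.rho)
            if prev_prof is not None:
                dmax = float(np.max(np.abs(prof - prev_prof)))
                if dmax < tolerance * sig and adv >= min_advance:
                    converged_at = adv
                elif adv >= max_advance:
                    raise ConvergenceError(
                        f"no steady state within {max_advance / sig:.0f} sigma of "
                        f"tip advance (last shape change {dmax:.2e})",
                        contour,
                    )
            prev_prof = prof

    track = np.asarray(tip_track)
    v_growth = float(np.polyfit(track[:, 0], track[:, 1], 1)[0])
    diameter = measure_diameter(contour)
    ktip = contour.tip_curvature()
    u = diameter / signal.fwhm
    alpha = diameter / sig
    prefactor = v_growth / (material.lumped_rate * diameter / 2.0)
    metrics = TipMetrics(
        diameter=diameter,
        tip_curvature_radius=1.0 / ktip,
        u=u,
        alpha=alpha,
        v_growth=v_growth,
        prefactor_C=prefactor,
    )
    return contour, metrics


# ---------------------------------------------------------------------------
# parameter sweeps


def diameter_signal_ratio_sweep(
    nu_values,
    signal: GrowthSignal | None = None,
    material: WallMaterial | None = None,
    **steady_kwargs,
) -> dict[str, np.ndarray]:
    """u(nu) and alpha(nu) for a common signal over a set of Poisson ratios."""
    signal = signal or GrowthSignal()
    base = material or WallMaterial()
    u_vals, a_vals = [], []
    for nu in nu_values:
        mat = WallMaterial(base.P, base.E, base.delta, float(nu), base.g_max)
        _, m = steady_state_tip(signal, mat, **steady_kwargs)
        u_vals.append(m.u)
        a_vals.append(m.alpha)
    return {
        "nu": np.asarray(nu_values, dtype=float),
        "u": np.asarray(u_vals),
        "alpha": np.asarray(a_vals),
    }


def bluntness_sweep(
    target_excess_kurtosis_values,
    fixed_sigma: float = 1.0,
    material: WallMaterial | None = None,
    **steady_kwargs,
) -> dict[str, np.ndarray]:
    """Ratio of tip radius of curvature to cell radius versus signal
    peakedness, at fixed signal standard deviation."""
    material = material or WallMaterial()
    ratios, qs = [], []
    for k in target_excess_kurtosis_values:
        sig = (
            GrowthSignal(sigma=fixed_sigma)
            if abs(k) < 1e-12
            else GrowthSignal.from_kurtosis(fixed_sigma, float(k))
        )
        _, m = steady_state_tip(sig, material, **steady_kwargs)
        ratios.append(m.tip_curvature_radius / (m.diameter / 2.0))
        qs.append(sig.shape_q if sig.family == "exponential_power" else 2.0)
    return {
        "excess_kurtosis": np.asarray(target_excess_kurtosis_values, dtype=float),
        "shape_q": np.asarray(qs),
        "tip_radius_over_cell_radius": np.asarray(ratios),
    }


def growth_velocity_prefactor(
    material: WallMaterial, signal: GrowthSignal, **steady_kwargs
) -> float:
    """Dimensionless C in v_growth = C G_max P r / (E delta)."""
    _, metrics = steady_state_tip(signal, material, **steady_kwargs)
    return metrics.prefactor_C


def infer_gmax(
    observed_velocity: float,
    cell_radius: float,
    material: WallMaterial,
    prefactor_C: float,
) -> float:
    """Solve v = C G_max P r / (E delta) for the remodeling rate G_max.

    ``observed_velocity`` in um/s, ``cell_radius`` in um.
    """
    return observed_velocity * material.E * material.delta / (
        prefactor_C * material.P * cell_radius
    )


# ---------------------------------------------------------------------------
# signal-width transition experiment


def diameter_transition(
    signal: GrowthSignal,
    delta_sigma: float,
    material: WallMaterial | None = None,
    completion_fraction: float = 0.9,
    spacing: float | None = None,
    steady: tuple[MeridianContour, TipMetrics] | None = None,
    **steady_kwargs,
) -> TransitionResult:
    """Instantaneously change the signal width by ``delta_sigma`` and follow
    the shape until the new diameter is established.

    Returns the axial length of the imprinted transition region (25%-75%
    width quantiles) and the equilibration extension: the axial distance
    from the apex position at the moment of the switch to the point where
    the width completes ``completion_fraction`` of its change.
    """
    material = material or WallMaterial()
    if spacing is None:
        spacing = signal.sigma / 40.0
    if steady is None:
        steady = steady_state_tip(signal, material, spacing=spacing, **steady_kwargs)
    contour, m0 = steady
    contour = MeridianContour(contour.z.copy(), contour.rho.copy(), contour.spacing)
    w_init = m0.diameter
    if delta_sigma == 0.0:
        return TransitionResult(w_init, w_init, 0.0, 0.0)
    new_sigma = signal.sigma + delta_sigma
    if new_sigma <= 0:
        raise ValueError("delta_sigma would make the signal width non-positive")
    new_signal = signal.with_sigma(new_sigma)
    # the steady diameter is strictly proportional to sigma
    w_final = w_init * new_sigma / signal.sigma

    z_switch = contour.z[0]
    target_adv = 10.0 * new_sigma
    while contour.z[0] - z_switch < target_adv:
        contour, _ = _step(contour, new_signal, material, None)

    # imprinted axial width profile behind the cap
    mask = contour.s > 3.0 * new_sigma
    zz = contour.z[mask]
    ww = 2.0 * contour.rho[mask]

    def crossing(frac: float) -> float:
        target = w_init + frac * (w_final - w_init)
        sign = np.sign(ww - target)
        flips = np.flatnonzero(np.diff(sign) != 0)
        if flips.size == 0:
            raise ConvergenceError(
                f"width never crossed the {frac:.0%} level", contour
            )
        i = flips[0]
        f = (target - ww[i]) / (ww[i + 1] - ww[i])
        return float(zz[i] + f * (zz[i + 1] - zz[i]))

    z25, z75 = crossing(0.25), crossing(0.75)
    z_done = crossing(completion_fraction)
    return TransitionResult(
        w_init=w_init,
        w_final=w_final,
        transition_length=abs(z75 - z25),
        equilibration_extension=z_done - z_switch,
    )


# ---------------------------------------------------------------------------
# whole-cell assembly and order-of-magnitude estimates


def revolution_volume(z: np.ndarray, rho: np.ndarray) -> float:
    """Volume of the solid of revolution of a meridian (trapezoid rule)."""
    return float(np.pi * np.abs(np.trapezoid(rho**2, z)))


def assemble_whole_cell(
    tip_contour: MeridianContour, target_volume: float
) -> tuple[np.ndarray, np.ndarray]:
    """Join two copies of a steady tip by a cylinder of the same diameter
    whose length is chosen so the solid of revolution has ``target_volume``.

    Returns the (z, rho) meridian of the whole cell, tip to tip.
    """
    geom = tip_contour.geometry()
    idx = np.flatnonzero(np.abs(geom.phi - np.pi / 2) < 1e-3)
    if idx.size == 0:
        raise ValueError("tip contour has no cylindrical section")
    cut = idx[0]
    z_cap = tip_contour.z[: cut + 1] - tip_contour.z[cut]
    rho_cap = tip_contour.rho[: cut + 1].copy()
    radius = float(rho_cap[-1])
    v_cap = revolution_volume(z_cap, rho_cap)
    v_mid = target_volume - 2.0 * v_cap
    if v_mid < -1e-9 * target_volume:
        raise ValueError(
            f"target volume {target_volume:g} smaller than two caps "
            f"({2 * v_cap:g})"
        )
    length_mid = max(v_mid, 0.0) / (np.pi * radius**2)
    # z_cap runs from the apex down to the cut (z_cap[-1] = 0, z_cap[0] > 0)
    z_r = length_mid / 2.0 + z_cap  # right cap, apex first
    if length_mid > 0:
        n_mid = max(int(np.ceil(length_mid / tip_contour.uniform_spacing)), 2)
        z_m = np.linspace(-length_mid / 2.0, length_mid / 2.0, n_mid + 1)[1:-1]
    else:
        z_m = np.empty(0)
    # meridian order: left apex -> left cut -> midsection -> right cut -> right apex
    z_all = np.concatenate([-z_r, z_m, z_r[::-1]])
    rho_all = np.concatenate(
        [rho_cap, np.full(z_m.size, radius), rho_cap[::-1]]
    )
    return z_all, rho_all


def membrane_turnover_estimate(
    n_patches: float = 25.0,
    vesicle_diameter: float = 0.3,
    zone_width: float = 4.5,
    patch_lifetime: float = 20.0,
) -> float:
    """Endocytic membrane internalization rate (1/s).

    Surface area of ``n_patches`` vesicles (spheres of the given diameter)
    divided by the area of a flat circular growth zone of the given width,
    per actin-patch lifetime.
    """
    if min(vesicle_diameter, zone_width, patch_lifetime) <= 0:
        raise ValueError("lengths and lifetime must be positive")
    vesicle_area = np.pi * vesicle_diameter**2
    zone_area = np.pi * (zone_width / 2.0) ** 2
    return float(n_patches * vesicle_area / zone_area / patch_lifetime)
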