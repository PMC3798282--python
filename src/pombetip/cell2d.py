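"""Whole-cell 2D morphogenesis: growth stencil, diffusing growth zones,
microtubule landmark potential.

The cell boundary grows where a mobile growth zone sits.  The zone's
center diffuses along the boundary arc in a potential made of Gaussian
wells (width sigma_MT, depth U0, drag absorbed into the units so U* has
units of um^2/min) centered on the two ends of the cell's long axis --
the landmark proteins delivered by microtubules.  Growth itself deforms
the outline toward a stencil: the cross-section of the steady tip shape
of the axisymmetric model, scaled to the growth-zone width.  Depending on
the zone mobility D_gz and the potential width, cells grow straight
(category I), bent (II: S- or banana-shaped) or bulged (III).

Units in this module: micrometres and minutes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contour import MeridianContour
from .outline2d import (
    BEND_THRESHOLD,
    WIDTH_THRESHOLD,
    CellOutline2D,
    ShapeMetrics2D,
    find_long_axis,
    resegment_outline,
    shape_metrics,
)
__all__ = [
    "Stencil2D",
    "make_stencil",
    "initial_outline",
    "tip_potential_profile",
    "potential_gradient",
    "step_growth_zone",
    "choose_timestep",
    "apply_stencil",
    "simulate_cell",
    "CellRunResult",
    "phase_diagram",
    "classify_bent_shape",
    "DEFAULT_U0",
    "DEFAULT_GENERATION_MINUTES",
]

DEFAULT_U0 = 0.2  # um^2/min, landmark potential depth
DEFAULT_GENERATION_MINUTES = 150.0  # time for a straight cell to double


# ---------------------------------------------------------------------------
# growth stencil


@dataclass(frozen=True)
class Stencil2D:
    """Planar cross-section of a steady 3D tip, used as a growth template.

    ``arc`` is meridional arc distance from the stencil apex, ``lateral``
    the half-width and ``depth`` the axial distance behind the apex at
    each arc sample.  ``S = arc[-1]`` is the maximum stencil arc.
    """

    arc: np.ndarray
    lateral: np.ndarray
    depth: np.ndarray
    kappa_stencil: float

    @property
    def S(self) -> float:
        return float(self.arc[-1])

    @property
    def width(self) -> float:
        return float(2.0 * self.lateral[-1])

    def scaled(self, factor: float) -> "Stencil2D":
        return Stencil2D(
            self.arc * factor,
            self.lateral * factor,
            self.depth * factor,
            self.kappa_stencil / factor,
        )


def make_stencil(
    sigma_gz: float,
    tip_contour: MeridianContour,
    tip_sigma: float = 1.0,
    phi_tol: float = 1e-3,
) -> Stencil2D:
    """Build the growth stencil from a steady tip contour.

    The contour (computed at signal width ``tip_sigma``) is trimmed where
    it becomes cylindrical and rescaled by ``sigma_gz / tip_sigma`` so the
    stencil width matches the growth-zone width parameter.
    """
    geom = tip_contour.geometry()
    idx = np.flatnonzero(np.abs(geom.phi - np.pi / 2) < phi_tol)
    if idx.size == 0:
        raise ValueError("tip contour has no cylindrical transition to trim at")
    cut = idx[0]
    factor = sigma_gz / tip_sigma
    s = tip_contour.s[: cut + 1]
    base = Stencil2D(
        arc=s.copy(),
        lateral=tip_contour.rho[: cut + 1].copy(),
        depth=tip_contour.z[0] - tip_contour.z[: cut + 1],
        kappa_stencil=tip_contour.tip_curvature(),
    )
    return base.scaled(factor)


def initial_outline(
    length: float, stencil: Stencil2D, points_per_curvature: float = 8.0
) -> CellOutline2D:
    """Spherocylinder-like outline: two stencil-shaped caps joined by
    straight flanks, apex-to-apex length ``length``.

    The vertex count follows the discretization rule n = c * perimeter *
    max(kappa): spacing about 1/(c * kappa_stencil).
    """
    w = stencil.width
    depth_total = float(stencil.depth[-1])
    if length < 2.0 * depth_total:
        raise ValueError("length must be at least twice the cap depth")
    half_flank = length / 2.0 - depth_total
    cap_x = length / 2.0 - stencil.depth  # apex first
    cap_y = stencil.lateral
    # CCW: right apex -> upper right cap -> upper flank -> left cap -> left
    # apex -> lower left cap -> lower flank -> lower right cap
    xs = [cap_x, np.array([-half_flank]), -cap_x[::-1]]
    ys = [cap_y, np.array([w / 2.0]), cap_y[::-1]]
    xs += [-cap_x[1:], np.array([half_flank]), cap_x[::-1][:-1]]
    ys += [-cap_y[1:], np.array([-w / 2.0]), -cap_y[::-1][:-1]]
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    raw = CellOutline2D(x, y)
    spacing = 1.0 / (points_per_curvature * stencil.kappa_stencil)
    n = max(int(round(raw.perimeter * points_per_curvature * stencil.kappa_stencil)), 24)
    return resegment_outline(raw, n_target=n)


# ---------------------------------------------------------------------------
# landmark potential and growth-zone dynamics


def _wrapped_offset(s: np.ndarray | float, center: float, perimeter: float):
    """Signed arc offset s - center wrapped into [-P/2, P/2)."""
    return (np.asarray(s, float) - center + perimeter / 2.0) % perimeter - perimeter / 2.0


def tip_potential_profile(
    s: np.ndarray,
    centers: np.ndarray,
    perimeter: float,
    sigma_mt: float,
    u0: float,
) -> np.ndarray:
    """Drag-absorbed potential U*(s) = -U0 sum_wells exp(-d^2 / 2 sigma^2)."""
    u = np.zeros_like(np.asarray(s, dtype=float))
    for c in np.atleast_1d(centers):
        d = _wrapped_offset(s, float(c), perimeter)
        u -= u0 * np.exp(-0.5 * (d / sigma_mt) ** 2)
    return u


def potential_gradient(
    s: np.ndarray | float,
    centers: np.ndarray,
    perimeter: float,
    sigma_mt: float,
    u0: float,
):
    """dU*/ds at arc position(s) s."""
    g = np.zeros_like(np.asarray(s, dtype=float))
    for c in np.atleast_1d(centers):
        d = _wrapped_offset(s, float(c), perimeter)
        g += u0 * (d / sigma_mt**2) * np.exp(-0.5 * (d / sigma_mt) ** 2)
    return g


def step_growth_zone(
    s_gz: float,
    centers: np.ndarray,
    perimeter: float,
    sigma_mt: float,
    u0: float,
    d_gz: float,
    dt: float,
    rng: np.random.Generator,
) -> float:
    """One Brownian-dynamics step of the growth-zone center."""
    grad = float(potential_gradient(s_gz, centers, perimeter, sigma_mt, u0))
    step = -grad * dt + np.sqrt(2.0 * d_gz * dt) * rng.standard_normal()
    return float((s_gz + step) % perimeter)


def choose_timestep(
    d_gz: float,
    sigma_mt: float,
    u0: float,
    v: float,
    kappa_stencil: float,
    eps: float = 0.01,
) -> float:
    """Safety-scaled minimum of the three step-size conditions: potential
    sampling under diffusion, drift accuracy, and contour-change size."""
    branches = []
    if d_gz > 0:
        branches.append(sigma_mt**2 / (2.0 * d_gz))
    if u0 > 0:
        grad_max = 2.0 * u0 * np.exp(-0.5) / sigma_mt
        branches.append(sigma_mt / grad_max)
    branches.append(1.0 / (v * kappa_stencil))
    return eps * min(branches)


# ---------------------------------------------------------------------------
# stencil growth


def apply_stencil(
    x: np.ndarray,
    y: np.ndarray,
    i0: int,
    stencil: Stencil2D,
    v_dt: float,
) -> None:
    """Grow the outline in place around vertex ``i0``.

    The stencil apex advances by ``v_dt`` along the outward normal at
    ``i0``; flanking vertices move toward the stencil point at the same
    arc distance, vetoed if the move points inward (against the vertex's
    own outward normal) and capped at 2 v_dt (1 - s/S).
    """
    n = x.size
    ip, im = (i0 + 1) % n, (i0 - 1) % n
    tx, ty = x[ip] - x[im], y[ip] - y[im]
    tn = np.hypot(tx, ty)
    tx, ty = tx / tn, ty / tn
    nx, ny = ty, -tx  # outward for CCW
    apex = np.array([x[i0] + v_dt * nx, y[i0] + v_dt * ny])

    h = tn / 2.0  # local spacing estimate
    kmax = min(int(stencil.S / h), n // 2 - 1)
    if kmax >= 1:
        k = np.arange(1, kmax + 1)
        arc_k = k * h
        lat = np.interp(arc_k, stencil.arc, stencil.lateral)
        dep = np.interp(arc_k, stencil.arc, stencil.depth)
        cap = 2.0 * v_dt * (1.0 - arc_k / stencil.S)
        for sign, idx in ((+1.0, (i0 + k) % n), (-1.0, (i0 - k) % n)):
            targ_x = apex[0] - dep * nx + sign * lat * tx
            targ_y = apex[1] - dep * ny + sign * lat * ty
            dx = targ_x - x[idx]
            dy = targ_y - y[idx]
            # outward normal at each flanking vertex
            jp, jm = (idx + 1) % n, (idx - 1) % n
            vnx = y[jp] - y[jm]
            vny = -(x[jp] - x[jm])
            outward = dx * vnx + dy * vny > 0.0
            dist = np.hypot(dx, dy)
            move = np.minimum(dist, cap)
            ok = outward & (dist > 1e-15)
            scalef = np.where(ok, move / np.where(dist > 0, dist, 1.0), 0.0)
            x[idx] += scalef * dx
            y[idx] += scalef * dy
    x[i0], y[i0] = apex


# ---------------------------------------------------------------------------
# whole-cell simulation


@dataclass
class CellRunResult:
    """Outcome of one whole-cell growth simulation."""

    outline: CellOutline2D
    metrics: ShapeMetrics2D
    t_final: float
    doubled: bool
    self_intersected: bool
    zone_positions: np.ndarray
    axis_endpoints: tuple[int, int]
    frames: list[CellOutline2D] = field(default_factory=list)
    zone_track: np.ndarray | None = None


def _nearest_vertex(outline: CellOutline2D, px: float, py: float) -> int:
    return int(np.argmin((outline.x - px) ** 2 + (outline.y - py) ** 2))


def _project_to_arc(x: np.ndarray, y: np.ndarray, arc: np.ndarray,
                    perimeter: float, px: float, py: float) -> float:
    """Arc coordinate of the boundary point closest to (px, py).

    Keeping the growth zone anchored geometrically (rather than by a raw
    arc number) matters: growth inserts boundary length at the tips, which
    would otherwise advect the zone's coordinate away from the landmark
    wells.
    """
    n = x.size
    k = int(np.argmin((x - px) ** 2 + (y - py) ** 2))
    best = (np.inf, 0.0)
    for a in (k - 1, k):
        b = (a + 1) % n
        a %= n
        ex, ey = x[b] - x[a], y[b] - y[a]
        ee = ex * ex + ey * ey
        if ee == 0:
            continue
        t = np.clip(((px - x[a]) * ex + (py - y[a]) * ey) / ee, 0.0, 1.0)
        qx, qy = x[a] + t * ex, y[a] + t * ey
        d2 = (qx - px) ** 2 + (qy - py) ** 2
        if d2 < best[0]:
            best = (d2, (arc[a] + t * np.sqrt(ee)) % perimeter)
    return float(best[1])


def _nearest_boundary_point(x: np.ndarray, y: np.ndarray,
                            px: float, py: float) -> tuple[float, float]:
    """Closest point on the polygon boundary to (px, py)."""
    n = x.size
    k = int(np.argmin((x - px) ** 2 + (y - py) ** 2))
    best = (np.inf, (float(x[k]), float(y[k])))
    for a in (k - 1, k):
        b = (a + 1) % n
        a %= n
        ex, ey = x[b] - x[a], y[b] - y[a]
        ee = ex * ex + ey * ey
        if ee == 0:
            continue
        t = np.clip(((px - x[a]) * ex + (py - y[a]) * ey) / ee, 0.0, 1.0)
        qx, qy = x[a] + t * ex, y[a] + t * ey
        d2 = (qx - px) ** 2 + (qy - py) ** 2
        if d2 < best[0]:
            best = (d2, (float(qx), float(qy)))
    return best[1]


def _point_at_arc(x: np.ndarray, y: np.ndarray, arc: np.ndarray,
                  perimeter: float, s: float) -> tuple[float, float]:
    """Linear interpolation of the boundary point at arc coordinate s."""
    n = x.size
    s = s % perimeter
    i = int(np.searchsorted(arc, s, side="right") - 1)
    i = max(i, 0)
    j = (i + 1) % n
    seg = arc[j] - arc[i] if j != 0 else perimeter - arc[i]
    t = 0.0 if seg <= 0 else (s - arc[i]) / seg
    return float(x[i] + t * (x[j] - x[i])), float(y[i] + t * (y[j] - y[i]))


def simulate_cell(
    stencil: Stencil2D,
    n_zones: int = 1,
    u0: float = DEFAULT_U0,
    sigma_mt: float = 0.5,
    d_gz: float = 0.05,
    seed: int = 0,
    length: float = 8.0,
    generation_minutes: float = DEFAULT_GENERATION_MINUTES,
    eps: float = 0.01,
    max_generations: float = 3.0,
    n_frames: int = 0,
    record_zone_track: bool = False,
    spacing_drift_limit: float = 0.02,
    check_interval: int = 200,
    bend_threshold: float = BEND_THRESHOLD,
    width_threshold: float = WIDTH_THRESHOLD,
) -> CellRunResult:
    """Grow a cell until its long axis doubles, or ``max_generations``
    straight-growth doubling times elapse.

    ``n_zones`` growth zones start at the cell tips and diffuse in the
    landmark potential anchored at the long-axis endpoints.  The total
    elongation speed of a straight cell is length/generation_minutes,
    split equally among zones.
    """
    if n_zones not in (1, 2):
        raise ValueError("n_zones must be 1 or 2")
    rng = np.random.default_rng(seed)
    outline = initial_outline(length, stencil)
    spacing0 = outline.perimeter / outline.n_points

    i_ax, j_ax = find_long_axis(outline)
    axis_vec = np.array(
        [outline.x[j_ax] - outline.x[i_ax], outline.y[j_ax] - outline.y[i_ax]]
    )
    L0 = float(np.hypot(*axis_vec))

    v_total = length / generation_minutes
    v_zone = v_total / n_zones
    dt = choose_timestep(d_gz, sigma_mt, u0, v_total, stencil.kappa_stencil, eps)
    t_max = max_generations * generation_minutes

    x = outline.x.copy()
    y = outline.y.copy()
    # zones start at the axis endpoints (the cell tips), anchored by
    # geometric position: boundary stretching must not advect them
    zone_idx = [j_ax, i_ax][:n_zones]
    zones_xy = [(float(outline.x[i]), float(outline.y[i])) for i in zone_idx]

    t = 0.0
    steps = 0
    doubled = False
    intersected = False
    frames: list[CellOutline2D] = []
    ztrack: list[list[float]] = []
    frame_interval = max(int(t_max / dt / n_frames), 1) if n_frames else 0

    while True:
        outline = CellOutline2D(x, y)
        if outline.spacing_drift() > spacing_drift_limit:
            ax_xy = (
                (outline.x[i_ax], outline.y[i_ax]),
                (outline.x[j_ax], outline.y[j_ax]),
            )
            n_new = max(int(round(outline.perimeter / spacing0)), 24)
            outline = resegment_outline(outline, n_target=n_new)
            x, y = outline.x, outline.y
            i_ax = _nearest_vertex(outline, *ax_xy[0])
            j_ax = _nearest_vertex(outline, *ax_xy[1])
        arc = outline.arc

        i_ax, j_ax = find_long_axis(outline, start=(i_ax, j_ax))
        perim = outline.perimeter
        centers = np.array([arc[i_ax], arc[j_ax]])

        for zi in range(n_zones):
            s_here = _project_to_arc(x, y, arc, perim, *zones_xy[zi])
            s_new = step_growth_zone(
                s_here, centers, perim, sigma_mt, u0, d_gz, dt, rng
            )
            zones_xy[zi] = _point_at_arc(x, y, arc, perim, s_new)
            i0 = int(np.argmin(np.abs(_wrapped_offset(arc, s_new, perim))))
            apply_stencil(x, y, i0, stencil, v_zone * dt)
            # ride the moved boundary: re-anchor on the updated polygon
            zones_xy[zi] = _nearest_boundary_point(x, y, *zones_xy[zi])

        t += dt
        steps += 1
        if record_zone_track:
            ztrack.append([t] + [
                _project_to_arc(x, y, arc, perim, *p) for p in zones_xy
            ])
        if frame_interval and steps % frame_interval == 0:
            frames.append(CellOutline2D(x.copy(), y.copy()))

        axis_len = float(
            np.hypot(x[j_ax] - x[i_ax], y[j_ax] - y[i_ax])
        )
        if axis_len >= 2.0 * L0:
            doubled = True
            break
        if t >= t_max:
            break
        if steps % check_interval == 0:
            if not CellOutline2D(x, y).is_simple():
                intersected = True
                break

    final = CellOutline2D(x, y)
    metrics = shape_metrics(
        final,
        axis_vec,
        endpoints=(i_ax, j_ax),
        bend_threshold=bend_threshold,
        width_threshold=width_threshold,
    )
    if intersected:
        metrics = ShapeMetrics2D(
            bend=metrics.bend,
            width=metrics.width,
            category="III",
            axis_length=metrics.axis_length,
        )
    return CellRunResult(
        outline=final,
        metrics=metrics,
        t_final=t,
        doubled=doubled,
        self_intersected=intersected,
        zone_positions=np.asarray(zones_xy),
        axis_endpoints=(i_ax, j_ax),
        frames=frames,
        zone_track=np.asarray(ztrack) if record_zone_track else None,
    )


# ---------------------------------------------------------------------------
# bent-shape morphology and phase diagram


def classify_bent_shape(
    outline: CellOutline2D,
    endpoints: tuple[int, int] | None = None,
    n_samples: int = 64,
    s_fraction: float = 0.25,
) -> str:
    """Classify a bent cell as "S" or "banana" from its midline.

    The midline (average of the two boundary chains between the axis
    endpoints) is compared with the endpoint chord; an S-shape deviates
    to both sides by at least ``s_fraction`` of the maximum deviation.
    """
    if endpoints is None:
        endpoints = find_long_axis(outline)
    i, j = endpoints
    pts = outline.points()
    n = outline.n_points
    chain_a = pts[np.arange(i, i + (j - i) % n + 1) % n]
    chain_b = pts[np.arange(j, j + (i - j) % n + 1) % n][::-1]

    def sample(chain: np.ndarray) -> np.ndarray:
        seg = np.hypot(*np.diff(chain, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        u = np.linspace(0.0, s[-1], n_samples)
        return np.column_stack(
            [np.interp(u, s, chain[:, 0]), np.interp(u, s, chain[:, 1])]
        )
    mid = 0.5 * (sample(chain_a) + sample(chain_b))
    a, b = pts[i], pts[j]
    u = (b - a) / np.hypot(*(b - a))
    rel = mid - a
    dev = rel[:, 0] * u[1] - rel[:, 1] * u[0]
    dmax = np.max(np.abs(dev))
    if dmax == 0:
        return "banana"
    pos, neg = float(np.max(dev, initial=0.0)), float(-np.min(dev, initial=0.0))
    return "S" if min(pos, neg) > s_fraction * dmax else "banana"


def phase_diagram(
    stencil: Stencil2D,
    d_grid: np.ndarray,
    sigma_mt_grid: np.ndarray,
    u0: float = DEFAULT_U0,
    n_zones: int = 1,
    reps_per_cell: int = 3,
    base_seed: int = 0,
    **sim_kwargs,
):
    """Majority-vote shape category over a (D_gz, sigma_MT) grid.

    Returns a pandas DataFrame with one row per simulation (d_gz,
    sigma_mt, rep, seed, category, bend, width, doubled) plus a
    categories array of shape (len(d_grid), len(sigma_mt_grid)).
    """
    import pandas as pd

    rows = []
    cats = np.empty((len(d_grid), len(sigma_mt_grid)), dtype=object)
    severity = {"I": 0, "II": 1, "III": 2}
    for i, d in enumerate(d_grid):
        for j, sig in enumerate(sigma_mt_grid):
            votes = []
            for rep in range(reps_per_cell):
                seed = int(
                    np.random.SeedSequence(
                        [int(base_seed), i, j, rep]
                    ).generate_state(1)[0]
                )
                try:
                    res = simulate_cell(
                        stencil,
                        n_zones=n_zones,
                        u0=u0,
                        sigma_mt=float(sig),
                        d_gz=float(d),
                        seed=seed,
                        **sim_kwargs,
                    )
                    cat = res.metrics.category
                    bend, width = res.metrics.bend, res.metrics.width
                    doubled = res.doubled
                except Exception:  # failed run counts as bulged
                    cat, bend, width, doubled = "III", np.nan, np.nan, False
                votes.append(cat)
                rows.append(
                    dict(
                        d_gz=float(d),
                        sigma_mt=float(sig),
                        rep=rep,
                        seed=seed,
                        category=cat,
                        bend=bend,
                        width=width,
                        doubled=doubled,
                    )
                )
            counts = {c: votes.count(c) for c in set(votes)}
            best = max(counts.items(), key=lambda kv: (kv[1], severity[kv[0]]))
            cats[i, j] = best[0]
    return pd.DataFrame(rows), cats
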