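"""Feedback between growth-signal width and cell shape across generations.

The mean cell diameter w̄ obeys, as the cell lengthens,

    d(w̄ L)/dL = alpha sigma_L(w̄, L)

where alpha is the diameter-to-signal-width ratio of the tip-growth model
and sigma_L(w̄, L) describes how the signal width depends on the current
shape.  Cells grow from birth length L0 to 2 L0 and divide in half; the
one-generation map of birth diameters has a fixed point w*, stable iff
the logarithmic sensitivity

    beta = w* (d sigma_L / d w̄) / sigma_L   (at the fixed point)

is below one.  A purely geometric microtubule-delivery model, in which the
growth zone covers the tip cap up to an offset Delta_MT from the cylinder
corner, gives sigma_L proportional to (w̄/2 - Delta_MT) and hence
beta = w0 / (w0 - 2 Delta_MT) > 1 for any positive offset: geometric
microtubule sensing alone over-responds to diameter changes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, curve_fit

__all__ = [
    "SignalWidthModel",
    "LineageState",
    "MTTipSample",
    "MTWidthCurve",
    "NoFixedPointError",
    "integrate_mean_width",
    "fixed_point",
    "division_map",
    "stability_beta",
    "simulate_lineage",
    "synth_mt_tips",
    "mt_tip_histogram_fit",
    "mt_width_curve_analysis",
    "beta_versus_alpha",
    "synthetic_mt_unfocusing_curve",
]


class NoFixedPointError(RuntimeError):
    pass


class InvalidWidthModelError(ValueError):
    pass


@dataclass(frozen=True)
class SignalWidthModel:
    """sigma_L(w̄, L): growth-signal width as a function of cell shape.

    Forms
    -----
    constant      sigma_L = sigma0
    linearized    sigma_L = sigma0 [1 + beta (w̄-w0)/w0 + gamma (L-L0)/L0]
    geometric_mt  sigma_L = (w0/alpha) (w̄/2 - delta_mt) / (w0/2 - delta_mt)
    tabulated     monotone-spline interpolation of (w̄, sigma_L) samples

    ``alpha`` is carried by the model because the growth law couples
    sigma_L to the laid-down tip diameter alpha*sigma_L.
    """

    form: str = "linearized"
    sigma0: float = 1.0
    beta: float = 0.0
    gamma: float = 0.0
    w0: float = 3.2
    L0: float | None = None
    delta_mt: float = 0.0
    alpha: float = 3.2
    table_w: np.ndarray | None = None
    table_sigma: np.ndarray | None = None
    _spline: PchipInterpolator | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.form not in ("constant", "linearized", "geometric_mt", "tabulated"):
            raise InvalidWidthModelError(f"unknown form {self.form!r}")
        if self.L0 is None:
            object.__setattr__(self, "L0", 2.5 * self.w0)
        if self.form == "geometric_mt" and self.delta_mt >= self.w0 / 2:
            raise InvalidWidthModelError("delta_mt must be below w0/2")
        if self.form == "tabulated":
            if self.table_w is None or self.table_sigma is None:
                raise InvalidWidthModelError("tabulated form needs table_w/table_sigma")
            object.__setattr__(
                self,
                "_spline",
                PchipInterpolator(
                    np.asarray(self.table_w, float),
                    np.asarray(self.table_sigma, float),
                    extrapolate=False,
                ),
            )

    # sigma0 of the geometric model is fixed by requiring the wild-type
    # fixed point: sigma_L(w0) = w0/alpha.
    def __call__(self, w: float, L: float | None = None) -> float:
        L = self.L0 if L is None else L
        if self.form == "constant":
            return self.sigma0
        if self.form == "linearized":
            return self.sigma0 * (
                1.0
                + self.beta * (w - self.w0) / self.w0
                + self.gamma * (L - self.L0) / self.L0
            )
        if self.form == "geometric_mt":
            return (self.w0 / self.alpha) * (w / 2.0 - self.delta_mt) / (
                self.w0 / 2.0 - self.delta_mt
            )
        val = float(self._spline(w))
        if np.isnan(val):
            raise InvalidWidthModelError(
                f"diameter {w:g} outside tabulated range "
                f"[{self.table_w[0]:g}, {self.table_w[-1]:g}]"
            )
        return val

    def dsigma_dw(self, w: float, L: float | None = None) -> float:
        L = self.L0 if L is None else L
        if self.form == "constant":
            return 0.0
        if self.form == "linearized":
            return self.sigma0 * self.beta / self.w0
        if self.form == "geometric_mt":
            return (self.w0 / self.alpha) * 0.5 / (self.w0 / 2.0 - self.delta_mt)
        return float(self._spline.derivative()(w))


@dataclass(frozen=True)
class LineageState:
    """One cell of a lineage: per-segment width profile at birth."""

    generation: int
    seg_lengths: np.ndarray
    seg_widths: np.ndarray

    @property
    def birth_length(self) -> float:
        return float(self.seg_lengths.sum())

    @property
    def birth_width(self) -> float:
        return float(
            np.sum(self.seg_lengths * self.seg_widths) / self.seg_lengths.sum()
        )


@dataclass(frozen=True)
class MTTipSample:
    """Synthetic meridional positions of microtubule tip/boundary contacts."""

    cell_diameter: float
    cell_length: float
    contact_positions: np.ndarray
    seed: int

    @property
    def n_samples(self) -> int:
        return self.contact_positions.size


@dataclass(frozen=True)
class MTWidthCurve:
    """sigma_MT(w̄) analysis result: fixed point and stability."""

    diameters: np.ndarray
    sigma_mt: np.ndarray
    alpha: float
    intersection_diameter: float | None
    beta_at_intersection: float | None

    @property
    def stable(self) -> bool | None:
        if self.beta_at_intersection is None:
            return None
        return self.beta_at_intersection < 1.0


# ---------------------------------------------------------------------------
# growth law


def integrate_mean_width(
    model: SignalWidthModel | Callable[[float, float], float],
    w_init: float,
    L_init: float,
    L_final: float,
    alpha: float | None = None,
    rtol: float = 1e-10,
):
    """Integrate d(w̄ L)/dL = alpha sigma_L(w̄, L) from L_init to L_final.

    Returns the solve_ivp solution object with dense output; ``sol.y[0]``
    is w̄ along ``sol.t``.
    """
    if alpha is None:
        if not isinstance(model, SignalWidthModel):
            raise ValueError("alpha required for a bare callable model")
        alpha = model.alpha

    def rhs(L, y):
        sig = model(y[0], L)
        if sig <= 0:
            raise InvalidWidthModelError(f"sigma_L <= 0 at w={y[0]:g}, L={L:g}")
        return [(alpha * sig - y[0]) / L]

    sol = solve_ivp(
        rhs,
        (L_init, L_final),
        [w_init],
        rtol=rtol,
        atol=1e-12 * w_init,
        dense_output=True,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"width integration failed: {sol.message}")
    return sol


def division_map(
    model: SignalWidthModel, w_birth: float, L0: float | None = None
) -> float:
    """Mean diameter at division (L = 2 L0) given the birth diameter.

    Symmetric halving does not change the mean width in this mean-field
    description, so this is also the daughters' birth diameter.
    """
    L0 = model.L0 if L0 is None else L0
    sol = integrate_mean_width(model, w_birth, L0, 2.0 * L0)
    return float(sol.y[0, -1])


def fixed_point(
    model: SignalWidthModel, bracket: tuple[float, float] | None = None
) -> float:
    """Birth diameter w* reproduced exactly by one growth-division cycle."""
    if model.form == "constant":
        return model.alpha * model.sigma0
    if bracket is None:
        bracket = (0.2 * model.w0, 5.0 * model.w0)
    lo, hi = bracket

    def gap(w: float) -> float:
        # a trajectory that drives sigma_L to zero is a collapsing cell:
        # its division width is effectively zero, far below w
        try:
            return division_map(model, w) - w
        except InvalidWidthModelError:
            return -w

    grid = np.geomspace(lo, hi, 41)
    vals = np.array([gap(w) for w in grid])
    sign_change = np.flatnonzero(np.diff(np.sign(vals)) != 0)
    if sign_change.size == 0:
        raise NoFixedPointError("no root of the division map in the bracket")
    a, b = grid[sign_change[0]], grid[sign_change[0] + 1]
    return float(brentq(gap, a, b, xtol=1e-12))


def stability_beta(
    model: SignalWidthModel, eps_frac: float = 1e-5
) -> tuple[float, bool, float]:
    """Effective beta at the fixed point and the measured per-generation
    error multiplier of the division map.

    Returns ``(beta_effective, stable, multiplier)`` where ``multiplier``
    is (M(w*+eps) - w*)/eps for the one-generation map M.
    """
    w_star = fixed_point(model)
    sig = model(w_star)
    beta_eff = w_star * model.dsigma_dw(w_star) / sig
    eps = eps_frac * model.w0
    mult = (division_map(model, w_star + eps) - w_star) / eps
    return float(beta_eff), bool(beta_eff < 1.0), float(mult)


# ---------------------------------------------------------------------------
# lineage simulation with spatial width profiles


def _smooth_profile(
    lengths: np.ndarray, widths: np.ndarray, window: float
) -> np.ndarray:
    """Moving average of the width profile over an axial window."""
    edges = np.concatenate([[0.0], np.cumsum(lengths)])
    mids = 0.5 * (edges[:-1] + edges[1:])
    out = np.empty_like(widths)
    for i, x in enumerate(mids):
        lo, hi = x - window / 2.0, x + window / 2.0
        overlap = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0, None)
        out[i] = np.sum(overlap * widths) / np.sum(overlap)
    return out


def simulate_lineage(
    model: SignalWidthModel,
    w_initial: float,
    n_generations: int,
    mode: str = "monopolar",
    track_both: bool = False,
    n_steps_per_generation: int = 200,
    smooth_over_radius: bool = False,
    width_bounds: tuple[float, float] = (1e-3, 1e3),
) -> list[list[LineageState]]:
    """Grow and divide cells, laying down tip width alpha*sigma_L(w̄, L).

    Cells start as rectangles (uniform width ``w_initial``) of length L0,
    grow to 2 L0 from one or both tips, then divide at mid-length.
    Returns, per generation, the list of tracked cells at birth (one cell
    unless ``track_both``).

    The cell-end convention: segment index 0 is the "new" end created at
    the last division; monopolar growth extends the opposite (old) end.
    """
    if mode not in ("monopolar", "bipolar"):
        raise ValueError("mode must be 'monopolar' or 'bipolar'")
    L0 = model.L0
    cells = [
        LineageState(0, np.array([L0]), np.array([float(w_initial)]))
    ]
    generations: list[list[LineageState]] = [list(cells)]
    for gen in range(1, n_generations + 1):
        next_cells: list[LineageState] = []
        for cell in cells:
            lens = list(cell.seg_lengths)
            wids = list(cell.seg_widths)
            length = cell.birth_length
            area = float(np.sum(cell.seg_lengths * cell.seg_widths))
            dL = L0 / n_steps_per_generation
            for _ in range(n_steps_per_generation):
                w_mean = area / length
                w_tip = model.alpha * model(w_mean, length)
                if not width_bounds[0] < w_tip < width_bounds[1]:
                    raise RuntimeError(
                        f"tip width {w_tip:g} out of bounds at generation {gen}"
                    )
                if mode == "monopolar":
                    lens.append(dL)
                    wids.append(w_tip)
                else:
                    lens.insert(0, dL / 2.0)
                    wids.insert(0, w_tip)
                    lens.append(dL / 2.0)
                    wids.append(w_tip)
                length += dL
                area += dL * w_tip
            lens_arr = np.asarray(lens)
            wids_arr = np.asarray(wids)
            if smooth_over_radius:
                wids_arr = _smooth_profile(
                    lens_arr, wids_arr, window=np.mean(wids_arr) / 2.0
                )
            daughters = _divide(gen, lens_arr, wids_arr)
            next_cells.extend(daughters if track_both else daughters[:1])
        cells = next_cells
        generations.append(list(cells))
    return generations


def _divide(
    gen: int, lengths: np.ndarray, widths: np.ndarray
) -> tuple[LineageState, LineageState]:
    """Split at mid-length; daughter 0 is the half with the growing end."""
    total = lengths.sum()
    edges = np.concatenate([[0.0], np.cumsum(lengths)])
    mid = total / 2.0
    i = int(np.searchsorted(edges, mid) - 1)
    first_l = np.concatenate([lengths[:i], [mid - edges[i]]])
    first_w = np.concatenate([widths[:i], [widths[i]]])
    second_l = np.concatenate([[edges[i + 1] - mid], lengths[i + 1 :]])
    second_w = np.concatenate([[widths[i]], widths[i + 1 :]])
    # new ends face the division plane: reverse the second half so its
    # segment 0 is the new end; the first half's new end is its last segment
    d_old = LineageState(gen, first_l[::-1], first_w[::-1])
    d_new = LineageState(gen, second_l, second_w)
    return d_new, d_old


# ---------------------------------------------------------------------------
# synthetic microtubule tip contacts and the width-curve pipeline


def synth_mt_tips(
    true_sigma_fn: Callable[[float, float], float] | SignalWidthModel,
    cell_diameter: float,
    cell_length: float,
    n_samples: int,
    seed: int,
) -> MTTipSample:
    """Draw meridional tip-contact distances from a half-Gaussian whose
    scale is the ground-truth signal width for this cell shape."""
    scale = float(true_sigma_fn(cell_diameter, cell_length))
    if scale <= 0:
        raise ValueError("true sigma must be positive")
    if n_samples < 50:
        warnings.warn(
            f"n_samples={n_samples} < 50: the histogram fit will be unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    positions = np.abs(rng.normal(0.0, scale, size=n_samples))
    return MTTipSample(cell_diameter, cell_length, positions, seed)


def mt_tip_histogram_fit(
    sample: MTTipSample, bin_width: float | None = None
) -> tuple[float, float]:
    """Least-squares Gaussian fit to the binned contact density.

    Returns (sigma_MT, rms residual of the fit).
    """
    x = sample.contact_positions
    if x.size < 50:
        raise ValueError("need at least 50 contacts to fit")
    if bin_width is None:
        bin_width = np.std(x) / 4.0
    edges = np.arange(0.0, x.max() + bin_width, bin_width)
    if edges.size < 4:
        raise ValueError("degenerate histogram: too few bins")
    density, edges = np.histogram(x, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(xx, amp, sig):
        return amp * np.exp(-0.5 * (xx / sig) ** 2)

    p0 = (density.max(), float(np.std(x)))
    popt, _ = curve_fit(gauss, centers, density, p0=p0, maxfev=10000)
    resid = float(np.sqrt(np.mean((gauss(centers, *popt) - density) ** 2)))
    return float(abs(popt[1])), resid


def synthetic_mt_unfocusing_curve(
    diameters: np.ndarray | None = None,
    cell_length: float = 8.0,
    sigma_floor: float = 0.08,
    slope: float = 0.05,
    spike_amplitude: float = 0.2,
    spike_margin: float = 0.5,
    spike_power: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth sigma_MT(w̄) curve emulating buckling-focused
    microtubule delivery.

    Strong buckling keeps the contact zone narrow at physiological
    diameters (low floor, shallow linear rise); when the diameter becomes
    comparable to the cell length the confinement that aligns microtubules
    is lost and the width spikes sharply.
    """
    if diameters is None:
        # stop at the cell length: beyond it the divergence is unphysical
        diameters = np.linspace(2.0, cell_length, 33)
    diameters = np.asarray(diameters, dtype=float)
    cut = cell_length + spike_margin
    if np.any(diameters >= cut):
        raise ValueError("diameters must stay below length + margin")
    sigma = (
        sigma_floor
        + slope * diameters
        + spike_amplitude / (cut - diameters) ** spike_power
    )
    return diameters, sigma


def _rational_sigma_fit(w: np.ndarray, s: np.ndarray):
    """Least-squares fit of sigma(w) = a + b w + A/(w_c - w).

    A smooth analytic form (linear trend plus an unfocusing divergence)
    whose derivative is noise-robust, unlike a spline through noisy
    points.
    """

    def model(x, a, b, amp, wc):
        return a + b * x + amp / np.clip(wc - x, 1e-6, None)

    span = w[-1] - w[0]
    p0 = (float(s[0]), float((s[-2] - s[0]) / max(span, 1e-9)), 0.1,
          float(w[-1] + 0.2 * span))
    popt, _ = curve_fit(
        model, w, s, p0=p0,
        bounds=([-np.inf, -np.inf, 0.0, w[-1] + 1e-6],
                [np.inf, np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    a, b, amp, wc = popt

    def f(x):
        return a + b * np.asarray(x, float) + amp / (wc - np.asarray(x, float))

    def df(x):
        return b + amp / (wc - np.asarray(x, float)) ** 2

    return f, df


def mt_width_curve_analysis(
    diameters: Sequence[float],
    sigma_mt: Sequence[float],
    alpha: float,
    fit: str = "pchip",
) -> MTWidthCurve:
    """Fit a smooth curve to sigma_MT(w̄), intersect with w̄/alpha, and
    evaluate beta = w̄ sigma' / sigma at the (smallest-diameter)
    intersection.  No intersection in range is reported, not fatal.

    ``fit`` is "pchip" (monotone spline through the points; exact data)
    or "rational" (analytic a + b w + A/(w_c - w); noisy data).
    """
    w = np.asarray(diameters, dtype=float)
    s = np.asarray(sigma_mt, dtype=float)
    if w.size < 5:
        raise ValueError("need at least 5 (diameter, sigma) points")
    order = np.argsort(w)
    w, s = w[order], s[order]
    if fit == "rational":
        spline, dspline = _rational_sigma_fit(w, s)
    elif fit == "pchip":
        interp = PchipInterpolator(w, s, extrapolate=False)
        spline, dspline = interp, interp.derivative()
    else:
        raise ValueError(f"unknown fit {fit!r}")

    def g(x):
        return float(spline(x)) - x / alpha

    grid = np.linspace(w[0], w[-1], 2048)
    vals = np.array([g(x) for x in grid])
    flips = np.flatnonzero(np.diff(np.sign(vals)) != 0)
    if flips.size == 0:
        return MTWidthCurve(w, s, alpha, None, None)
    a, b = grid[flips[0]], grid[flips[0] + 1]
    w_star = float(brentq(g, a, b, xtol=1e-12))
    beta = float(w_star * dspline(w_star) / spline(w_star))
    return MTWidthCurve(w, s, alpha, w_star, beta)


def beta_versus_alpha(
    diameters: Sequence[float],
    sigma_mt: Sequence[float],
    alphas: Sequence[float],
    fit: str = "pchip",
) -> list[MTWidthCurve]:
    """Sweep alpha and collect the intersection and beta per value
    (stability-versus-alpha analysis)."""
    return [mt_width_curve_analysis(diameters, sigma_mt, a, fit=fit) for a in alphas]
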