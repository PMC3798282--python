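"""Five-point finite-difference stencils on uniform grids.

Derivatives on the meridian are taken with the classic five-point central
stencil.  At the tip (index 0) the axisymmetric mirror image of the contour
provides ghost values with the appropriate parity; at the base end one-sided
five-point formulas are used.
"""
from __future__ import annotations

import numpy as np

__all__ = ["deriv5_mirrored", "deriv5_interior"]

# forward one-sided first-derivative coefficients on 5 points
_FWD0 = np.array([-25.0, 48.0, -36.0, 16.0, -3.0]) / 12.0
_FWD1 = np.array([-3.0, -10.0, 18.0, -6.0, 1.0]) / 12.0


def deriv5_mirrored(y: np.ndarray, h: float, parity: int) -> np.ndarray:
    """d/ds of samples ``y`` on a uniform grid with spacing ``h``.

    ``parity`` is +1 if y is an even function of arc length about the tip
    (e.g. the axial coordinate z) and -1 if odd (e.g. the radial coordinate
    rho, or the normal angle phi).  Mirrored ghost nodes make the stencil
    central at the first two points; the last two points use one-sided
    five-point formulas.
    """
    n = y.size
    if n < 7:
        raise ValueError("need at least 7 points for five-point stencils")
    d = np.empty(n)
    ext = np.empty(n + 2)
    if parity > 0:
        ext[0], ext[1] = y[2], y[1]
    else:
        ext[0], ext[1] = -y[2], -y[1]
    ext[2:] = y
    d[: n - 2] = (
        ext[0 : n - 2]
        - 8.0 * ext[1 : n - 1]
        + 8.0 * ext[3 : n + 1]
        - ext[4 : n + 2]
    ) / (12.0 * h)
    d[n - 2] = -np.dot(_FWD1, y[-1:-6:-1]) / h
    d[n - 1] = -np.dot(_FWD0, y[-1:-6:-1]) / h
    return d


def deriv5_interior(y: np.ndarray, h: float) -> np.ndarray:
    """Five-point derivative with one-sided stencils at both ends."""
    n = y.size
    if n < 7:
        raise ValueError("need at least 7 points for five-point stencils")
    d = np.empty(n)
    d[2 : n - 2] = (y[: n - 4] - 8.0 * y[1 : n - 3] + 8.0 * y[3 : n - 1] - y[4:n]) / (
        12.0 * h
    )
    d[0] = np.dot(_FWD0, y[:5]) / h
    d[1] = np.dot(_FWD1, y[:5]) / h
    d[n - 2] = -np.dot(_FWD1, y[-1:-6:-1]) / h
    d[n - 1] = -np.dot(_FWD0, y[-1:-6:-1]) / h
    return d
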