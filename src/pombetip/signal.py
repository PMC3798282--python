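"""Cortical growth-signal profiles Lambda(s).

Lambda(s) is the normalized concentration of the tip growth machinery
(active Cdc42 and effectors) as a function of meridional distance s from
the apex; it sets the local wall-remodeling rate.  Two families are
supported: a Gaussian, and the exponential-power (generalized normal)
family exp(-|s/a|^q), whose shape parameter q tunes the peakedness
(excess kurtosis) of the profile at fixed standard deviation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = [
    "GrowthSignal",
    "InvalidSignalError",
    "KurtosisInfeasibleError",
    "FWHM_PER_SIGMA",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


class InvalidSignalError(ValueError):
    pass


class KurtosisInfeasibleError(ValueError):
    """Requested excess kurtosis outside the exponential-power range."""


def _gnorm_kurtosis(q: float) -> float:
    # excess kurtosis of the generalized normal with shape q
    lg = gammaln
    return float(np.exp(lg(5.0 / q) + lg(1.0 / q) - 2.0 * lg(3.0 / q)) - 3.0)


def _gnorm_sigma_over_a(q: float) -> float:
    lg = gammaln
    return float(np.exp(0.5 * (lg(3.0 / q) - lg(1.0 / q))))


@dataclass(frozen=True)
class GrowthSignal:
    """Normalized growth-signal profile with Lambda(0) = 1.

    Parameters
    ----------
    family : ``"gaussian"`` or ``"exponential_power"``.
    sigma : standard deviation of the profile in micrometres, treating the
        half-profile on s >= 0 as one side of a symmetric density.
    shape_q : exponential-power shape parameter (ignored for the Gaussian;
        q = 2 reproduces it).
    support_cutoff : Lambda level below which the signal is treated as
        exactly zero (the wall there never remodels).
    """

    family: str = "gaussian"
    sigma: float = 1.0
    shape_q: float = 2.0
    support_cutoff: float = 1e-6

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "exponential_power"):
            raise InvalidSignalError(f"unknown signal family {self.family!r}")
        if self.sigma <= 0:
            raise InvalidSignalError("sigma must be positive")
        if self.family == "exponential_power" and self.shape_q <= 0:
            raise InvalidSignalError("shape_q must be positive")

    # -- evaluation -------------------------------------------------------
    @property
    def scale(self) -> float:
        """Scale parameter a of exp(-|s/a|^q) matching the requested sigma."""
        if self.family == "gaussian":
            return self.sigma * np.sqrt(2.0)
        return self.sigma / _gnorm_sigma_over_a(self.shape_q)

    def __call__(self, s: np.ndarray | float) -> np.ndarray:
        s = np.abs(np.asarray(s, dtype=float))
        if self.family == "gaussian":
            lam = np.exp(-0.5 * (s / self.sigma) ** 2)
        else:
            lam = np.exp(-((s / self.scale) ** self.shape_q))
        return np.where(lam < self.support_cutoff, 0.0, lam)

    @property
    def fwhm(self) -> float:
        if self.family == "gaussian":
            return FWHM_PER_SIGMA * self.sigma
        return 2.0 * self.scale * np.log(2.0) ** (1.0 / self.shape_q)

    @property
    def support_radius(self) -> float:
        """Arc distance beyond which Lambda is treated as zero."""
        return self.scale * (-np.log(self.support_cutoff)) ** (
            1.0 / (self.shape_q if self.family == "exponential_power" else 2.0)
        )

    @property
    def excess_kurtosis(self) -> float:
        if self.family == "gaussian":
            return 0.0
        return _gnorm_kurtosis(self.shape_q)

    def with_sigma(self, sigma: float) -> "GrowthSignal":
        return GrowthSignal(self.family, sigma, self.shape_q, self.support_cutoff)

    # -- construction from moments ---------------------------------------
    @classmethod
    def from_kurtosis(
        cls, sigma: float, excess_kurtosis: float, support_cutoff: float = 1e-6
    ) -> "GrowthSignal":
        """Exponential-power profile with prescribed (sigma, excess kurtosis).

        The shape parameter is found by root-finding on the closed-form
        kurtosis of the family (monotone decreasing in q); the scale then
        follows from sigma.  Excess kurtosis 0 recovers the Gaussian q = 2.
        """
        q_lo, q_hi = 0.35, 80.0
        k_hi, k_lo = _gnorm_kurtosis(q_lo), _gnorm_kurtosis(q_hi)
        if not (k_lo < excess_kurtosis < k_hi):
            raise KurtosisInfeasibleError(
                f"excess kurtosis {excess_kurtosis:g} outside attainable "
                f"range ({k_lo:.3f}, {k_hi:.1f})"
            )
        q = brentq(
            lambda qq: _gnorm_kurtosis(qq) - excess_kurtosis, q_lo, q_hi, xtol=1e-12
        )
        return cls("exponential_power", sigma, q, support_cutoff)
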