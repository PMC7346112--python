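"""Lorentzian lineshape primitives shared by the generator and the quantifier.

A 1H NMR absorption line under complete relaxation is modelled as a pure
Lorentzian of full width at half maximum ``fwhm`` (ppm).  Both the synthetic
renderer and the window-integration bookkeeping use the same closed forms, so
peak-area proportionality is exact by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lorentzian", "window_fraction"]


def lorentzian(ppm: np.ndarray, center: float, area: float, fwhm: float) -> np.ndarray:
    """Lorentzian profile with total (infinite-support) integral ``area``.

    Parameters
    ----------
    ppm : array of chemical shifts (any order).
    center : peak position, ppm.
    area : analytic integral over the whole axis, intensity*ppm.
    fwhm : full width at half maximum, ppm (> 0).
    """
    gamma = 0.5 * fwhm  # half width at half maximum
    return (area / np.pi) * gamma / ((ppm - center) ** 2 + gamma**2)


def window_fraction(center: float, lo: float, hi: float, fwhm: float) -> float:
    """Fraction of a Lorentzian's total area falling inside [lo, hi].

    Closed form: (1/pi) * (arctan((hi-c)/g) - arctan((lo-c)/g)), g = fwhm/2.
    This is the truncation factor of a finite integration window and the
    cross-window leakage factor used in overlap corrections.
    """
    if hi < lo:
        raise ValueError(f"empty window [{lo}, {hi}]")
    gamma = 0.5 * fwhm
    return float(np.arctan((hi - center) / gamma) - np.arctan((lo - center) / gamma)) / np.pi
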