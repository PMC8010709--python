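"""Powder-XRD crystallinity metrics for cellulose allomorphs.

Cellulose I shows equatorial reflections near 14.9, 17.1 and 23.0 degrees
2-theta; ammonia-derived cellulose III near 11.8, 17.4 and 20.9 degrees.
The module matches observed peaks against expected allomorph positions,
computes the Segal crystallinity index
CrI = (I_max - I_am) / I_max * 100 from the main crystalline peak and the
amorphous-angle intensity, and estimates crystallite size with the
Scherrer equation size = K lambda / (beta cos theta), beta being the peak
full width at half maximum in radians.  Defaults assume Cu K-alpha
radiation (lambda = 0.15418 nm) and shape factor K = 0.9.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, signal

from .datasets import XrdPattern

__all__ = [
    "CELLULOSE_I_PEAKS",
    "CELLULOSE_III_PEAKS",
    "AMORPHOUS_2THETA",
    "locate_peaks",
    "estimate_fwhm",
    "segal_cri",
    "scherrer_size",
]

CELLULOSE_I_PEAKS = (14.9, 17.1, 23.0)  # (100), (010), (110) reflections
CELLULOSE_III_PEAKS = (11.8, 17.4, 20.9)  # (010), (002), (100) reflections

# Segal amorphous angles; cellulose III has no established convention, the
# 16.0 deg default is a configurable package choice
AMORPHOUS_2THETA = {"cellulose_I": 18.0, "cellulose_III": 16.0}

CU_K_ALPHA_NM = 0.15418
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def locate_peaks(pattern: XrdPattern, expected_positions, window: float = 1.0,
                 min_prominence: float = 0.02) -> dict:
    """Match local intensity maxima to expected 2-theta positions.

    For each expected position the highest local maximum within +-window
    degrees is reported; positions with no local maximum in their window
    are listed in ``missing``.  ``min_prominence`` (as a fraction of the
    pattern's intensity range) screens out counting-noise bumps.
    """
    if len(pattern) == 0:
        raise ValueError("empty pattern")
    tt, I = pattern.two_theta, pattern.intensity
    lo, hi = tt[0], tt[-1]
    for p in expected_positions:
        if not lo <= p <= hi:
            raise ValueError(f"expected position {p} deg outside grid [{lo}, {hi}]")
    idx_max, _ = signal.find_peaks(I, prominence=min_prominence * max(np.ptp(I), 1e-12))
    matched, missing = {}, []
    for p in expected_positions:
        cand = idx_max[np.abs(tt[idx_max] - p) <= window]
        if cand.size == 0:
            missing.append(float(p))
            continue
        best = cand[np.argmax(I[cand])]
        matched[float(p)] = {"position": float(tt[best]), "height": float(I[best])}
    return {"matched": matched, "missing": missing}


def estimate_fwhm(pattern: XrdPattern, peak_2theta: float, window: float = 1.5) -> float:
    """FWHM (degrees) of a reflection by a local Gaussian-plus-offset fit.

    A Gaussian with constant background is fitted within +-window degrees
    of the peak; more noise-robust than raw half-height crossings.
    """
    tt, I = pattern.two_theta, pattern.intensity
    sel = np.abs(tt - peak_2theta) <= window
    if sel.sum() < 5:
        raise ValueError("too few grid points around the peak")
    x, y = tt[sel], I[sel]

    def gauss(t, amp, mu, sigma, c):
        return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2) + c

    p0 = [float(y.max() - y.min()), float(x[np.argmax(y)]),
          max(window / 4.0, 0.05), float(y.min())]
    popt, _ = optimize.curve_fit(gauss, x, y, p0=p0, maxfev=20000)
    return float(abs(popt[2]) / _FWHM_TO_SIGMA)


def segal_cri(pattern: XrdPattern, crystalline_peak_2theta: float,
              amorphous_2theta: float) -> float:
    """Segal crystallinity index, percent.

    CrI = (I_max - I_am) / I_max * 100 with I_max the intensity at the main
    crystalline reflection and I_am the intensity at the amorphous angle.
    """
    tt, I = pattern.two_theta, pattern.intensity
    lo, hi = tt[0], tt[-1]
    for angle in (crystalline_peak_2theta, amorphous_2theta):
        if not lo <= angle <= hi:
            raise ValueError(f"angle {angle} deg outside grid [{lo}, {hi}]")
    i_max = float(I[np.argmin(np.abs(tt - crystalline_peak_2theta))])
    i_am = float(I[np.argmin(np.abs(tt - amorphous_2theta))])
    if i_max <= 0:
        raise ValueError("crystalline-peak intensity must be positive")
    if i_am > i_max:
        raise ValueError("amorphous intensity exceeds peak intensity (non-physical)")
    return (i_max - i_am) / i_max * 100.0


def scherrer_size(two_theta: float, fwhm: float,
                  wavelength: float = CU_K_ALPHA_NM, K: float = 0.9) -> float:
    """Scherrer crystallite size (nm) from a reflection's FWHM (degrees)."""
    if not 0 < two_theta < 180:
        raise ValueError("two_theta must lie in (0, 180) degrees")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive (zero implies infinite size)")
    beta = np.deg2rad(fwhm)
    theta = np.deg2rad(two_theta / 2.0)
    return float(K * wavelength / (beta * np.cos(theta)))
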