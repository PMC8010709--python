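"""FRAP and QCM-D binding-kinetics analysis.

FRAP recovery is fitted with the reaction-dominated (binding-dominated)
model, which ignores diffusive transport and treats recovery as exchange of
bleached for unbleached protein at the desorption rate:

    I(t) = baseline + F_M * (1 - exp(-k_off * t))

where k_off (s^-1) is the desorption rate constant and F_M the reversibly
bound (mobile) fraction.

QCM-D sensorgrams are fitted with Langmuir adsorption kinetics.  During
the adsorption phase the surface coverage relaxes at the observed rate
k_on* + k_off toward Gamma_eq = A k_on*/(k_on* + k_off); during the buffer
rinse it decays as a pure exponential at k_off.  k_on* is a pseudo-first-
order adsorption rate (true k_on times the free protein concentration), so
only the rinse phase separates k_on* from k_off.  Frequency shifts are
converted to areal mass with the Sauerbrey relation delta_m = -C delta_f/n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .datasets import KineticCurve

__all__ = [
    "AVOGADRO",
    "SAUERBREY_C",
    "FrapFit",
    "QcmdFit",
    "FrapRecoveryModel",
    "QcmdKineticsModel",
    "fit_frap",
    "frap_fold_change",
    "sauerbrey_mass",
    "mass_to_molecules",
    "fit_qcmd",
]

AVOGADRO = 6.02214076e23  # mol^-1
SAUERBREY_C = 17.7  # ng cm^-2 Hz^-1, 5 MHz AT-cut quartz sensor


@dataclass
class FrapFit:
    """Fitted binding-dominated FRAP recovery."""

    k_off: float
    F_M: float
    baseline: float
    std_errors: dict = field(default_factory=dict)
    converged: bool = False
    identifiable: bool = True

    def to_dict(self) -> dict:
        return {
            "k_off": float(self.k_off),
            "F_M": float(self.F_M),
            "baseline": float(self.baseline),
            "std_errors": {k: float(v) for k, v in self.std_errors.items()},
            "converged": bool(self.converged),
            "identifiable": bool(self.identifiable),
        }


@dataclass
class QcmdFit:
    """Fitted Langmuir QCM-D kinetics.

    A is the number of bound molecules at full saturation; k_on_star the
    pseudo-adsorption rate (s^-1); k_off the desorption rate (s^-1).
    ``separable`` is False when no rinse phase was available, in which case
    only the relaxation sum k_obs = k_on* + k_off is identified.
    """

    k_on_star: float
    k_off: float
    A: float
    std_errors: dict = field(default_factory=dict)
    converged: bool = False
    separable: bool = True
    k_obs: float | None = None

    def gamma_eq(self) -> float:
        return self.A * self.k_on_star / (self.k_on_star + self.k_off)

    def to_dict(self) -> dict:
        return {
            "k_on_star": float(self.k_on_star),
            "k_off": float(self.k_off),
            "A": float(self.A),
            "std_errors": {k: float(v) for k, v in self.std_errors.items()},
            "converged": bool(self.converged),
            "separable": bool(self.separable),
            "k_obs": None if self.k_obs is None else float(self.k_obs),
        }


# ---------------------------------------------------------------------------
# Sauerbrey conversion
# ---------------------------------------------------------------------------


def sauerbrey_mass(delta_f, overtone: int = 3, C: float = SAUERBREY_C):
    """Areal mass (ng/cm^2) from a frequency shift via delta_m = -C delta_f / n.

    A negative frequency shift corresponds to adsorption (positive mass);
    a positive shift yields negative mass, i.e. net desorption.
    """
    if overtone <= 0 or overtone % 2 == 0:
        raise ValueError("overtone must be an odd positive integer")
    return -C * np.asarray(delta_f, float) / overtone if np.ndim(delta_f) else -C * float(delta_f) / overtone


def mass_to_molecules(areal_mass, area: float, molar_mass: float):
    """Molecule count from areal mass (ng/cm^2), sensor area (cm^2), and
    molar mass (g/mol)."""
    if area <= 0:
        raise ValueError("area must be positive")
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    total_ng = np.asarray(areal_mass, float) * area
    count = total_ng * 1e-9 * AVOGADRO / molar_mass
    return float(count) if np.ndim(areal_mass) == 0 else count


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------


class FrapRecoveryModel(BaseEstimator):
    """Nonlinear fit of the binding-dominated FRAP recovery model.

    Attributes after ``fit``: ``k_off_``, ``F_M_``, ``baseline_``,
    ``std_errors_``, ``converged_``, ``identifiable_``.  A non-recovering
    curve (fitted F_M ~ 0) leaves k_off flagged non-identifiable.
    """

    def __init__(self, f_m_floor: float = 1e-3):
        self.f_m_floor = f_m_floor

    def fit(self, curve: KineticCurve, y=None):
        t = np.asarray(curve.time, float)
        I = np.asarray(curve.signal, float)
        if t.size < 10:
            raise ValueError("need >= 10 post-bleach samples")

        def model(tt, baseline, F_M, k_off):
            return baseline + F_M * (1.0 - np.exp(-k_off * tt))

        span = float(I[-1] - I[0])
        half = I[0] + 0.5 * span
        idx = np.argmax(I >= half) if span > 0 else 1
        t_half = t[idx] if t[idx] > 0 else (t[1] if t.size > 1 else 1.0)
        p0 = [float(I[0]), float(np.clip(abs(span), 1e-3, 1.0)), np.log(2.0) / t_half]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    model, t, I, p0=p0,
                    bounds=([-np.inf, 0.0, 1e-12], [np.inf, 1.0, np.inf]),
                    maxfev=20000,
                )
            converged = True
        except (RuntimeError, ValueError):
            popt = np.array([float(np.mean(I)), 0.0, np.nan])
            pcov = np.full((3, 3), np.nan)
            converged = False
        se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        self.baseline_, self.F_M_, self.k_off_ = (float(v) for v in popt)
        self.std_errors_ = {"baseline": se[0], "F_M": se[1], "k_off": se[2]}
        self.identifiable_ = bool(self.F_M_ > self.f_m_floor)
        self.converged_ = bool(converged and np.all(np.isfinite(se)))
        return self

    def predict(self, t):
        t = np.asarray(t, float)
        return self.baseline_ + self.F_M_ * (1.0 - np.exp(-self.k_off_ * t))

    def result_(self) -> FrapFit:
        return FrapFit(
            k_off=self.k_off_,
            F_M=self.F_M_,
            baseline=self.baseline_,
            std_errors=dict(self.std_errors_),
            converged=self.converged_,
            identifiable=self.identifiable_,
        )


def fit_frap(curve: KineticCurve) -> FrapFit:
    """Fit I(t) = baseline + F_M (1 - e^{-k_off t}) to a recovery curve."""
    return FrapRecoveryModel().fit(curve).result_()


def frap_fold_change(fit_a: FrapFit, fit_b: FrapFit) -> float:
    """Desorption-rate fold change k_off(b) / k_off(a)."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both FRAP fits must have converged")
    if not (fit_a.identifiable and fit_b.identifiable):
        raise ValueError("k_off non-identifiable in at least one fit")
    return float(fit_b.k_off / fit_a.k_off)


# ---------------------------------------------------------------------------
# QCM-D
# ---------------------------------------------------------------------------


class QcmdKineticsModel(BaseEstimator):
    """Joint Langmuir-kinetics fit of a QCM-D adsorption + rinse sensorgram.

    The frequency-shift curve is converted to a molecule-count coverage via
    the Sauerbrey relation, then both phases are fitted jointly:
    adsorption Gamma(t) = Gamma_eq (1 - e^{-(k_on*+k_off) t}) and rinse
    Gamma(t) = Gamma(t_rinse) e^{-k_off (t - t_rinse)}.  Without a rinse
    phase only k_obs = k_on* + k_off is identifiable and the fit is flagged
    non-separable.

    Parameters
    ----------
    overtone : odd int
        Harmonic at which delta-f was recorded (default 3).
    C : float
        Sauerbrey constant, ng cm^-2 Hz^-1.
    molar_mass : float
        Molar mass of the adsorbing protein (g/mol); required to express
        the saturation amplitude A in molecules.
    area : float
        Active sensor area in cm^2.
    """

    def __init__(
        self,
        overtone: int = 3,
        C: float = SAUERBREY_C,
        molar_mass: float = 45000.0,
        area: float = 1.0,
    ):
        self.overtone = overtone
        self.C = C
        self.molar_mass = molar_mass
        self.area = area

    def _coverage(self, curve: KineticCurve) -> np.ndarray:
        n = curve.overtone or self.overtone
        mass = sauerbrey_mass(curve.signal, overtone=n, C=self.C)
        return mass_to_molecules(mass, self.area, self.molar_mass)

    def fit(self, curve: KineticCurve, phase_boundaries=None):
        t = np.asarray(curve.time, float)
        gamma = self._coverage(curve)
        if phase_boundaries is None or not len(phase_boundaries):
            raise ValueError(
                "phase_boundaries=(t_rinse,) is required to identify the phases"
            )
        t_rinse = float(phase_boundaries[0])
        ads = t < t_rinse
        rinse = ~ads
        if not np.any(ads):
            # rinse only: k_off from pure exponential decay
            k_off, _ = self._fit_decay(t[rinse] - t[rinse][0], gamma[rinse])
            self.k_on_star_ = np.nan
            self.k_off_ = k_off
            self.A_ = np.nan
            self.k_obs_ = np.nan
            self.std_errors_ = {}
            self.separable_ = False
            self.converged_ = True
            return self
        if not np.any(rinse):
            # adsorption only: Gamma_eq and k_obs identifiable, rates are not
            k_obs, g_eq = self._fit_rise(t[ads], gamma[ads])
            self.k_on_star_ = np.nan
            self.k_off_ = np.nan
            self.A_ = np.nan
            self.k_obs_ = k_obs
            self.gamma_eq_ = g_eq
            self.std_errors_ = {}
            self.separable_ = False
            self.converged_ = True
            return self

        # joint fit of both phases in (A, k_on*, k_off)
        k_obs0, g_eq0 = self._fit_rise(t[ads], gamma[ads])
        k_off0, _ = self._fit_decay(t[rinse] - t_rinse, gamma[rinse])
        k_off0 = float(np.clip(k_off0, 1e-8, 0.99 * k_obs0))
        k_on0 = max(k_obs0 - k_off0, 1e-8)
        A0 = g_eq0 * k_obs0 / k_on0

        def model(theta):
            A, k_on, k_off = theta
            k_obs = k_on + k_off
            g_eq = A * k_on / k_obs
            g = np.where(
                ads,
                g_eq * (1.0 - np.exp(-k_obs * t)),
                g_eq * (1.0 - np.exp(-k_obs * t_rinse))
                * np.exp(-k_off * np.clip(t - t_rinse, 0, None)),
            )
            return g

        scale = max(abs(gamma).max(), 1.0)

        def resid(theta):
            return (model(theta) - gamma) / scale

        sol = optimize.least_squares(
            resid, x0=[A0, k_on0, k_off0],
            bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        A, k_on, k_off = sol.x
        # covariance from the Jacobian at the optimum
        dof = max(t.size - 3, 1)
        try:
            JTJ = sol.jac.T @ sol.jac
            cov = np.linalg.pinv(JTJ) * 2 * sol.cost / dof
            se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(3, np.nan)
        self.A_ = float(A)
        self.k_on_star_ = float(k_on)
        self.k_off_ = float(k_off)
        self.k_obs_ = float(k_on + k_off)
        self.std_errors_ = {"A": se[0], "k_on_star": se[1], "k_off": se[2]}
        self.separable_ = True
        self.converged_ = bool(sol.success)
        return self

    @staticmethod
    def _fit_decay(t, g):
        """Log-linear estimate of a pure exponential decay rate."""
        g = np.asarray(g, float)
        pos = g > 0
        if pos.sum() < 2:
            return np.nan, g
        slope = np.polyfit(t[pos], np.log(g[pos]), 1)[0]
        return float(max(-slope, 1e-12)), g

    @staticmethod
    def _fit_rise(t, g):
        """Single-exponential rise: returns (rate, plateau)."""
        g_eq0 = float(g[-1]) if g[-1] != 0 else float(np.max(np.abs(g)) + 1e-12)

        def f(tt, g_eq, k):
            return g_eq * (1.0 - np.exp(-k * tt))

        t_half = t[np.argmax(g >= 0.5 * g_eq0)] if np.any(g >= 0.5 * g_eq0) else t[-1] / 2
        k0 = np.log(2.0) / max(t_half, t[1] if t.size > 1 else 1.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(f, t, g, p0=[g_eq0, k0], maxfev=20000)
            return float(popt[1]), float(popt[0])
        except (RuntimeError, ValueError):
            return float(k0), g_eq0

    def result_(self) -> QcmdFit:
        return QcmdFit(
            k_on_star=self.k_on_star_,
            k_off=self.k_off_,
            A=self.A_,
            std_errors=dict(self.std_errors_),
            converged=self.converged_,
            separable=self.separable_,
            k_obs=self.k_obs_,
        )


def fit_qcmd(
    sensorgram: KineticCurve,
    phase_boundaries,
    overtone: int = 3,
    C: float = SAUERBREY_C,
    molar_mass: float = 45000.0,
    area: float = 1.0,
) -> QcmdFit:
    """Fit Langmuir kinetics to an adsorption + rinse sensorgram.

    ``phase_boundaries`` is (t_rinse,): the time at which the buffer rinse
    starts.  Pass the full sensorgram; samples at t >= t_rinse form the
    desorption phase.
    """
    est = QcmdKineticsModel(
        overtone=overtone, C=C, molar_mass=molar_mass, area=area
    ).fit(sensorgram, phase_boundaries)
    return est.result_()
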