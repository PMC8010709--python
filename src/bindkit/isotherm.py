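"""Equilibrium adsorption-isotherm models and diagnostics.

Implements the three phenomenological models routinely fitted to
protein-polysaccharide pull-down (solid depletion) assay data:

* Langmuir one-site:      B = n_max * F / (K_d + F)
* Langmuir two-site:      B = sum of two independent one-site terms
* Langmuir-Freundlich:    B = n_max * F**m / (K_d**m + F**m)

with F the free protein concentration (uM) and B the bound amount
(umol protein / g cellulose).  The Langmuir-Freundlich form is chosen so
that K_d keeps concentration units and F = K_d gives half-saturation.

Alongside the nonlinear fits the module provides the partition coefficient
(initial slope of B vs F, equal to n_max/K_d in the one-site low-concentration
limit), dataset truncation sensitivity analysis, Scatchard-plot curvature as a
multi-site diagnostic, and affinity fold changes between substrates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .datasets import AdsorptionDataset

__all__ = [
    "IsothermParams",
    "IsothermFitResult",
    "IsothermRegressor",
    "MODELS",
    "eval_isotherm",
    "fit_isotherm",
    "partition_coefficient",
    "truncate_and_fit",
    "scatchard_diagnostic",
    "affinity_fold_change",
]

MODELS = ("one_site", "two_site", "langmuir_freundlich")

# parameter names per model, in optimizer order
_PARAM_NAMES = {
    "one_site": ("n_max", "K_d"),
    "two_site": ("n_max", "K_d", "n_max_2", "K_d_2"),
    "langmuir_freundlich": ("n_max", "K_d", "m"),
}


@dataclass
class IsothermParams:
    """Parameters of an adsorption isotherm.

    n_max is the binding-site capacity (umol/g), K_d the dissociation
    constant (uM).  Two-site models carry a second (n_max_2, K_d_2) pair;
    by convention site 1 is the low-affinity site (K_d >= K_d_2).  The
    Freundlich exponent m (dimensionless, 0 < m <= 2) applies only to the
    Langmuir-Freundlich model.
    """

    n_max: float
    K_d: float
    n_max_2: float | None = None
    K_d_2: float | None = None
    m: float | None = None

    def validate(self, model_id: str) -> None:
        if self.n_max <= 0 or self.K_d <= 0:
            raise ValueError("n_max and K_d must be positive")
        if model_id == "two_site":
            if self.n_max_2 is None or self.K_d_2 is None:
                raise ValueError("two_site model requires n_max_2 and K_d_2")
            if self.n_max_2 <= 0 or self.K_d_2 <= 0:
                raise ValueError("n_max_2 and K_d_2 must be positive")
        if model_id == "langmuir_freundlich":
            if self.m is None:
                raise ValueError("langmuir_freundlich model requires m")
            if not 0 < self.m <= 2:
                raise ValueError("m must lie in (0, 2]")

    def total_capacity(self) -> float:
        return self.n_max + (self.n_max_2 or 0.0)

    def to_vector(self, model_id: str) -> np.ndarray:
        return np.array([getattr(self, k) for k in _PARAM_NAMES[model_id]], float)

    @classmethod
    def from_vector(cls, model_id: str, theta) -> "IsothermParams":
        return cls(**dict(zip(_PARAM_NAMES[model_id], np.asarray(theta, float))))


@dataclass
class IsothermFitResult:
    """Fitted isotherm with per-parameter standard errors and RMSE."""

    model_id: str
    params: IsothermParams
    std_errors: dict = field(default_factory=dict)
    rmse: float = float("nan")
    converged: bool = False
    n_points: int = 0

    def to_dict(self) -> dict:
        p = {
            k: getattr(self.params, k)
            for k in ("n_max", "K_d", "n_max_2", "K_d_2", "m")
            if getattr(self.params, k) is not None
        }
        return {
            "model_id": self.model_id,
            "params": {k: float(v) for k, v in p.items()},
            "std_errors": {k: float(v) for k, v in self.std_errors.items()},
            "rmse": float(self.rmse),
            "converged": bool(self.converged),
            "n_points": int(self.n_points),
        }


def _eval(model_id: str, theta: np.ndarray, F: np.ndarray) -> np.ndarray:
    if model_id == "one_site":
        n_max, K_d = theta
        return n_max * F / (K_d + F)
    if model_id == "two_site":
        n1, K1, n2, K2 = theta
        return n1 * F / (K1 + F) + n2 * F / (K2 + F)
    if model_id == "langmuir_freundlich":
        n_max, K_d, m = theta
        with np.errstate(divide="ignore", invalid="ignore"):
            Fm = np.power(F, m)
            out = n_max * Fm / (K_d**m + Fm)
        return np.where(F == 0, 0.0, out)
    raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODELS}")


def eval_isotherm(model_id: str, params: IsothermParams, F) -> np.ndarray | float:
    """Evaluate an isotherm model at free concentration(s) F (uM)."""
    if model_id not in _PARAM_NAMES:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODELS}")
    params.validate(model_id)
    F_arr = np.asarray(F, dtype=float)
    if np.any(F_arr < 0):
        raise ValueError("free concentration must be >= 0")
    out = _eval(model_id, params.to_vector(model_id), F_arr)
    return float(out) if np.isscalar(F) else out


class IsothermRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares adsorption-isotherm estimator.

    Fits one of the three Langmuir-type models by unweighted least squares
    with multi-start initialization (K_d starts log-spaced over the observed
    concentration range) and best-RMSE selection.  For the two-site model
    the sites are ordered so K_d >= K_d_2 (low-affinity site first) to break
    label-switching ties.

    Parameters
    ----------
    model : {"one_site", "two_site", "langmuir_freundlich"}
    n_starts : int
        Number of log-spaced K_d starting values (default 8).

    Attributes
    ----------
    params_ : IsothermParams
    std_errors_ : dict
        Standard errors from the covariance at the optimum (empty when the
        fit did not converge).
    rmse_ : float
    converged_ : bool
    n_points_ : int
    """

    def __init__(self, model: str = "one_site", n_starts: int = 8):
        self.model = model
        self.n_starts = n_starts

    # -- internal helpers -------------------------------------------------

    def _starts(self, F: np.ndarray, B: np.ndarray) -> list[np.ndarray]:
        Fpos = F[F > 0]
        lo = max(Fpos.min() / 4.0, 1e-3)
        hi = max(Fpos.max() * 4.0, lo * 10)
        kd_grid = np.geomspace(lo, hi, self.n_starts)
        n0 = max(B.max(), 1e-6) * 1.2
        starts = []
        for kd in kd_grid:
            if self.model == "one_site":
                starts.append(np.array([n0, kd]))
            elif self.model == "two_site":
                # pair a high-K_d and a low-K_d site around each start
                starts.append(np.array([0.8 * n0, kd, 0.2 * n0, kd / 50.0]))
            else:
                starts.append(np.array([n0, kd, 0.8]))
        return starts

    def fit(self, F, B=None):
        """Fit the model to free (F, uM) and bound (B, umol/g) data.

        Accepts either ``fit(dataset)`` with an :class:`AdsorptionDataset`
        or ``fit(F, B)`` with paired arrays.
        """
        if isinstance(F, AdsorptionDataset):
            dataset = F
            F, B = dataset.free, dataset.bound
        F = np.asarray(F, float).ravel()
        B = np.asarray(B, float).ravel()
        if F.shape != B.shape:
            raise ValueError("F and B must have equal length")
        names = _PARAM_NAMES.get(self.model)
        if names is None:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        n_par = len(names)
        if F.size < 2 * n_par:
            raise ValueError(
                f"need at least {2 * n_par} points to fit {self.model} ({F.size} given)"
            )
        if np.allclose(B, 0):
            raise ValueError("all bound values are zero: isotherm non-identifiable")
        if np.ptp(B) < 1e-12 * max(abs(B).max(), 1.0):
            raise ValueError("bound values are constant: isotherm non-identifiable")

        lower = np.full(n_par, 1e-12)
        upper = np.full(n_par, np.inf)
        if self.model == "langmuir_freundlich":
            upper[2] = 2.0

        model_id = self.model

        def f(x, *theta):
            return _eval(model_id, np.asarray(theta), x)

        best = None
        for theta0 in self._starts(F, B):
            theta0 = np.clip(theta0, lower + 1e-12, np.where(np.isinf(upper), theta0, upper))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = optimize.curve_fit(
                        f, F, B, p0=theta0, bounds=(lower, upper), maxfev=20000
                    )
            except (RuntimeError, ValueError):
                continue
            resid = B - f(F, *popt)
            rmse = float(np.sqrt(np.mean(resid**2)))
            if best is None or rmse < best[2]:
                best = (popt, pcov, rmse)

        self.n_points_ = F.size
        if best is None:
            self.params_ = None
            self.std_errors_ = {}
            self.rmse_ = float("nan")
            self.converged_ = False
            return self

        popt, pcov, rmse = best
        if self.model == "two_site" and popt[1] < popt[3]:
            order = [2, 3, 0, 1]
            popt = popt[order]
            pcov = pcov[np.ix_(order, order)]
        se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        self.params_ = IsothermParams.from_vector(self.model, popt)
        self.std_errors_ = dict(zip(names, se))
        self.covariance_ = pcov
        self.rmse_ = rmse
        self.converged_ = bool(np.all(np.isfinite(se)))
        return self

    def predict(self, F):
        if getattr(self, "params_", None) is None:
            raise RuntimeError("estimator is not fitted or did not converge")
        return _eval(self.model, self.params_.to_vector(self.model), np.asarray(F, float))

    def result_(self) -> IsothermFitResult:
        """Package the fitted state as an :class:`IsothermFitResult`."""
        return IsothermFitResult(
            model_id=self.model,
            params=self.params_,
            std_errors=dict(self.std_errors_) if self.converged_ else {},
            rmse=self.rmse_,
            converged=self.converged_,
            n_points=self.n_points_,
        )


def fit_isotherm(
    dataset: AdsorptionDataset, model_id: str = "one_site", n_starts: int = 8
) -> IsothermFitResult:
    """Fit an adsorption model to a dataset; non-convergence is flagged,
    not raised."""
    est = IsothermRegressor(model=model_id, n_starts=n_starts).fit(dataset)
    if est.params_ is None:
        return IsothermFitResult(
            model_id=model_id, params=IsothermParams(np.nan, np.nan),
            rmse=float("nan"), converged=False, n_points=len(dataset),
        )
    return est.result_()


def partition_coefficient(dataset: AdsorptionDataset, max_free: float) -> dict:
    """Initial-slope partition coefficient (L/g) from the low-concentration
    linear region.

    Ordinary least-squares slope through the origin of bound vs free,
    restricted to points with free <= ``max_free`` uM.  For one-site
    Langmuir data the slope converges to n_max/K_d as max_free -> 0.
    """
    mask = dataset.free <= max_free
    F, B = dataset.free[mask], dataset.bound[mask]
    if F.size < 3:
        raise ValueError(
            f"need >= 3 points with free <= {max_free} uM, found {F.size}"
        )
    sxx = float(np.sum(F * F))
    if sxx == 0:
        raise ValueError("all selected free concentrations are zero")
    slope = float(np.sum(F * B) / sxx)
    resid = B - slope * F
    dof = max(F.size - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return {"slope": slope, "se": se, "n": int(F.size)}


def truncate_and_fit(
    dataset: AdsorptionDataset, cutoffs, model_id: str = "one_site"
) -> list[IsothermFitResult]:
    """Full-data fit followed by one fit per truncation cutoff (F <= cutoff).

    Mirrors the sensitivity analysis in which pull-down datasets are trimmed
    to progressively lower maximum free concentrations to expose how poorly
    constrained n_max and K_d become without the saturation plateau.
    """
    cutoffs = [float(c) for c in cutoffs]
    if any(c <= 0 for c in cutoffs):
        raise ValueError("cutoffs must be positive")
    results = [fit_isotherm(dataset, model_id)]
    for c in cutoffs:
        results.append(fit_isotherm(dataset.truncated(c), model_id))
    return results


def scatchard_diagnostic(dataset: AdsorptionDataset) -> dict:
    """Scatchard-plot curvature as a multiple-binding-site diagnostic.

    Plots B/F against B and fits a quadratic.  A single-site Langmuir gives
    an exactly linear Scatchard plot; concave-up curvature (positive
    quadratic coefficient) indicates multiple classes of sites or overlapping
    sites.  Points with F = 0 are excluded with a warning.
    """
    F, B = dataset.free, dataset.bound
    if np.any(F == 0):
        warnings.warn("excluding points with free concentration = 0 from Scatchard plot")
        keep = F > 0
        F, B = F[keep], B[keep]
    if F.size < 4:
        raise ValueError("need >= 4 points with F > 0 for the quadratic Scatchard fit")
    ratio = B / F
    design = np.column_stack([B**2, B, np.ones_like(B)])
    coef, res, rank, _ = np.linalg.lstsq(design, ratio, rcond=None)
    dof = F.size - 3
    if dof > 0 and res.size:
        sigma2 = float(res[0]) / dof
    else:
        sigma2 = float(np.sum((ratio - design @ coef) ** 2) / max(dof, 1))
    cov = sigma2 * np.linalg.pinv(design.T @ design)
    se_quad = float(np.sqrt(max(cov[0, 0], 0.0)))
    quad = float(coef[0])
    if se_quad > 0 and abs(quad) < 2 * se_quad:
        sign = 0
    else:
        sign = int(np.sign(quad))
    return {
        "points": np.column_stack([B, ratio]),
        "quadratic_coef": quad,
        "quadratic_se": se_quad,
        "curvature_sign": sign,
    }


def affinity_fold_change(
    fit_a: IsothermFitResult, fit_b: IsothermFitResult, site: str = "primary"
) -> float:
    """Fold change K_d(b) / K_d(a) for the selected site.

    ``site`` is "primary" (n_max/K_d pair; the low-affinity site in the
    two-site convention) or "high_affinity" (the K_d_2 site of a two-site
    fit).  A ratio > 1 means substrate b binds more weakly.
    """
    if fit_a.model_id != fit_b.model_id:
        raise ValueError(
            f"cannot compare fits of different models "
            f"({fit_a.model_id!r} vs {fit_b.model_id!r})"
        )
    if site == "primary":
        return float(fit_b.params.K_d / fit_a.params.K_d)
    if site == "high_affinity":
        if fit_a.params.K_d_2 is None or fit_b.params.K_d_2 is None:
            raise ValueError("high_affinity site requires two-site fits")
        return float(fit_b.params.K_d_2 / fit_a.params.K_d_2)
    raise ValueError("site must be 'primary' or 'high_affinity'")
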