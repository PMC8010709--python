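"""Force-binned bond-lifetime analysis of single-bond rupture events.

A slip bond (Bell model) has force-dependent mean lifetime
tau(F) = tau0 * exp(-F * x_dagger / kBT), with tau0 the zero-force lifetime
and x_dagger the distance to the transition state.  Rupture events are
pooled, binned at 2.5-pN intervals, and the per-bin mean lifetimes are
fitted by weighted least squares (weights 1/SEM^2).  Deviations from a
single-exponential lifetime distribution — the signature of multiple
binding modes — are tested with exponential-mixture EM fits whose order is
selected by sequential parametric-bootstrap likelihood-ratio tests, and
one-way ANOVA compares lifetime samples across force bins or substrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .datasets import RuptureEventSet

__all__ = [
    "ForceBinSummary",
    "BellFit",
    "BellSlipBondModel",
    "ExponentialMixture",
    "summarize_lifetime",
    "standard_error_of_mean",
    "bin_events",
    "fit_bell_slip",
    "exponential_mixture_test",
    "anova_bins",
]

KBT_298K = 4.114  # pN nm


@dataclass
class ForceBinSummary:
    """Per-force-bin lifetime statistics on half-open bins [lo, hi)."""

    bin_edges: np.ndarray  # len n_bins + 1
    n: np.ndarray
    mean_lifetime: np.ndarray
    sem: np.ndarray  # nan where n < 2

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1


@dataclass
class BellFit:
    """Fitted Bell slip-bond parameters."""

    tau0: float  # s
    x_dagger: float  # nm
    kBT: float  # pN nm
    covariance: np.ndarray = None
    std_errors: dict = field(default_factory=dict)
    converged: bool = False

    def lifetime(self, force) -> np.ndarray:
        return self.tau0 * np.exp(-np.asarray(force, float) * self.x_dagger / self.kBT)


def summarize_lifetime(events: RuptureEventSet) -> dict:
    """Mean, SD, and SEM of bond lifetimes.

    SEM = SD / sqrt(N); with a single event the SEM is undefined and
    returned as NaN with ``sem_defined`` False.
    """
    life = events.lifetime
    n = life.size
    if n == 0:
        raise ValueError("empty event set")
    mean = float(np.mean(life))
    if n == 1:
        return {"mean": mean, "sd": float("nan"), "sem": float("nan"),
                "n": 1, "sem_defined": False}
    sd = float(np.std(life, ddof=1))
    return {"mean": mean, "sd": sd, "sem": sd / np.sqrt(n), "n": int(n),
            "sem_defined": True}


def standard_error_of_mean(sd: float, n: int) -> float:
    """SEM from a sample SD and size: SD / sqrt(n)."""
    if n < 2:
        raise ValueError("SEM undefined for n < 2")
    return float(sd) / np.sqrt(n)


def bin_events(events: RuptureEventSet, width: float = 2.5,
               force_range: tuple | None = None) -> ForceBinSummary:
    """Bin rupture events on half-open force intervals [lo, lo+width), ...

    An event whose force equals an interior edge goes to the upper bin.
    Events outside ``force_range`` are excluded; bin counts therefore sum
    to the number of in-range events.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    if len(events) == 0:
        raise ValueError("empty event set")
    f = events.force
    life = events.lifetime
    if force_range is None:
        lo = 0.0
        hi = float(np.ceil((f.max() + 1e-12) / width) * width)
        if hi <= lo:
            hi = lo + width
    else:
        lo, hi = map(float, force_range)
    n_bins = int(np.round((hi - lo) / width))
    idx = np.floor((f - lo) / width).astype(int)
    in_range = (idx >= 0) & (idx < n_bins)
    idx, life_in = idx[in_range], life[in_range]
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=life_in, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    sems = np.full(n_bins, np.nan)
    for b in range(n_bins):
        if counts[b] >= 2:
            sems[b] = np.std(life_in[idx == b], ddof=1) / np.sqrt(counts[b])
    edges = lo + width * np.arange(n_bins + 1)
    return ForceBinSummary(edges, counts, means, sems)


class BellSlipBondModel(BaseEstimator):
    """Weighted Bell-model fit of mean lifetime vs force.

    Fits tau(F) = tau0 exp(-F x_dagger / kBT) to the per-bin mean lifetimes
    with weights 1/SEM^2, in linear lifetime space by default (``space=
    'log'`` fits log tau linearly for comparison).  Bins with fewer than
    ``min_bin_n`` events are excluded.
    """

    def __init__(self, kBT: float = KBT_298K, space: str = "linear",
                 min_bin_n: int = 3):
        self.kBT = kBT
        self.space = space
        self.min_bin_n = min_bin_n

    def fit(self, bins: ForceBinSummary, y=None):
        use = (bins.n >= self.min_bin_n) & np.isfinite(bins.sem) & (bins.sem > 0)
        if use.sum() < 3:
            raise ValueError(
                f"need >= 3 bins with n >= {self.min_bin_n}; only {int(use.sum())}"
            )
        F = bins.centers[use]
        tau = bins.mean_lifetime[use]
        sem = bins.sem[use]
        kBT = self.kBT
        if self.space == "log":
            w = (tau / sem) ** 2  # delta-method weights for log tau
            X = np.column_stack([np.ones_like(F), F])
            W = np.diag(w)
            beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(w) * np.log(tau), rcond=None)
            cov = np.linalg.pinv(X.T @ W @ X)
            tau0 = float(np.exp(beta[0]))
            x_dagger = float(-beta[1] * kBT)
            se = np.sqrt(np.diag(cov))
            std = {"tau0": tau0 * se[0], "x_dagger": se[1] * kBT}
            self.fit_ = BellFit(tau0, x_dagger, kBT, cov, std, True)
            return self

        def model(f, tau0, xd):
            return tau0 * np.exp(-f * xd / kBT)

        slope0 = np.polyfit(F, np.log(np.clip(tau, 1e-12, None)), 1)
        p0 = [float(np.exp(slope0[1])), float(-slope0[0] * kBT)]
        popt, pcov = optimize.curve_fit(
            model, F, tau, p0=p0, sigma=sem, absolute_sigma=False, maxfev=20000
        )
        se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        self.fit_ = BellFit(
            tau0=float(popt[0]), x_dagger=float(popt[1]), kBT=kBT,
            covariance=pcov,
            std_errors={"tau0": float(se[0]), "x_dagger": float(se[1])},
            converged=bool(np.all(np.isfinite(se))),
        )
        return self


def fit_bell_slip(bins: ForceBinSummary, kBT: float = KBT_298K,
                  space: str = "linear") -> BellFit:
    """Weighted single-exponential (Bell) fit of binned lifetimes vs force."""
    return BellSlipBondModel(kBT=kBT, space=space).fit(bins).fit_


# ---------------------------------------------------------------------------
# exponential mixtures and order selection
# ---------------------------------------------------------------------------


class ExponentialMixture(BaseEstimator):
    """EM fit of a k-component exponential mixture to lifetimes.

    Attributes: ``taus_``, ``weights_``, ``log_likelihood_``, ``converged_``.
    """

    def __init__(self, n_components: int = 1, max_iter: int = 250,
                 tol: float = 1e-9):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol

    def _loglik(self, t, taus, w):
        dens = np.sum(
            w[None, :] / taus[None, :] * np.exp(-t[:, None] / taus[None, :]), axis=1
        )
        return float(np.sum(np.log(np.maximum(dens, np.finfo(float).tiny))))

    def _em_once(self, t, taus0):
        k = taus0.size
        taus = taus0.copy()
        w = np.full(k, 1.0 / k)
        ll_old = -np.inf
        converged = False
        for _ in range(self.max_iter):
            dens = w[None, :] / taus[None, :] * np.exp(-t[:, None] / taus[None, :])
            tot = np.maximum(dens.sum(axis=1, keepdims=True), np.finfo(float).tiny)
            r = dens / tot
            nk = np.maximum(r.sum(axis=0), 1e-12)
            taus = np.maximum(r.T @ t / nk, 1e-12)
            w = nk / t.size
            ll = self._loglik(t, taus, w)
            if abs(ll - ll_old) < self.tol * max(abs(ll), 1.0):
                converged = True
                break
            ll_old = ll
        order = np.argsort(taus)
        return taus[order], w[order], ll, converged

    def fit(self, lifetimes, y=None):
        t = np.asarray(lifetimes, float)
        if np.any(t <= 0):
            raise ValueError("lifetimes must be positive")
        k = self.n_components
        if k == 1:
            tau = float(np.mean(t))
            self.taus_ = np.array([tau])
            self.weights_ = np.array([1.0])
            self.log_likelihood_ = float(-t.size * (np.log(tau) + 1.0))
            self.converged_ = True
            return self
        # two initializations: quantile split and geometric spread
        qs = np.quantile(t, (np.arange(k) + 0.5) / k)
        geo = np.mean(t) * np.geomspace(0.2, 2.0, k)
        best = None
        for taus0 in (qs, geo):
            taus0 = np.maximum(np.asarray(taus0, float), 1e-12)
            res = self._em_once(t, taus0)
            if best is None or res[2] > best[2]:
                best = res
        self.taus_, self.weights_, self.log_likelihood_, self.converged_ = best
        return self

    def sample(self, n, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(self.taus_.size, size=n, p=self.weights_)
        return rng.exponential(self.taus_[comp])


def _batch_em_loglik(T: np.ndarray, k: int, max_iter: int = 150,
                     tol: float = 1e-6) -> np.ndarray:
    """Maximized log-likelihood of a k-exponential mixture for each row of T.

    Vectorized EM over a batch of datasets (rows), used to build the
    parametric-bootstrap null distribution cheaply.  Two initializations
    per dataset (quantile split and geometric spread); the better final
    log-likelihood is kept.
    """
    B, n = T.shape
    if k == 1:
        tau = T.mean(axis=1)
        return -n * (np.log(tau) + 1.0)
    tiny = np.finfo(float).tiny
    qs = np.quantile(T, (np.arange(k) + 0.5) / k, axis=1).T  # (B, k)
    geo = T.mean(axis=1, keepdims=True) * np.geomspace(0.2, 2.0, k)[None, :]
    best = np.full(B, -np.inf)
    for taus0 in (qs, geo):
        taus = np.maximum(taus0.copy(), 1e-12)
        w = np.full((B, k), 1.0 / k)
        ll_old = np.full(B, -np.inf)
        for _ in range(max_iter):
            dens = (
                w[:, None, :] / taus[:, None, :]
                * np.exp(-T[:, :, None] / taus[:, None, :])
            )
            tot = np.maximum(dens.sum(axis=2), tiny)
            r = dens / tot[:, :, None]
            nk = np.maximum(r.sum(axis=1), 1e-12)
            taus = np.maximum((r * T[:, :, None]).sum(axis=1) / nk, 1e-12)
            w = nk / n
            ll = np.log(tot).sum(axis=1)
            if np.all(np.abs(ll - ll_old) < tol * np.maximum(np.abs(ll), 1.0)):
                break
            ll_old = ll
        best = np.maximum(best, ll)
    return best


def exponential_mixture_test(
    lifetimes,
    max_components: int = 3,
    n_bootstrap: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Select the number of exponential lifetime components.

    Fits mixtures with 1..max_components components by EM and selects the
    order with sequential parametric-bootstrap likelihood-ratio tests
    (the LRT null for mixture order is non-standard, so the null LRT
    distribution is simulated from the smaller model): starting at k = 1,
    k is incremented while the bootstrap p-value for k vs k+1 falls below
    ``alpha``.  A selected k > 1 is the multimodality signature: the data
    reject a single-exponential (single binding mode) lifetime law.
    """
    t = np.asarray(lifetimes, float)
    if t.size < 20:
        raise ValueError("need >= 20 lifetimes; mixture test underpowered")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(17,)))

    fits = {
        k: ExponentialMixture(n_components=k).fit(t)
        for k in range(1, max_components + 1)
    }
    # observed log-likelihoods recomputed with the same EM budget as the
    # bootstrap fits, so observed and null LRTs are exchangeable
    ll_obs = {
        k: float(_batch_em_loglik(t[None, :], k)[0])
        for k in range(1, max_components + 1)
    }
    p_values = {}
    k_selected = 1
    for k in range(1, max_components):
        lrt_obs = 2.0 * (ll_obs[k + 1] - ll_obs[k])
        null = fits[k]
        comp = rng.choice(null.taus_.size, size=(n_bootstrap, t.size),
                          p=null.weights_)
        Tb = rng.exponential(null.taus_[comp])
        ll_k = _batch_em_loglik(Tb, k)
        ll_k1 = _batch_em_loglik(Tb, k + 1)
        count = int(np.sum(2.0 * (ll_k1 - ll_k) >= lrt_obs))
        p = (1.0 + count) / (n_bootstrap + 1.0)
        p_values[f"{k}_vs_{k + 1}"] = p
        if p < alpha:
            k_selected = k + 1
        else:
            break
    chosen = fits[k_selected]
    return {
        "k_selected": k_selected,
        "taus": chosen.taus_.tolist(),
        "weights": chosen.weights_.tolist(),
        "p_values": p_values,
        "converged": {k: bool(f.converged_) for k, f in fits.items()},
        "log_likelihoods": {k: float(f.log_likelihood_) for k, f in fits.items()},
    }


def anova_bins(groups) -> dict:
    """One-way ANOVA across lifetime groups (per force bin or substrate)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each ANOVA group needs n >= 2")
    F, p = stats.f_oneway(*groups)
    return {"F_stat": float(F), "p": float(p)}
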