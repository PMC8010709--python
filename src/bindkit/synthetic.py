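"""Seeded synthetic-data generators for every analysis stage.

Each generator is a pure function of its config (same seed -> identical
output) and emulates one instrument data type:

* processive motility traces: piecewise-constant staircases with
  exponential dwells, a weighted step-size mixture, back-stepping, optional
  pre-commitment instability spikes, and additive Gaussian position noise;
* single-bond rupture events: Bell-model lifetimes (optionally a mixture of
  binding modes) under sampled pulling forces;
* adsorption isotherms: one-site / two-site / Langmuir-Freundlich curves
  with additive noise truncated at zero;
* FRAP recovery curves: single-exponential binding-dominated recovery;
* QCM-D sensorgrams: Langmuir adsorption kinetics converted to frequency
  shift through the inverse Sauerbrey relation;
* powder XRD patterns: Gaussian reflections over a broad amorphous halo.

Per-stream seeds are derived from the master seed through a stable
SeedSequence spawn-key schedule, so adding one generator never shifts
another generator's stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import isotherm as _iso
from .datasets import (
    AdsorptionDataset,
    KineticCurve,
    MotilityTrace,
    RuptureEventSet,
    XrdPattern,
)
from .kinetics import AVOGADRO, SAUERBREY_C

__all__ = [
    "TraceGenConfig",
    "RuptureGenConfig",
    "IsothermGenConfig",
    "stream_rng",
    "gen_motility_trace",
    "gen_rupture_events",
    "gen_isotherm",
    "gen_frap_curve",
    "gen_qcmd_sensorgram",
    "gen_xrd_pattern",
]

# fixed spawn keys: one integer per generator stream
_STREAMS = {
    "trace": 1,
    "rupture": 2,
    "isotherm": 3,
    "frap": 4,
    "qcmd": 5,
    "xrd": 6,
}


def stream_rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """Independent generator for one named stream under a master seed."""
    key = _STREAMS.get(stream)
    if key is None:
        raise ValueError(f"unknown stream {stream!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key, int(index)))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# motility traces
# ---------------------------------------------------------------------------


@dataclass
class TraceGenConfig:
    """Configuration of a processive-motility staircase trace.

    Defaults reflect a Cel7A-like enzyme on crystalline cellulose: ~1 nm
    fundamental steps (one cellobiose unit), 0.75 s mean dwell, 35 %
    back-stepping, 1 kHz sampling with 0.3 nm Gaussian position noise.
    ``spike_amplitude``/``n_spikes`` produce pre-commitment instability
    excursions (default amplitude 100 nm) that return to baseline before the
    staircase begins.
    """

    dwell_mean: float = 0.75  # s
    step_sizes: tuple = ((1.0, 1.0),)  # (displacement nm, weight)
    back_step_prob: float = 0.35
    noise_sd: float = 0.3  # nm
    sample_rate: float = 1000.0  # Hz
    duration: float = 60.0  # s
    detach_rate: float = 0.0  # s^-1, 0 = never
    spike_amplitude: float = 100.0  # nm
    n_spikes: int = 0
    spike_duration: float = 0.5  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dwell_mean <= 0:
            raise ValueError("dwell_mean must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not 0 <= self.back_step_prob <= 1:
            raise ValueError("back_step_prob must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        w = np.array([w for _, w in self.step_sizes], float)
        if w.size == 0 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("step-size weights must be >= 0 and sum to 1")
        if self.detach_rate < 0:
            raise ValueError("detach_rate must be >= 0")


def gen_motility_trace(config: TraceGenConfig) -> MotilityTrace:
    """Simulate a bead-displacement trace of a processively stepping enzyme.

    The staircase is a signed renewal process: dwell times are exponential
    with mean ``dwell_mean``; step magnitudes are drawn from the weighted
    mixture; each step's sign is flipped with probability ``back_step_prob``.
    With back-step probability p the expected net velocity is
    (1 - 2p) * E[step] / dwell_mean.
    """
    rng = stream_rng(config.seed, "trace")
    n = int(round(config.duration * config.sample_rate)) + 1
    t = np.arange(n) / config.sample_rate
    pos = np.zeros(n)

    # pre-commitment instability spikes: excursions that return to baseline
    t_start = 0.0
    if config.n_spikes > 0:
        total_spike = config.n_spikes * 2.0 * config.spike_duration
        for k in range(config.n_spikes):
            s0 = (2 * k) * config.spike_duration
            i0 = int(round(s0 * config.sample_rate))
            i1 = int(round((s0 + config.spike_duration) * config.sample_rate))
            amp = config.spike_amplitude * rng.uniform(0.8, 1.2)
            # triangular excursion away from and back to baseline
            half = max((i1 - i0) // 2, 1)
            ramp = np.concatenate(
                [np.linspace(0, amp, half), np.linspace(amp, 0, max(i1 - i0 - half, 1))]
            )
            pos[i0 : i0 + ramp.size] = ramp[: max(n - i0, 0)][: ramp.size]
        t_start = total_spike

    # detachment time (position frozen afterwards)
    t_detach = np.inf
    if config.detach_rate > 0:
        t_detach = t_start + rng.exponential(1.0 / config.detach_rate)

    sizes = np.array([s for s, _ in config.step_sizes], float)
    weights = np.array([w for _, w in config.step_sizes], float)

    level = 0.0
    t_now = t_start + rng.exponential(config.dwell_mean)
    while t_now < min(config.duration, t_detach):
        mag = rng.choice(sizes, p=weights)
        sign = -1.0 if rng.random() < config.back_step_prob else 1.0
        level += sign * mag
        idx = int(np.ceil(t_now * config.sample_rate))
        if idx < n:
            pos[idx:] = level
        t_now += rng.exponential(config.dwell_mean)

    if config.noise_sd > 0:
        pos = pos + rng.normal(0.0, config.noise_sd, size=n)
    return MotilityTrace(t, pos, config.sample_rate, label=f"synthetic-seed{config.seed}")


# ---------------------------------------------------------------------------
# rupture events
# ---------------------------------------------------------------------------


@dataclass
class RuptureGenConfig:
    """Configuration of Bell-model single-bond rupture events.

    ``modes`` lists (tau0 s, x_dagger nm, weight) binding modes; lifetimes
    are exponential with force-dependent mean tau0 * exp(-F * x_dagger / kBT).
    Forces default to uniform on [0, 20] pN so every 2.5-pN bin is populated.
    """

    modes: tuple = ((2.0, 0.4, 1.0),)
    force_range: tuple = (0.0, 20.0)  # pN, uniform sampler
    force_sampler: object = None  # optional callable(rng, n) -> forces pN
    kBT: float = 4.114  # pN nm at 298 K
    n_events: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        w = np.array([m[2] for m in self.modes], float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mode weights must sum to 1 (tol 1e-9)")
        for tau0, xd, _ in self.modes:
            if tau0 <= 0:
                raise ValueError("tau0 must be positive")
            if xd < 0:
                raise ValueError("x_dagger must be >= 0")
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")


def gen_rupture_events(config: RuptureGenConfig) -> RuptureEventSet:
    """Draw (force, lifetime) rupture events from a Bell-model mixture."""
    rng = stream_rng(config.seed, "rupture")
    n = config.n_events
    if config.force_sampler is not None:
        force = np.asarray(config.force_sampler(rng, n), float)
    else:
        lo, hi = config.force_range
        force = rng.uniform(lo, hi, size=n)
    taus = np.array([m[0] for m in config.modes], float)
    xds = np.array([m[1] for m in config.modes], float)
    weights = np.array([m[2] for m in config.modes], float)
    mode = rng.choice(len(config.modes), size=n, p=weights)
    mean_life = taus[mode] * np.exp(-force * xds[mode] / config.kBT)
    lifetime = rng.exponential(mean_life)
    # exponential draws of 0.0 are measure-zero but guard the >0 invariant
    lifetime = np.maximum(lifetime, np.finfo(float).tiny)
    return RuptureEventSet(force, lifetime, substrate="synthetic")


# ---------------------------------------------------------------------------
# adsorption isotherms
# ---------------------------------------------------------------------------


def _default_free_grid() -> tuple:
    # 20-point serial-dilution style grid spanning 0.05-250 uM, as used in
    # pull-down assays covering both the linear region and near-saturation
    return tuple(np.geomspace(0.05, 250.0, 20))


@dataclass
class IsothermGenConfig:
    """Configuration of a synthetic pull-down adsorption dataset."""

    model_id: str = "one_site"
    params: _iso.IsothermParams = field(
        default_factory=lambda: _iso.IsothermParams(n_max=4.34, K_d=8.69)
    )
    free_grid: tuple = field(default_factory=_default_free_grid)
    noise_sd: float = 0.1  # umol/g
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.free_grid):
            raise ValueError("free_grid values must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.model_id not in _iso.MODELS:
            raise ValueError(
                f"unknown model_id {self.model_id!r}; expected one of {_iso.MODELS}"
            )
        self.params.validate(self.model_id)


def gen_isotherm(config: IsothermGenConfig) -> AdsorptionDataset:
    """Generate bound-vs-free data from an isotherm model plus Gaussian
    noise, truncated at zero; replicates are stacked."""
    rng = stream_rng(config.seed, "isotherm")
    free = np.tile(np.asarray(config.free_grid, float), config.replicates)
    bound = _iso.eval_isotherm(config.model_id, config.params, free)
    if config.noise_sd > 0:
        bound = bound + rng.normal(0.0, config.noise_sd, size=free.size)
    bound = np.clip(bound, 0.0, None)
    return AdsorptionDataset(free, bound, protein="synthetic")


# ---------------------------------------------------------------------------
# FRAP and QCM-D kinetics
# ---------------------------------------------------------------------------


def gen_frap_curve(
    k_off: float,
    F_M: float,
    baseline: float = 0.2,
    noise_sd: float = 0.0,
    t_grid=None,
    seed: int = 0,
) -> KineticCurve:
    """Binding-dominated FRAP recovery: I(t) = baseline + F_M (1 - e^{-k_off t}).

    k_off is the desorption rate (s^-1); F_M the reversibly bound (mobile)
    fraction in [0, 1].  The recovery half-time is ln2 / k_off.
    """
    if k_off <= 0:
        raise ValueError("k_off must be positive")
    if not 0 <= F_M <= 1:
        raise ValueError("F_M must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if t_grid is None:
        t_grid = np.linspace(0.0, 5.0 / k_off, 200)
    t = np.asarray(t_grid, float)
    intensity = baseline + F_M * (1.0 - np.exp(-k_off * t))
    if noise_sd > 0:
        rng = stream_rng(seed, "frap")
        intensity = intensity + rng.normal(0.0, noise_sd, size=t.size)
    return KineticCurve(t, intensity, kind="frap")


def gen_qcmd_sensorgram(
    k_on_star: float,
    k_off: float,
    A: float,
    phase_times: tuple = (600.0, 1200.0),
    overtone: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    molar_mass: float = 45000.0,
    area: float = 1.0,
    sample_rate: float = 1.0,
) -> KineticCurve:
    """Langmuir-kinetics QCM-D sensorgram in frequency-shift units.

    Adsorption phase (0 <= t < t_rinse): coverage
    Gamma(t) = Gamma_eq (1 - e^{-(k_on* + k_off) t}) with
    Gamma_eq = A k_on* / (k_on* + k_off) molecules; rinse phase decays as
    Gamma(t_rinse) e^{-k_off (t - t_rinse)}.  Coverage (molecules over
    ``area`` cm^2 of a ``molar_mass`` g/mol protein) is converted to the
    frequency shift at the requested overtone via the inverse Sauerbrey
    relation delta_f = -n * delta_m / C.
    """
    if k_on_star <= 0 or k_off <= 0:
        raise ValueError("rates must be positive")
    if A <= 0:
        raise ValueError("A must be positive")
    t_rinse, t_end = phase_times
    if not 0 < t_rinse < t_end:
        raise ValueError("phase boundaries must satisfy 0 < t_rinse < t_end")
    n = int(round(t_end * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    k_obs = k_on_star + k_off
    gamma_eq = A * k_on_star / k_obs
    gamma = np.where(
        t < t_rinse,
        gamma_eq * (1.0 - np.exp(-k_obs * t)),
        gamma_eq * (1.0 - np.exp(-k_obs * t_rinse)) * np.exp(-k_off * (t - t_rinse)),
    )
    # molecules -> areal mass (ng/cm^2) -> delta_f (Hz)
    mass_areal = gamma * molar_mass / AVOGADRO / area * 1e9
    delta_f = -overtone * mass_areal / SAUERBREY_C
    if noise_sd > 0:
        rng = stream_rng(seed, "qcmd")
        delta_f = delta_f + rng.normal(0.0, noise_sd, size=t.size)
    return KineticCurve(t, delta_f, kind="qcmd", overtone=overtone)


# ---------------------------------------------------------------------------
# XRD patterns
# ---------------------------------------------------------------------------

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gen_xrd_pattern(
    peaks,
    amorphous: tuple = (18.0, 6.0, 8.0),
    noise_sd: float = 0.0,
    grid=None,
    seed: int = 0,
    allomorph: str = "unknown",
) -> XrdPattern:
    """Synthetic diffractogram: Gaussian reflections over a broad amorphous
    Gaussian halo plus optional noise.

    ``peaks`` is a list of (two_theta deg, height, fwhm deg); ``amorphous``
    is (two_theta deg, height, sd deg) for the halo.
    """
    if grid is None:
        grid = np.arange(5.0, 40.0, 0.02)
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    lo, hi = grid[0], grid[-1]
    intensity = np.zeros_like(grid)
    for center, height, fwhm in peaks:
        if height < 0:
            raise ValueError("peak heights must be >= 0")
        if not lo <= center <= hi:
            raise ValueError(f"peak at {center} deg lies outside the grid [{lo}, {hi}]")
        sigma = fwhm * _FWHM_TO_SIGMA
        intensity += height * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    ac, ah, aw = amorphous
    if ah > 0:
        intensity += ah * np.exp(-0.5 * ((grid - ac) / aw) ** 2)
    if noise_sd > 0:
        rng = stream_rng(seed, "xrd")
        intensity = intensity + rng.normal(0.0, noise_sd, size=grid.size)
    intensity = np.clip(intensity, 0.0, None)
    return XrdPattern(grid, intensity, allomorph=allomorph)
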