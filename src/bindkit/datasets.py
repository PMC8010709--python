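"""Core data containers for binding-analysis inputs.

Each container wraps validated numpy arrays for one instrument-style data
type: equilibrium adsorption points, optical-tweezer bead traces, single-bond
rupture events, FRAP/QCM-D kinetic curves, and powder XRD patterns.  All of
them round-trip through plain CSV with fixed, documented column headers so
pipelines can be driven from files as well as from the synthetic generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AdsorptionDataset",
    "MotilityTrace",
    "RuptureEventSet",
    "KineticCurve",
    "XrdPattern",
    "FitResult",
]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class AdsorptionDataset:
    """Paired (free, bound) observations from a pull-down binding assay.

    Parameters
    ----------
    free : array-like
        Free protein concentration at equilibrium, in uM.
    bound : array-like
        Bound protein per unit substrate, in umol protein / g cellulose.
    protein, substrate : str
        Labels identifying the protein construct and cellulose allomorph.
    """

    free: np.ndarray
    bound: np.ndarray
    protein: str = ""
    substrate: str = ""

    def __post_init__(self) -> None:
        self.free = _as_1d(self.free, "free")
        self.bound = _as_1d(self.bound, "bound")
        if self.free.shape != self.bound.shape:
            raise ValueError("free and bound must have equal length")
        if np.any(self.free < 0):
            raise ValueError("free concentrations must be >= 0")
        if np.any(self.bound < 0):
            raise ValueError("bound amounts must be >= 0")

    def __len__(self) -> int:
        return self.free.size

    def truncated(self, max_free: float) -> "AdsorptionDataset":
        """Sub-dataset with free concentration <= ``max_free`` uM."""
        mask = self.free <= max_free
        if not np.any(mask):
            raise ValueError(f"no points with free <= {max_free} uM")
        return AdsorptionDataset(
            self.free[mask], self.bound[mask], self.protein, self.substrate
        )

    def to_csv(self, path) -> None:
        pd.DataFrame({"free_uM": self.free, "bound_umol_g": self.bound}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, protein: str = "", substrate: str = "") -> "AdsorptionDataset":
        df = pd.read_csv(path)
        return cls(df["free_uM"], df["bound_umol_g"], protein, substrate)


@dataclass
class MotilityTrace:
    """Uniformly sampled bead displacement from an optical-tweezer assay.

    ``position`` is the bead displacement from the trap center in nm; the
    time grid must be uniform to within 1e-9 relative spacing.
    """

    time: np.ndarray
    position: np.ndarray
    sample_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        self.time = _as_1d(self.time, "time")
        self.position = _as_1d(self.position, "position")
        if self.time.shape != self.position.shape:
            raise ValueError("time and position must have equal length")
        if self.time.size < 2:
            raise ValueError("trace needs at least two samples")
        dt = np.diff(self.time)
        if np.any(np.abs(dt - dt[0]) > 1e-9 * max(abs(dt[0]), 1e-12)):
            raise ValueError("time grid must be uniform")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def __len__(self) -> int:
        return self.time.size

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "position_nm": self.position}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, sample_rate: float | None = None, label: str = "") -> "MotilityTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if sample_rate is None:
            sample_rate = 1.0 / float(np.median(np.diff(t)))
        return cls(t, df["position_nm"], sample_rate, label)


@dataclass
class RuptureEventSet:
    """Single CBM-cellulose bond rupture observations: (force, lifetime)."""

    force: np.ndarray
    lifetime: np.ndarray
    substrate: str = ""
    construct: str = ""

    def __post_init__(self) -> None:
        self.force = _as_1d(self.force, "force")
        self.lifetime = _as_1d(self.lifetime, "lifetime")
        if self.force.shape != self.lifetime.shape:
            raise ValueError("force and lifetime must have equal length")
        if np.any(self.force < 0):
            raise ValueError("forces must be >= 0 pN")
        if np.any(self.lifetime <= 0):
            raise ValueError("lifetimes must be > 0 s")

    def __len__(self) -> int:
        return self.force.size

    def to_csv(self, path) -> None:
        pd.DataFrame({"force_pN": self.force, "lifetime_s": self.lifetime}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, substrate: str = "", construct: str = "") -> "RuptureEventSet":
        df = pd.read_csv(path)
        return cls(df["force_pN"], df["lifetime_s"], substrate, construct)


@dataclass
class KineticCurve:
    """Time series for FRAP (normalized intensity) or QCM-D (delta-f, Hz).

    ``kind`` is "frap" or "qcmd"; for QCM-D, ``overtone`` records the odd
    harmonic at which the frequency shift was read.
    """

    time: np.ndarray
    signal: np.ndarray
    kind: str = "frap"
    overtone: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.time = _as_1d(self.time, "time")
        self.signal = _as_1d(self.signal, "signal")
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if self.kind not in ("frap", "qcmd"):
            raise ValueError("kind must be 'frap' or 'qcmd'")
        if self.kind == "qcmd" and self.overtone is None:
            self.overtone = 3

    def __len__(self) -> int:
        return self.time.size

    def to_csv(self, path) -> None:
        col = "intensity" if self.kind == "frap" else "delta_f_Hz"
        pd.DataFrame({"time_s": self.time, col: self.signal}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "frap", overtone: int | None = None) -> "KineticCurve":
        df = pd.read_csv(path)
        col = "intensity" if kind == "frap" else "delta_f_Hz"
        return cls(df["time_s"], df[col], kind, overtone)


@dataclass
class XrdPattern:
    """Powder X-ray diffractogram on a strictly increasing 2-theta grid."""

    two_theta: np.ndarray
    intensity: np.ndarray
    allomorph: str = "unknown"

    def __post_init__(self) -> None:
        self.two_theta = _as_1d(self.two_theta, "two_theta")
        self.intensity = _as_1d(self.intensity, "intensity")
        if self.two_theta.shape != self.intensity.shape:
            raise ValueError("two_theta and intensity must have equal length")
        if np.any(np.diff(self.two_theta) <= 0):
            raise ValueError("two_theta grid must be strictly increasing")

    def __len__(self) -> int:
        return self.two_theta.size

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"two_theta_deg": self.two_theta, "intensity": self.intensity}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, allomorph: str = "unknown") -> "XrdPattern":
        df = pd.read_csv(path)
        return cls(df["two_theta_deg"], df["intensity"], allomorph)


@dataclass
class FitResult:
    """Generic record of one fitted model.

    ``params`` and ``std_errors`` are name->value mappings; ``std_errors``
    is populated only when the optimizer converged.
    """

    model_id: str
    params: dict = field(default_factory=dict)
    std_errors: dict = field(default_factory=dict)
    rmse: float = float("nan")
    log_likelihood: float | None = None
    converged: bool = False
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": {k: float(v) for k, v in self.params.items()},
            "std_errors": {k: float(v) for k, v in self.std_errors.items()},
            "rmse": float(self.rmse),
            "log_likelihood": None
            if self.log_likelihood is None
            else float(self.log_likelihood),
            "converged": bool(self.converged),
            "n_points": int(self.n_points),
        }
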