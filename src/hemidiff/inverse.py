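"""Weighted minimum-norm estimation (WMNE) of cortical sources.

The linear inverse problem ``y = L x + noise`` is underdetermined (far more
sources than sensors); WMNE resolves it by penalising a weighted source norm:

    x_hat = argmin_x  (y - L x)^T C^-1 (y - L x) + lambda ||W x||^2

whose solution is applied through the kernel

    K = R_w L^T (L R_w L^T + lambda C)^-1,     R_w = diag(w)^-2,

with ``C`` the sensor noise covariance estimated from baseline data and
``w_i = ||L[:, i]||^gamma`` the depth weights: deep sources have weak
columns, get small weights and hence a larger prior variance ``R_w``, which
compensates the depth bias of unweighted minimum-norm solutions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .headmodel import Leadfield
from .preprocess import EpochSet

__all__ = [
    "NoiseCovariance",
    "SourceWeighting",
    "InverseOperator",
    "estimate_noise_covariance",
    "depth_weights",
    "build_wmne_operator",
    "apply_inverse",
    "WMNEInverse",
]


@dataclass
class NoiseCovariance:
    """Sensor-space covariance (volts^2) with diagonal loading applied."""

    matrix: np.ndarray
    loading: float
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        sym_err = np.max(np.abs(m - m.T))
        if sym_err > 1e-12 * max(np.max(np.abs(m)), 1e-300):
            raise ValueError("covariance must be symmetric")


@dataclass
class SourceWeighting:
    """One positive weight per source (diagonal of W) and its exponent."""

    weights: np.ndarray
    gamma: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("all source weights must be positive")


@dataclass
class InverseOperator:
    """Sources x sensors kernel realising the WMNE solution for fixed lambda."""

    kernel: np.ndarray
    lam: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.ndim != 2:
            raise ValueError("kernel must be 2-D (sources x sensors)")
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("kernel contains non-finite entries")

    def save(self, path) -> None:
        path = Path(path)
        np.savetxt(path, self.kernel)
        sidecar = {"lambda": self.lam, **self.provenance}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))


def estimate_noise_covariance(
    segments: list[np.ndarray],
    loading: float = 0.1,
) -> NoiseCovariance:
    """Sample covariance of concatenated, demeaned baseline segments.

    Diagonal loading regularises towards a scaled identity:
    ``C <- (1 - loading) C + loading mean(diag(C)) I``; ``loading=1`` gives
    exactly the spherical covariance.  If fewer baseline samples than
    sensors are available the estimate is rank-deficient; a warning is
    raised and the loading floor is raised to 0.5.
    """
    if not segments:
        raise ValueError("no baseline segments given")
    if not (0.0 <= loading <= 1.0):
        raise ValueError("loading must lie in [0, 1]")
    demeaned = [s - s.mean(axis=1, keepdims=True) for s in segments]
    data = np.concatenate(demeaned, axis=1)
    n_chan, n_samp = data.shape
    if n_samp < n_chan:
        warnings.warn(
            f"only {n_samp} baseline samples for {n_chan} sensors; raising "
            "diagonal loading to 0.5", RuntimeWarning, stacklevel=2)
        loading = max(loading, 0.5)
    cov = data @ data.T / max(n_samp - 1, 1)
    cov = 0.5 * (cov + cov.T)
    target = float(np.mean(np.diag(cov)))
    cov = (1.0 - loading) * cov + loading * target * np.eye(n_chan)
    return NoiseCovariance(matrix=cov, loading=loading, n_samples=n_samp)


def depth_weights(L: Leadfield | np.ndarray, gamma: float = 0.5) -> SourceWeighting:
    """Depth weights ``w_i = ||L[:, i]||^gamma``; gamma=0 is plain MNE."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    gain = L.gain if isinstance(L, Leadfield) else np.asarray(L)
    norms = np.linalg.norm(gain, axis=0)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"leadfield column {int(zero[0])} has zero norm")
    return SourceWeighting(weights=norms ** gamma, gamma=gamma)


def auto_lambda(
    L: Leadfield | np.ndarray,
    C: NoiseCovariance,
    W: SourceWeighting,
    snr_power: float = 9.0,
) -> float:
    """Regularisation from an assumed power SNR (default 9, amplitude 3)."""
    gain = L.gain if isinstance(L, Leadfield) else np.asarray(L)
    r_w = 1.0 / W.weights ** 2
    tr_signal = float(np.einsum("ij,j,ij->", gain, r_w, gain))
    tr_noise = float(np.trace(C.matrix))
    return tr_signal / (tr_noise * snr_power)


def build_wmne_operator(
    L: Leadfield | np.ndarray,
    C: NoiseCovariance,
    W: SourceWeighting | None = None,
    lam: float | str = "auto",
    snr_power: float = 9.0,
) -> InverseOperator:
    """Assemble the WMNE kernel ``K = R_w L^T (L R_w L^T + lambda C)^-1``."""
    gain = L.gain if isinstance(L, Leadfield) else np.asarray(L)
    n_sensors, n_sources = gain.shape
    if C.matrix.shape != (n_sensors, n_sensors):
        raise ValueError("covariance shape does not match leadfield rows")
    if W is None:
        W = depth_weights(gain)
    if len(W.weights) != n_sources:
        raise ValueError("one weight per source required")
    if lam == "auto":
        lam = auto_lambda(gain, C, W, snr_power)
    lam = float(lam)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    r_w = 1.0 / W.weights ** 2
    gram = (gain * r_w[None, :]) @ gain.T + lam * C.matrix
    try:
        solved = np.linalg.solve(gram, gain)  # (L R_w L^T + lam C)^-1 L
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular system: L R_w L^T + lambda C is not invertible; "
            "use lambda > 0 with a rank-deficient leadfield"
        ) from exc
    kernel = r_w[:, None] * solved.T
    meta = {"gamma": W.gamma, "loading": C.loading, "snr_power": snr_power}
    if isinstance(L, Leadfield):
        meta["leadfield"] = L.meta.get("model", "unknown")
    return InverseOperator(kernel=kernel, lam=lam, provenance=meta)


def apply_inverse(K: InverseOperator, epochs: EpochSet) -> EpochSet:
    """Map scalp epochs to source epochs (trials x sources x samples)."""
    if epochs.n_channels != K.kernel.shape[1]:
        missing = K.kernel.shape[1] - epochs.n_channels
        raise ValueError(
            f"epoch channel count {epochs.n_channels} does not match the "
            f"inverse kernel's {K.kernel.shape[1]} sensors "
            f"({missing:+d} channels)"
        )
    n_trials, n_chan, n_samp = epochs.epochs.shape
    flat = epochs.epochs.transpose(1, 0, 2).reshape(n_chan, -1)
    sources = (K.kernel @ flat).reshape(-1, n_trials, n_samp).transpose(1, 0, 2)
    return EpochSet(epochs=sources, labels=epochs.labels.copy(),
                    fs=epochs.fs, montage=None)


class WMNEInverse(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: scalp epochs -> cortical source epochs.

    ``fit`` estimates the noise covariance from baseline segments and builds
    the inverse kernel; ``transform`` applies it per trial.
    """

    def __init__(self, leadfield: Leadfield | None = None,
                 lam: float | str = "auto", gamma: float = 0.5,
                 loading: float = 0.1, snr_power: float = 9.0):
        self.leadfield = leadfield
        self.lam = lam
        self.gamma = gamma
        self.loading = loading
        self.snr_power = snr_power

    def fit(self, X, y=None):
        """``X``: list of baseline arrays (channels x samples)."""
        if self.leadfield is None:
            raise ValueError("WMNEInverse needs a leadfield")
        segments = X if isinstance(X, list) else [np.asarray(X)]
        self.noise_cov_ = estimate_noise_covariance(segments, self.loading)
        self.weighting_ = depth_weights(self.leadfield, self.gamma)
        self.operator_ = build_wmne_operator(
            self.leadfield, self.noise_cov_, self.weighting_,
            lam=self.lam, snr_power=self.snr_power)
        self.lambda_ = self.operator_.lam
        return self

    def transform(self, X: EpochSet) -> EpochSet:
        return apply_inverse(self.operator_, X)
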