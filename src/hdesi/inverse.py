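"""Weighted minimum-norm inverse: noise covariance, depth-weighted operator,
application at a time sample, and source-maximum extraction.

Sources carry free 3-component orientations; the map value at a grid point is
the Euclidean norm of its moment estimate.  Regularization follows the common
SNR heuristic: lambda^2 = trace(L W L^T) / (trace(C) * snr^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import InputError, NoPeakError, NumericError, ParameterError
from .epochs import AverageIED, Epoch, BASELINE_WINDOW_S
from .forward import LeadField

__all__ = [
    "NoiseCovariance",
    "InverseOperator",
    "SourceMap",
    "estimate_noise_covariance",
    "compute_wmne_operator",
    "apply_inverse",
    "find_source_maximum",
]

DEFAULT_SNR = 3.0
DEFAULT_DEPTH_EXPONENT = 0.5
DEFAULT_LOADING_FRAC = 0.1


@dataclass(frozen=True)
class NoiseCovariance:
    """Sensor covariance (uV^2) with diagonal loading."""

    matrix: np.ndarray
    loading_frac: float
    n_samples: int


@dataclass(frozen=True)
class InverseOperator:
    """Kernel mapping average-referenced data to source moments (nAm per uV)."""

    kernel: np.ndarray  # (3 * n_sources) x channels
    lambda2: float
    depth_exponent: float
    source_weights: np.ndarray  # per-source scalar weights, length n_sources
    n_channels: int

    @property
    def n_sources(self) -> int:
        return self.kernel.shape[0] // 3


@dataclass(frozen=True)
class SourceMap:
    """Per-grid-point moment magnitude (nAm) at one time sample."""

    values: np.ndarray
    sample: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 1 or v.size == 0:
            raise InputError("source map must be a non-empty vector")
        if np.any(v < 0):
            raise InputError("source map values must be non-negative")
        object.__setattr__(self, "values", v)


def estimate_noise_covariance(
    epochs: list[Epoch],
    baseline_window_s: tuple[float, float] = BASELINE_WINDOW_S,
    loading_frac: float = DEFAULT_LOADING_FRAC,
) -> NoiseCovariance:
    """Sample covariance of baseline samples pooled across epochs.

    Diagonal loading: C <- (1 - a) C + a * mean(diag(C)) * I, which also keeps
    the average-referenced (rank-deficient) covariance invertible.
    """
    if not epochs:
        raise InputError("need at least one epoch")
    if not 0.0 <= loading_frac <= 1.0:
        raise ParameterError("loading_frac must be in [0, 1]")
    rate = epochs[0].sampling_rate_Hz
    segments = []
    for e in epochs:
        c = e.center_sample
        b0 = max(c + int(round(baseline_window_s[0] * rate)), 0)
        b1 = c + int(round(baseline_window_s[1] * rate))
        if b1 <= b0 or b1 > e.n_samples:
            raise InputError("baseline window does not fit inside the epoch")
        segments.append(e.data[:, b0:b1])
    pooled = np.concatenate(segments, axis=1)
    n = pooled.shape[1]
    if n < 50:
        raise InputError(f"need >= 50 pooled baseline samples, got {n}")
    pooled = pooled - pooled.mean(axis=1, keepdims=True)
    cov = pooled @ pooled.T / (n - 1)
    mu = float(np.mean(np.diag(cov)))
    cov = (1.0 - loading_frac) * cov + loading_frac * mu * np.eye(cov.shape[0])
    try:
        scipy.linalg.cholesky(cov)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - loading prevents this
        raise NumericError("loaded covariance is not positive definite") from exc
    return NoiseCovariance(matrix=cov, loading_frac=loading_frac, n_samples=n)


def compute_wmne_operator(
    leadfield: LeadField,
    noise_cov: NoiseCovariance,
    snr: float = DEFAULT_SNR,
    depth_exponent: float = DEFAULT_DEPTH_EXPONENT,
) -> InverseOperator:
    """Depth-weighted minimum-norm kernel M = W L^T (L W L^T + lambda^2 C)^-1.

    Depth weights per source: (Frobenius norm of its 3-column gain block)
    raised to -2 * depth_exponent; exponent 0 gives plain MNE.
    """
    if snr <= 0:
        raise ParameterError(f"snr must be positive, got {snr}")
    if not 0.0 <= depth_exponent <= 1.0:
        raise ParameterError("depth_exponent must be in [0, 1]")
    gain = leadfield.gain
    n_ch = gain.shape[0]
    if noise_cov.matrix.shape != (n_ch, n_ch):
        raise InputError("noise covariance shape does not match the lead field")

    block_norms = np.sqrt(
        np.sum(gain.reshape(n_ch, -1, 3) ** 2, axis=(0, 2))
    )  # per-source Frobenius norm
    if np.any(block_norms == 0):
        raise NumericError("lead field contains an all-zero source block")
    w = block_norms ** (-2.0 * depth_exponent)
    w3 = np.repeat(w, 3)

    gram = (gain * w3[None, :]) @ gain.T  # L W L^T
    lam2 = float(np.trace(gram) / (np.trace(noise_cov.matrix) * snr**2))
    system = gram + lam2 * noise_cov.matrix
    try:
        solved = scipy.linalg.solve(system, gain * w3[None, :], assume_a="pos")
    except scipy.linalg.LinAlgError as exc:
        raise NumericError("regularized system is singular") from exc
    return InverseOperator(
        kernel=solved.T,
        lambda2=lam2,
        depth_exponent=depth_exponent,
        source_weights=w,
        n_channels=n_ch,
    )


def apply_inverse(op: InverseOperator, avg, sample: int) -> SourceMap:
    """Source-moment magnitudes from one average-referenced data column.

    ``avg`` may be an :class:`AverageIED` or a raw channels x samples array.
    """
    data = avg.data if isinstance(avg, AverageIED) else np.asarray(avg, float)
    if data.ndim != 2 or data.shape[0] != op.n_channels:
        raise InputError(
            f"data has {data.shape[0] if data.ndim == 2 else '?'} channels, "
            f"operator expects {op.n_channels}"
        )
    if not 0 <= sample < data.shape[1]:
        raise InputError(f"sample {sample} outside [0, {data.shape[1]})")
    col = data[:, sample]
    col = col - col.mean()  # average reference
    moments = (op.kernel @ col).reshape(-1, 3)
    return SourceMap(values=np.linalg.norm(moments, axis=1), sample=int(sample))


def find_source_maximum(source_map: SourceMap) -> int:
    """Grid index of the map maximum; ties break to the lowest index."""
    if not np.any(source_map.values):
        raise NoPeakError("source map is identically zero")
    return int(np.argmax(source_map.values))
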