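"""Localization scoring: distance to the resection mask, sublobar concordance
against a geometric atlas surrogate, and the spike-count subsampling
experiment."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.vq import kmeans2

from .errors import InputError, NoPeakError, ParameterError
from .epochs import average_epochs, find_half_rise
from .forward import SourceGrid
from .inverse import InverseOperator, apply_inverse, find_source_maximum
from .simulate import ResectionMask

__all__ = [
    "SublobeAtlas",
    "DistanceResult",
    "SubsamplingCurve",
    "distance_to_mask",
    "build_sublobe_atlas",
    "sublobar_concordance",
    "subsample_experiment",
    "smallest_N_below",
]

log = logging.getLogger(__name__)

SUBLOBES_PER_HEMISPHERE = 19
DEFAULT_SUBSAMPLE_REPS = 25
DEFAULT_DISTANCE_THRESHOLD_MM = 10.0


@dataclass(frozen=True)
class SublobeAtlas:
    """Per-grid-point region label; hemispheres split at x = 0."""

    labels: np.ndarray  # int label per grid point
    n_per_hemisphere: int

    @property
    def n_regions(self) -> int:
        return int(np.unique(self.labels).size)


@dataclass(frozen=True)
class DistanceResult:
    source_max_index: int
    distance_mm: float
    concordant_sublobe: bool | None = None
    concordant_hemisphere: bool | None = None


@dataclass(frozen=True)
class SubsamplingCurve:
    """Distance statistics per subsample size N."""

    Ns: tuple[int, ...]
    n_reps: int
    mean_dist_to_full_mm: tuple[float, ...]
    sd_dist_to_full_mm: tuple[float, ...]
    mean_dist_to_mask_mm: tuple[float, ...]
    sd_dist_to_mask_mm: tuple[float, ...]
    n_total: int
    seed: int | None
    full_max_index: int


def distance_to_mask(max_index: int, mask: ResectionMask, grid: SourceGrid) -> float:
    """Shortest Euclidean distance (mm) from the source maximum to the mask.

    Zero if the maximum lies inside the mask.
    """
    if not 0 <= max_index < grid.n_points:
        raise InputError(f"grid index {max_index} outside [0, {grid.n_points})")
    if max_index in mask:
        return 0.0
    d = np.linalg.norm(grid.positions[mask.indices] - grid.positions[max_index], axis=1)
    return float(d.min())


def build_sublobe_atlas(
    grid: SourceGrid,
    n_per_hemisphere: int = SUBLOBES_PER_HEMISPHERE,
    seed: int | None = 0,
) -> SublobeAtlas:
    """Geometric sublobe surrogate: k-centroid partition of each hemisphere.

    Left hemisphere (x < 0) takes labels 0..n-1, right (x >= 0) n..2n-1.
    Deterministic under ``seed``.  An empty hemisphere contributes no regions.
    """
    if n_per_hemisphere < 1:
        raise ParameterError("n_per_hemisphere must be >= 1")
    labels = np.full(grid.n_points, -1, int)
    for hemi, sel in enumerate([grid.positions[:, 0] < 0, grid.positions[:, 0] >= 0]):
        pts = grid.positions[sel]
        if pts.shape[0] == 0:
            continue
        if pts.shape[0] < n_per_hemisphere:
            raise ParameterError(
                f"hemisphere has {pts.shape[0]} points < {n_per_hemisphere} regions"
            )
        for attempt in range(10):
            _, lab = kmeans2(
                pts, n_per_hemisphere, minit="++", rng=(seed or 0) + attempt
            )
            if np.unique(lab).size == n_per_hemisphere:
                break
        else:  # pragma: no cover - ++ init essentially never leaves empties
            raise ParameterError("could not form the requested number of regions")
        labels[sel] = lab + hemi * n_per_hemisphere
    return SublobeAtlas(labels=labels, n_per_hemisphere=n_per_hemisphere)


def sublobar_concordance(
    max_index: int, atlas: SublobeAtlas, mask: ResectionMask
) -> tuple[bool, bool]:
    """(same-sublobe, same-hemisphere) flags for the source maximum vs the mask."""
    if not 0 <= max_index < atlas.labels.size:
        raise InputError("grid index outside the atlas")
    mask_labels = set(atlas.labels[mask.indices].tolist())
    label = int(atlas.labels[max_index])
    n = atlas.n_per_hemisphere
    mask_hemis = {lbl // n for lbl in mask_labels}
    return label in mask_labels, (label // n) in mask_hemis


def _localize(epochs, op: InverseOperator, fallback_sample: int | None = None) -> tuple[int, int]:
    """Average, find half-rise (with fallback), invert, return (max index, sample)."""
    avg = average_epochs(epochs)
    try:
        sample = find_half_rise(avg)
    except NoPeakError:
        if fallback_sample is None:
            raise
        sample = fallback_sample
        log.debug("half-rise failed on subsample; falling back to full-average sample")
    src_map = apply_inverse(op, avg, sample)
    return find_source_maximum(src_map), sample


def subsample_experiment(
    epochs,
    inverse_op: InverseOperator,
    grid: SourceGrid,
    mask: ResectionMask,
    Ns,
    n_reps: int = DEFAULT_SUBSAMPLE_REPS,
    seed: int | None = 0,
) -> SubsamplingCurve:
    """Effect of the number of averaged spikes on source-maximum localization.

    The full-average maximum is computed once.  For each N and repetition, N
    epochs are drawn without replacement, averaged, localized at their
    half-rise sample (falling back to the full-average half-rise when the
    subaverage has no detectable rise), and two distances recorded: to the
    full-average maximum and to the resection mask.
    """
    n_total = len(epochs)
    Ns = [int(n) for n in Ns]
    if not Ns:
        raise ParameterError("Ns may not be empty")
    if any(n < 1 or n > n_total for n in Ns):
        raise ParameterError(f"every N must be in [1, {n_total}], got {Ns}")
    if sorted(Ns) != Ns or len(set(Ns)) != len(Ns):
        raise ParameterError("Ns must be strictly increasing")
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")

    full_max, full_sample = _localize(epochs, inverse_op)
    full_pos = grid.positions[full_max]

    streams = np.random.SeedSequence(seed).spawn(len(Ns) * n_reps)
    m_full, s_full, m_mask, s_mask = [], [], [], []
    for i, n in enumerate(Ns):
        d_full, d_mask = [], []
        for rep in range(n_reps):
            rng = np.random.default_rng(streams[i * n_reps + rep])
            take = rng.choice(n_total, size=n, replace=False)
            idx, _ = _localize([epochs[k] for k in take], inverse_op, full_sample)
            d_full.append(float(np.linalg.norm(grid.positions[idx] - full_pos)))
            d_mask.append(distance_to_mask(idx, mask, grid))
        m_full.append(float(np.mean(d_full)))
        s_full.append(float(np.std(d_full)))
        m_mask.append(float(np.mean(d_mask)))
        s_mask.append(float(np.std(d_mask)))
    return SubsamplingCurve(
        Ns=tuple(Ns),
        n_reps=n_reps,
        mean_dist_to_full_mm=tuple(m_full),
        sd_dist_to_full_mm=tuple(s_full),
        mean_dist_to_mask_mm=tuple(m_mask),
        sd_dist_to_mask_mm=tuple(s_mask),
        n_total=n_total,
        seed=seed,
        full_max_index=full_max,
    )


def smallest_N_below(
    curve: SubsamplingCurve, threshold_mm: float = DEFAULT_DISTANCE_THRESHOLD_MM
) -> int | None:
    """Smallest N whose mean distance-to-full-maximum is below the threshold,
    with every larger sampled N also below it; None if no such N."""
    if threshold_mm <= 0:
        raise ParameterError("threshold must be positive")
    means = curve.mean_dist_to_full_mm
    result = None
    for n, m in zip(reversed(curve.Ns), reversed(means)):
        if m < threshold_mm:
            result = n
        else:
            break
    return result
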