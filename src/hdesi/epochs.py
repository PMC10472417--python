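"""Event epochs: extraction around marks, artifact rejection, averaging, and
the 50%-rising-phase sample of the averaged spike."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InputError, NoPeakError, ParameterError
from .detect import MarkList
from .simulate import SimulatedRecording

__all__ = [
    "Epoch",
    "AverageIED",
    "extract_epochs",
    "reject_artifact_epochs",
    "average_epochs",
    "find_half_rise",
]

log = logging.getLogger(__name__)

DEFAULT_HALF_WIDTH_S = 2.0
#: baseline window relative to the epoch center, seconds
BASELINE_WINDOW_S = (-1.5, -0.5)
#: peak search restricted to this window around the epoch center, seconds
PEAK_SEARCH_S = 0.5
DEFAULT_PTP_THRESHOLD_UV = 300.0


@dataclass(frozen=True)
class Epoch:
    """A fixed window around one event mark; an exact slice of the recording."""

    data: np.ndarray  # channels x samples
    mark_time_s: float
    sampling_rate_Hz: float
    channel_ids: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def center_sample(self) -> int:
        return self.n_samples // 2

    def max_peak_to_peak(self) -> float:
        return float(np.max(self.data.max(axis=1) - self.data.min(axis=1)))


@dataclass
class AverageIED:
    """Cluster-average waveform with its peak bookkeeping."""

    data: np.ndarray  # channels x samples, mean across epochs
    n_epochs: int
    sampling_rate_Hz: float
    channel_ids: tuple[str, ...]
    peak_channel: int
    peak_sample: int
    half_rise_sample: int | None = None

    @property
    def center_sample(self) -> int:
        return self.data.shape[1] // 2


def extract_epochs(
    recording: SimulatedRecording,
    marks: MarkList,
    half_width_s: float = DEFAULT_HALF_WIDTH_S,
) -> list[Epoch]:
    """One epoch per mark that fits fully inside the recording.

    Marks too close to an edge are skipped (logged).  Epoch data is an exact
    slice — no filtering or resampling.
    """
    if half_width_s <= 0:
        raise ParameterError(f"half_width_s must be positive, got {half_width_s}")
    rate = recording.sampling_rate_Hz
    n_half = int(round(half_width_s * rate))
    out, skipped = [], 0
    for t in marks.times:
        c = int(round(t * rate))
        if c - n_half < 0 or c + n_half + 1 > recording.n_samples:
            skipped += 1
            continue
        out.append(
            Epoch(
                data=recording.data[:, c - n_half : c + n_half + 1],
                mark_time_s=float(t),
                sampling_rate_Hz=rate,
                channel_ids=recording.channel_ids,
            )
        )
    if skipped:
        log.info("extract_epochs: skipped %d edge mark(s) of %d", skipped, len(marks))
    return out


def reject_artifact_epochs(
    epochs: list[Epoch], ptp_threshold_uV: float = DEFAULT_PTP_THRESHOLD_UV
) -> list[Epoch]:
    """Drop epochs whose worst-channel peak-to-peak amplitude exceeds the threshold."""
    if ptp_threshold_uV < 0:
        raise ParameterError("ptp_threshold_uV must be >= 0")
    kept = [e for e in epochs if e.max_peak_to_peak() <= ptp_threshold_uV]
    if epochs and not kept:
        log.warning("reject_artifact_epochs: all %d epochs rejected", len(epochs))
    return kept


def average_epochs(epochs: list[Epoch]) -> AverageIED:
    """Arithmetic mean across epochs; peak = max |mean| near the epoch center."""
    if not epochs:
        raise InputError("cannot average zero epochs")
    shapes = {e.data.shape for e in epochs}
    if len(shapes) != 1:
        raise InputError(f"epoch shapes differ: {sorted(shapes)}")
    mean = np.mean([e.data for e in epochs], axis=0)
    rate = epochs[0].sampling_rate_Hz
    center = mean.shape[1] // 2
    w = int(round(PEAK_SEARCH_S * rate))
    lo, hi = max(center - w, 0), min(center + w + 1, mean.shape[1])
    window = np.abs(mean[:, lo:hi])
    ch, rel = np.unravel_index(np.argmax(window), window.shape)
    return AverageIED(
        data=mean,
        n_epochs=len(epochs),
        sampling_rate_Hz=rate,
        channel_ids=epochs[0].channel_ids,
        peak_channel=int(ch),
        peak_sample=int(lo + rel),
    )


def _half_rise_scan(trace: np.ndarray, peak: int, baseline: float) -> int:
    """First sample of the rising flank reaching 50% of (peak - baseline)."""
    exc = trace - baseline
    sign = np.sign(exc[peak]) or 1.0
    exc = exc * sign
    if exc[peak] <= 0:
        raise NoPeakError("no excursion above baseline at the peak")
    crossings = np.flatnonzero(exc[:peak] <= 0)
    if crossings.size == 0:
        raise NoPeakError("no baseline crossing before the peak")
    start = int(crossings[-1])
    half = 0.5 * exc[peak]
    above = np.flatnonzero(exc[start : peak + 1] >= half)
    if above.size == 0:  # pragma: no cover - peak itself satisfies >= half
        raise NoPeakError("rising phase never reaches 50%")
    return start + int(above[0])


def find_half_rise(avg: AverageIED, mode: str = "peak_channel", min_snr: float = 5.0) -> int:
    """Sample index where the rising phase reaches 50% of peak minus baseline.

    Baseline is the mean of the [-1.5, -0.5] s window before the epoch center;
    the rising phase runs from the last baseline crossing to the peak.
    Polarity-agnostic.  ``mode='gfp'`` uses the global field power (std across
    channels) instead of the single peak channel.

    Raises :class:`NoPeakError` if the peak excursion is below ``min_snr``
    baseline standard deviations or there is no baseline crossing.
    """
    rate = avg.sampling_rate_Hz
    center = avg.center_sample
    b0 = center + int(round(BASELINE_WINDOW_S[0] * rate))
    b1 = center + int(round(BASELINE_WINDOW_S[1] * rate))
    b0 = max(b0, 0)
    if b1 <= b0:
        raise ParameterError("epoch too short for the baseline window")

    if mode == "peak_channel":
        trace = avg.data[avg.peak_channel]
        peak = avg.peak_sample
    elif mode == "gfp":
        trace = avg.data.std(axis=0)
        w = int(round(PEAK_SEARCH_S * rate))
        lo = max(center - w, 0)
        peak = lo + int(np.argmax(trace[lo : center + w + 1]))
    else:
        raise ParameterError(f"unknown mode {mode!r}")

    baseline = float(trace[b0:b1].mean())
    base_sd = float(trace[b0:b1].std())
    if abs(trace[peak] - baseline) <= min_snr * base_sd:
        raise NoPeakError(
            f"peak excursion {abs(trace[peak] - baseline):.3g} below "
            f"{min_snr} x baseline SD {base_sd:.3g}"
        )
    idx = _half_rise_scan(trace, peak, baseline)
    avg.half_rise_sample = idx
    return idx
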