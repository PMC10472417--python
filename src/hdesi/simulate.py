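"""Ground-truthed synthetic hdEEG: spike-wave templates, 1/f background,
event injection through the lead field, and resection masks.

Every generator takes an explicit seed and is bit-for-bit reproducible.  Event
times keep >= 4 s pairwise spacing and >= 2 s edge margins so that the +/-2 s
analysis epochs never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CapacityError, GeometryError, ParameterError
from .forward import LeadField

__all__ = [
    "IEDTemplate",
    "GroundTruthEvent",
    "SimulatedRecording",
    "ResectionMask",
    "generate_ied_template",
    "generate_background",
    "simulate_recording",
    "make_resection_mask",
]

MIN_EVENT_SPACING_S = 4.0
EDGE_MARGIN_S = 2.0

#: relative amplitude of the slow wave vs the spike peak
SLOW_WAVE_RATIO = 0.3


@dataclass(frozen=True)
class IEDTemplate:
    """Unit-peak spike-and-slow-wave shape sampled at a fixed rate."""

    waveform: np.ndarray
    sampling_rate_Hz: float
    peak_sample: int
    spike_width_ms: float
    slow_wave_width_ms: float
    polarity: int

    @property
    def n_samples(self) -> int:
        return self.waveform.shape[0]


@dataclass(frozen=True)
class GroundTruthEvent:
    time_s: float
    grid_index: int
    moment_nAm: np.ndarray  # 3-vector, includes the per-event amplitude scale
    amplitude_scale: float


@dataclass(frozen=True)
class SimulatedRecording:
    """Multichannel EEG (uV) with its embedded ground truth."""

    data: np.ndarray  # channels x samples
    sampling_rate_Hz: float
    channel_ids: tuple[str, ...]
    events: tuple[GroundTruthEvent, ...]
    seed: int | None = None
    leadfield: LeadField | None = field(default=None, repr=False)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_Hz


@dataclass(frozen=True)
class ResectionMask:
    """Grid indices treated as the resected volume."""

    indices: np.ndarray  # sorted int array, non-empty
    center_index: int | None = None
    radius_mm: float | None = None

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, int))
        if idx.size == 0:
            raise ParameterError("resection mask may not be empty")
        object.__setattr__(self, "indices", idx)

    def __contains__(self, index: int) -> bool:
        return bool(np.isin(index, self.indices))


def _ied_shape(t_s: np.ndarray, spike_width_ms: float, slow_wave_width_ms: float) -> np.ndarray:
    """Continuous-time spike + opposite-sign slow wave, before normalization.

    Widths are FWHMs of the two Gaussian phases; t = 0 at the nominal spike
    center.  6-sigma support keeps the edges below 1e-6 of the peak.
    """
    sig_s = spike_width_ms / 1000.0 / 2.3548200450309493  # FWHM -> sigma
    sig_w = slow_wave_width_ms / 1000.0 / 2.3548200450309493
    t_wave = (spike_width_ms + slow_wave_width_ms) / 2.0 / 1000.0
    return np.exp(-0.5 * (t_s / sig_s) ** 2) - SLOW_WAVE_RATIO * np.exp(
        -0.5 * ((t_s - t_wave) / sig_w) ** 2
    )


def generate_ied_template(
    rate: float,
    spike_width_ms: float = 70.0,
    slow_wave_width_ms: float = 300.0,
    polarity: int = 1,
) -> IEDTemplate:
    """Biphasic interictal spike-wave template, normalized to unit peak."""
    if rate not in (250, 1000):
        raise ParameterError(f"sampling rate must be 250 or 1000 Hz, got {rate}")
    if spike_width_ms <= 0 or slow_wave_width_ms <= 0:
        raise ParameterError("widths must be positive")
    if polarity not in (1, -1):
        raise ParameterError(f"polarity must be +1 or -1, got {polarity}")
    sig_s = spike_width_ms / 1000.0 / 2.3548200450309493
    sig_w = slow_wave_width_ms / 1000.0 / 2.3548200450309493
    t_wave = (spike_width_ms + slow_wave_width_ms) / 2.0 / 1000.0
    t0 = min(-6.0 * sig_s, t_wave - 6.0 * sig_w)
    t1 = max(6.0 * sig_s, t_wave + 6.0 * sig_w)
    n = int(np.ceil((t1 - t0) * rate)) + 1
    t = t0 + np.arange(n) / rate
    w = _ied_shape(t, spike_width_ms, slow_wave_width_ms)
    peak = int(np.argmax(np.abs(w)))
    w = polarity * w / np.abs(w[peak])
    return IEDTemplate(
        waveform=w,
        sampling_rate_Hz=rate,
        peak_sample=peak,
        spike_width_ms=spike_width_ms,
        slow_wave_width_ms=slow_wave_width_ms,
        polarity=polarity,
    )


def generate_background(
    n_channels: int,
    n_samples: int,
    rate: float,
    spectral_exponent: float = 1.0,
    rms_uV: float = 10.0,
    seed: int | np.random.SeedSequence | None = None,
) -> np.ndarray:
    """Independent per-channel noise with PSD ~ 1/f^exponent and exact RMS."""
    if not 0 <= spectral_exponent <= 2:
        raise ParameterError(f"spectral_exponent must be in [0, 2], got {spectral_exponent}")
    if rms_uV <= 0:
        raise ParameterError(f"rms_uV must be positive, got {rms_uV}")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-spectral_exponent / 2.0)
    noise = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    scale = rms_uV / np.sqrt(np.mean(noise**2, axis=1, keepdims=True))
    return noise * scale


def _draw_event_times(
    n_events: int, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Sorted times with >= 4 s spacing and >= 2 s edge margins."""
    usable = duration_s - 2 * EDGE_MARGIN_S - (n_events - 1) * MIN_EVENT_SPACING_S
    if usable < 0:
        raise CapacityError(
            f"{n_events} events with {MIN_EVENT_SPACING_S} s spacing do not fit "
            f"into {duration_s} s"
        )
    slack = np.sort(rng.uniform(0.0, usable, size=n_events))
    return EDGE_MARGIN_S + slack + MIN_EVENT_SPACING_S * np.arange(n_events)


def _moment_direction(leadfield: LeadField, grid_index: int, orientation) -> np.ndarray:
    if isinstance(orientation, str):
        pos = leadfield.grid.positions[grid_index]
        r = np.linalg.norm(pos)
        radial = pos / r if r > 1e-9 else np.array([0.0, 0.0, 1.0])
        if orientation == "radial":
            return radial
        if orientation == "tangential":
            ref = np.array([0.0, 0.0, 1.0])
            if abs(radial @ ref) > 0.99:
                ref = np.array([1.0, 0.0, 0.0])
            t = np.cross(radial, ref)
            return t / np.linalg.norm(t)
        raise ParameterError(f"unknown orientation {orientation!r}")
    v = np.asarray(orientation, float)
    if v.shape != (3,) or np.linalg.norm(v) == 0:
        raise ParameterError("orientation vector must be a nonzero 3-vector")
    return v / np.linalg.norm(v)


def simulate_recording(
    leadfield: LeadField,
    template: IEDTemplate,
    n_events: int,
    event_grid_index: int,
    amplitude_nAm: float = 100.0,
    jitter_amplitude_frac: float = 0.0,
    noise_rms_uV: float = 10.0,
    duration_s: float = 120.0,
    rate: float | None = None,
    seed: int | None = 0,
    orientation="radial",
    spectral_exponent: float = 1.0,
) -> SimulatedRecording:
    """Project spike-wave events through the lead field and add 1/f background.

    Each event contributes ``template * amplitude * (1 + jitter)`` nAm along a
    fixed moment direction at one grid point.  Event placement and noise use
    independent child streams of ``seed``, so the background of a run with
    ``n_events = 0`` is identical to the background component of any other run
    with the same seed.
    """
    if n_events < 0:
        raise ParameterError("n_events must be >= 0")
    if not 0 <= jitter_amplitude_frac < 1:
        raise ParameterError("jitter_amplitude_frac must be in [0, 1)")
    if not 0 <= event_grid_index < leadfield.n_sources:
        raise GeometryError(
            f"grid index {event_grid_index} outside [0, {leadfield.n_sources})"
        )
    rate = float(rate if rate is not None else template.sampling_rate_Hz)
    if rate != template.sampling_rate_Hz:
        raise ParameterError("template sampling rate must match the recording rate")
    n_samples = int(round(duration_s * rate))
    n_ch = leadfield.n_channels

    ss_events, ss_noise = np.random.SeedSequence(seed).spawn(2)
    rng_ev = np.random.default_rng(ss_events)

    if noise_rms_uV > 0:
        data = generate_background(
            n_ch, n_samples, rate, spectral_exponent, noise_rms_uV, ss_noise
        )
    else:
        data = np.zeros((n_ch, n_samples))

    events: list[GroundTruthEvent] = []
    if n_events > 0:
        times = _draw_event_times(n_events, duration_s, rng_ev)
        jitters = rng_ev.uniform(-jitter_amplitude_frac, jitter_amplitude_frac, n_events)
        direction = _moment_direction(leadfield, event_grid_index, orientation)
        topo = leadfield.source_gain(event_grid_index) @ direction  # uV per nAm
        for t, j in zip(times, jitters):
            scale = amplitude_nAm * (1.0 + j)
            peak_idx = int(round(t * rate))
            start = peak_idx - template.peak_sample
            lo, hi = max(start, 0), min(start + template.n_samples, n_samples)
            seg = template.waveform[lo - start : hi - start]
            data[:, lo:hi] += scale * topo[:, None] * seg[None, :]
            events.append(
                GroundTruthEvent(
                    time_s=peak_idx / rate,
                    grid_index=event_grid_index,
                    moment_nAm=direction * scale,
                    amplitude_scale=scale,
                )
            )
    return SimulatedRecording(
        data=data,
        sampling_rate_Hz=rate,
        channel_ids=leadfield.electrodes.channel_ids,
        events=tuple(events),
        seed=seed,
        leadfield=leadfield,
    )


def make_resection_mask(grid, center_index: int, radius_mm: float) -> ResectionMask:
    """All grid points within ``radius_mm`` of the center point (center included)."""
    if radius_mm < 0:
        raise ParameterError(f"radius must be >= 0, got {radius_mm}")
    if not 0 <= center_index < grid.n_points:
        raise GeometryError(f"center index {center_index} outside [0, {grid.n_points})")
    d = np.linalg.norm(grid.positions - grid.positions[center_index], axis=1)
    members = np.flatnonzero(d <= radius_mm + 1e-9)
    return ResectionMask(indices=members, center_index=center_index, radius_mm=radius_mm)
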