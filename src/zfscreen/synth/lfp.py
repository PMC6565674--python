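"""Synthetic local field potential traces with planted seizure bursts.

Background activity is 1/f-like noise; seizures are multi-peak
high-amplitude bursts (trains of sharp biphasic transients under a rapid
rise / slow decay envelope) matching the morphology of photosensitive
seizure discharges in the epilepsy model. Event amplitude is expressed as
an SNR multiple of the background standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LFPTrace:
    """Single-channel LFP recording in millivolts."""

    samples: np.ndarray
    rate: float
    true_events: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        dur = len(self.samples) / self.rate
        last = 0.0
        for start, end in self.true_events:
            if start < last or end > dur or end <= start:
                raise ValueError("events must be ordered, non-overlapping, in range")
            last = end

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


def _pink_noise(n: int, rate: float, rng: np.random.Generator, sd: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec /= np.sqrt(np.maximum(freqs, 0.5))
    x = np.fft.irfft(spec, n)
    return x / x.std() * sd


def _burst(duration: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """One seizure burst: sharp biphasic spikes at ~4-8 Hz under an envelope."""
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    out = np.zeros(n)
    spike_freq = rng.uniform(4.0, 8.0)
    width = 0.02  # s, sharpness of each transient
    times = np.arange(0.1, duration - 0.1, 1.0 / spike_freq)
    times = times + rng.normal(0.0, 0.02, size=times.shape)
    for ts in times:
        amp = rng.uniform(0.7, 1.3)
        # Biphasic: derivative-of-Gaussian transient.
        out += amp * -(t - ts) / width * np.exp(-((t - ts) ** 2) / (2 * width**2))
    env = (1.0 - np.exp(-t / 0.2)) * np.exp(-np.maximum(t - 0.6 * duration, 0.0) / (0.4 * duration))
    out *= env
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out


def simulate_lfp(
    duration: float,
    rate: float = 100.0,
    event_rate: float = 0.5,
    snr: float = 8.0,
    seed: int = 0,
    event_times: list[float] | None = None,
    event_duration: tuple[float, float] = (2.0, 5.0),
    background_sd: float = 0.05,
) -> LFPTrace:
    """Simulate an LFP recording with planted seizure events.

    Parameters
    ----------
    duration, rate
        Trace length (s) and sampling rate (Hz); both must be positive.
    event_rate
        Expected seizures per minute (Poisson); ignored when explicit
        ``event_times`` (event onsets, s) are given.
    snr
        Peak burst amplitude in units of the background SD.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    x = _pink_noise(n, rate, rng, background_sd)

    if event_times is None:
        n_ev = rng.poisson(event_rate * duration / 60.0)
        starts = np.sort(rng.uniform(1.0, max(duration - event_duration[1] - 1.0, 1.0), n_ev))
    else:
        starts = np.asarray(sorted(event_times), dtype=float)

    events: list[tuple[float, float]] = []
    last_end = 0.0
    for s in starts:
        d = rng.uniform(*event_duration)
        if s < last_end + 1.0:  # enforce non-overlap with a 1 s guard
            if event_times is not None:
                raise ValueError(f"requested event at {s} s overlaps the previous event")
            continue
        if s + d > duration:
            d = duration - s
            if d < 0.5:
                continue
        i0 = int(round(s * rate))
        burst = _burst(d, rate, rng) * snr * background_sd
        x[i0:i0 + len(burst)] += burst
        events.append((float(s), float(s + d)))
        last_end = s + d
    return LFPTrace(samples=x, rate=rate, true_events=events)
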