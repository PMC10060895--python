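"""Synthetic scalp EEG with known injected epileptiform spikes.

Emulates the study conditions of a centro-temporal (rolandic) epilepsy
recording: 16-channel 10-20 scalp EEG at 1 kHz, spikes concentrated on
C3/P3 with amplitude far above background, 20-70 ms duration, and elevated
cross-channel phase synchrony during each discharge.  Every event is
recorded in an :class:`AnnotationSet`, so downstream detection, feature
extraction and classification can be scored against exact ground truth.

The background model is the sum of

* 1/f ("pink") broadband noise per channel,
* a posterior-dominant ~10 Hz rhythm, and
* sparse non-epileptiform sharp transients (single channel, 2-5x the
  background standard deviation, 40-120 ms) whose slopes straddle the
  morphology gates of the matcher, so the candidate stage over-generates
  the way real recordings do.

It is deliberately simple: no blink/EMG artifact modeling, no
spike-and-wave complexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CapacityError, ConfigError
from .signal_io import AV_CHANNELS, Recording

#: Channels carrying the posterior-dominant alpha rhythm, by weight.
_ALPHA_VARIANCE_SHARE = {
    "O1": 0.40, "O2": 0.40, "P3": 0.25, "P4": 0.25, "T5": 0.25, "T6": 0.25,
}
_ALPHA_DEFAULT_SHARE = 0.08

#: Background sharp-transient model (per-recording rate and ranges).
_TRANSIENT_RATE_HZ = 0.3
_TRANSIENT_AMP_RANGE = (2.0, 5.0)      # x background_std
_TRANSIENT_DURATION_MS = (40.0, 120.0)

#: Common-phase burst injected during each spike epoch: amplitude scale
#: (x background_std, before the per-channel gain and sync_strength) and
#: per-channel gain spread.
_SYNC_AMP_FACTOR = 3.0
_SYNC_GAIN_RANGE = (0.5, 1.5)
_SYNC_HALF_WINDOW_MS = 50.0

#: Minimum apex separation; keeps 300 ms analysis frames on one event.
MIN_SEPARATION_S = 0.6
_EDGE_MARGIN_S = 0.4


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated recording."""

    duration: float = 1200.0          # seconds (~20 min, as in the study data)
    fs: float = 1000.0                # Hz
    n_channels: int = 16
    labels: tuple[str, ...] = AV_CHANNELS
    spike_channels: tuple[str, ...] = ("C3", "P3")
    n_spikes: int = 240
    spike_amplitude: float = 300.0    # µV
    spike_duration_ms: float = 60.0   # within the clinical 20-70 ms range
    spike_sign: float = -1.0          # surface-negative by clinical convention
    discharge_mode: str = "multi"     # single | multi
    sync_strength: float = 0.8        # [0, 1] cross-channel phase coupling
    background_std: float = 20.0      # µV
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.fs <= 0:
            raise ConfigError("duration and fs must be positive")
        if self.n_channels != len(self.labels):
            raise ConfigError("n_channels must match the label list")
        if not (20.0 <= self.spike_duration_ms <= 70.0):
            raise ConfigError(
                f"spike_duration_ms must lie in [20, 70], got {self.spike_duration_ms}"
            )
        unknown = [c for c in self.spike_channels if c.upper() not in self.labels]
        if unknown:
            raise ConfigError(f"spike_channels not in channel labels: {unknown}")
        if not (0.0 <= self.sync_strength <= 1.0):
            raise ConfigError("sync_strength must lie in [0, 1]")
        if self.discharge_mode not in ("single", "multi"):
            raise ConfigError(f"unknown discharge_mode {self.discharge_mode!r}")
        if self.background_std < 0:
            raise ConfigError("background_std must be non-negative")
        if self.n_spikes < 0:
            raise ConfigError("n_spikes must be non-negative")
        object.__setattr__(self, "spike_channels",
                           tuple(c.upper() for c in self.spike_channels))


@dataclass(frozen=True)
class AnnotationSet:
    """Ground-truth spike events: (channel label, apex sample index, label)."""

    events: tuple[tuple[str, int, str], ...]
    fs: float

    def __post_init__(self):
        # sorted by time within channel
        events = tuple(sorted(self.events, key=lambda e: (e[0], e[1])))
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return len(self.events)

    def for_channel(self, label: str) -> np.ndarray:
        """Apex sample indices on one channel, sorted."""
        label = label.upper()
        return np.array([e[1] for e in self.events if e[0] == label], dtype=int)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(sorted({e[0] for e in self.events}))

    def to_frame(self) -> pd.DataFrame:
        rows = [(ch, idx, idx / self.fs, lab) for ch, idx, lab in self.events]
        return pd.DataFrame(rows, columns=["channel", "apex_sample",
                                           "apex_seconds", "label"])


def write_annotations(annotations: AnnotationSet, path) -> None:
    annotations.to_frame().to_csv(path, index=False)


def read_annotations(path, fs: float) -> AnnotationSet:
    frame = pd.read_csv(path)
    events = tuple(
        (str(r.channel).upper(), int(r.apex_sample), str(r.label))
        for r in frame.itertuples()
    )
    return AnnotationSet(events=events, fs=fs)


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------

def make_spike_waveform(amplitude: float, duration_ms: float, fs: float) -> np.ndarray:
    """Symmetric triangular spike: zero at both ends, ``amplitude`` at midpoint.

    Length is ``round(duration_ms * fs / 1000) + 1`` samples, so a
    300 µV / 60 ms template at 1 kHz spans 61 samples peaking at index 30.
    """
    if amplitude <= 0:
        raise ConfigError(f"amplitude must be positive, got {amplitude}")
    n = int(round(duration_ms * fs / 1000.0)) + 1
    if n < 3:
        raise ConfigError(
            f"duration {duration_ms} ms is under 2 samples at fs={fs}"
        )
    mid = (n - 1) / 2.0
    return np.interp(np.arange(n), [0.0, mid, n - 1.0], [0.0, amplitude, 0.0])


def _unit_std(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return x / s if s > 0 else x


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    spec[0] = 0.0  # zero mean
    spec[1:] /= np.sqrt(freqs[1:])
    return _unit_std(np.fft.irfft(spec, n))


# ---------------------------------------------------------------------------
# Background
# ---------------------------------------------------------------------------

def generate_background(config: SimulationConfig) -> Recording:
    """Background EEG: pink noise + posterior alpha + sparse sharp transients.

    Deterministic under ``config.seed``; channel means are ~0 and the
    per-channel standard deviation is ~``background_std``.
    """
    n = int(round(config.duration * config.fs))
    data = np.zeros((config.n_channels, n))
    if config.background_std == 0:
        return Recording(data=data, fs=config.fs, labels=config.labels)

    rng = np.random.default_rng([config.seed, 0])
    t = np.arange(n) / config.fs
    for i, label in enumerate(config.labels):
        share = _ALPHA_VARIANCE_SHARE.get(label, _ALPHA_DEFAULT_SHARE)
        pink = _pink_noise(rng, n)
        # amplitude-modulated alpha (waxing/waning spindles of ~1 s)
        envelope = 1.0 + 0.5 * np.sin(2 * np.pi * rng.uniform(0.3, 0.7) * t
                                      + rng.uniform(0, 2 * np.pi))
        alpha = _unit_std(envelope * np.sin(2 * np.pi * 10.0 * t
                                            + rng.uniform(0, 2 * np.pi)))
        data[i] = np.sqrt(1 - share) * pink + np.sqrt(share) * alpha

    # sparse non-epileptiform sharp transients on single random channels
    n_transients = rng.poisson(_TRANSIENT_RATE_HZ * config.duration)
    for _ in range(n_transients):
        ch = rng.integers(config.n_channels)
        dur = rng.uniform(*_TRANSIENT_DURATION_MS)
        amp = rng.uniform(*_TRANSIENT_AMP_RANGE)
        wave = make_spike_waveform(amp, dur, config.fs) * rng.choice([-1.0, 1.0])
        start = rng.integers(0, max(1, n - len(wave)))
        data[ch, start : start + len(wave)] += wave[: n - start]

    data *= config.background_std
    data -= data.mean(axis=1, keepdims=True)
    return Recording(data=data, fs=config.fs, labels=config.labels)


# ---------------------------------------------------------------------------
# Spike injection
# ---------------------------------------------------------------------------

def _draw_apex_times(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """Event apex times with pairwise separation > MIN_SEPARATION_S, uniform
    over the feasible set (order statistics of a shrunk interval)."""
    n = config.n_spikes
    lo, hi = _EDGE_MARGIN_S, config.duration - _EDGE_MARGIN_S
    slack = (hi - lo) - (n - 1) * MIN_SEPARATION_S
    if n == 0:
        return np.array([])
    if hi <= lo or slack <= 0:
        raise CapacityError(
            f"{n} spikes at >{MIN_SEPARATION_S}s separation do not fit "
            f"{config.duration}s"
        )
    u = np.sort(rng.uniform(0, slack, size=n))
    return lo + u + np.arange(n) * MIN_SEPARATION_S


def inject_spikes(recording: Recording,
                  config: SimulationConfig) -> tuple[Recording, AnnotationSet]:
    """Add triangular spikes (and spike-epoch synchrony bursts) to a recording.

    In ``multi`` discharge mode every event hits all ``spike_channels`` at the
    same apex; in ``single`` mode each event hits one of them (round-robin).
    During each spike epoch (apex +/- 50 ms) all channels additionally
    receive a narrowband (14.5-70 Hz) component with a common phase but
    per-channel random gain, scaled by ``sync_strength``, so that
    spike-epoch pairwise phase locking exceeds background phase locking.
    The recording length is unchanged.
    """
    rng = np.random.default_rng([config.seed, 1])
    data = recording.data.copy()
    n = recording.n_samples
    fs = recording.fs
    apex_times = _draw_apex_times(rng, config)

    half_sync = int(round(_SYNC_HALF_WINDOW_MS * fs / 1000.0))
    sync_window = np.hanning(2 * half_sync + 1)
    t_sync = np.arange(2 * half_sync + 1) / fs

    events: list[tuple[str, int, str]] = []
    for k, t_apex in enumerate(apex_times):
        apex = int(round(t_apex * fs))
        if config.discharge_mode == "multi":
            targets = config.spike_channels
        else:
            targets = (config.spike_channels[k % len(config.spike_channels)],)

        amp = config.spike_amplitude * rng.uniform(1.0, 1.2)
        wave = config.spike_sign * make_spike_waveform(
            amp, config.spike_duration_ms, fs
        )
        half = (len(wave) - 1) // 2
        for label in targets:
            i = recording.labels.index(label)
            start = apex - half
            data[i, start : start + len(wave)] += wave
            events.append((label, apex, "spike"))

        if config.sync_strength > 0 and config.background_std > 0:
            freq = rng.uniform(14.5, 70.0)
            # phase anchored so the burst crosses zero at the spike apex and
            # never erodes the apex amplitude; sign randomized
            phase = (np.pi * rng.integers(0, 2)
                     - 2 * np.pi * freq * t_sync[half_sync])
            burst = np.sin(2 * np.pi * freq * t_sync + phase) * sync_window
            gains = rng.uniform(*_SYNC_GAIN_RANGE, size=config.n_channels)
            scale = (config.sync_strength * _SYNC_AMP_FACTOR
                     * config.background_std)
            lo = apex - half_sync
            seg = slice(max(lo, 0), min(lo + len(burst), n))
            boff = seg.start - lo
            data[:, seg] += (scale * gains)[:, None] * burst[boff : boff + seg.stop - seg.start]

    out = Recording(data=data, fs=fs, labels=recording.labels,
                    montage=recording.montage)
    return out, AnnotationSet(events=tuple(events), fs=fs)


def simulate(config: SimulationConfig) -> tuple[Recording, AnnotationSet]:
    """Background plus injected spikes, in one call."""
    return inject_spikes(generate_background(config), config)
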