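"""Phase-locking-value (PLV) functional brain networks.

The instantaneous phase of each (band-limited) channel comes from the
analytic signal Z = x + iH(x), with H the Hilbert transform; the PLV of a
channel pair over a window of N samples is

    PLV = | (1/N) sum_n exp(i (p*phi_x[n] - q*phi_y[n])) |

— the modulus of the mean unit phasor of the phase difference, a pure
phase statistic in [0, 1] (1 = perfect locking) that is invariant to
amplitude scaling of either signal.  Signals are band-passed to the spike
band (14.5-70 Hz by default; spikes last 20-70 ms) before the Hilbert
transform, since instantaneous phase is only interpretable for narrowband
signals.  One functional brain network per candidate epoch is obtained by
averaging the pairwise PLV matrices of the non-overlapping 100 ms windows
tiling the 300 ms candidate frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigError, InsufficientDataError, UndefinedPhaseError
from .signal_io import Recording


@dataclass(frozen=True)
class PLVConfig:
    """Windowing and band parameters of the network construction."""

    window_ms: float = 100.0
    step_ms: float = 100.0
    band: tuple[float, float] = (14.5, 70.0)
    p: int = 1
    q: int = 1
    pad_ms: float = 50.0   # reflect padding before the Hilbert transform
    filter_order: int = 4

    def __post_init__(self):
        if self.window_ms <= 0 or self.step_ms <= 0:
            raise ConfigError("window_ms and step_ms must be positive")
        if not (0 < self.band[0] < self.band[1]):
            raise ConfigError(f"invalid band {self.band}")


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous phase (radians, in (-pi, pi]) and amplitude envelope."""

    phase: np.ndarray
    amplitude_envelope: np.ndarray
    fs: float


@dataclass(frozen=True)
class FBN:
    """Symmetric weighted adjacency of PLV values over the AV channels."""

    nodes: tuple[str, ...]
    weights: np.ndarray  # n x n, in [0, 1], unit diagonal

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise ConfigError("weights must be square over the node labels")
        if not np.allclose(w, w.T, atol=1e-9):
            raise ConfigError("weights must be symmetric")
        if w.min() < -1e-9 or w.max() > 1 + 1e-9:
            raise ConfigError("PLV weights must lie in [0, 1]")
        if not np.allclose(np.diag(w), 1.0):
            raise ConfigError("diagonal must be 1")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def mean_offdiagonal(self) -> float:
        n = self.n_nodes
        return float((self.weights.sum() - n) / (n * (n - 1)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.nodes),
                            columns=list(self.nodes))

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def _analytic(x: np.ndarray, fs: float, config: PLVConfig) -> np.ndarray:
    """Band-passed analytic signal with reflect padding trimmed off."""
    low, high = config.band
    if high >= fs / 2:
        raise ConfigError(f"band upper edge {high} Hz >= Nyquist {fs / 2} Hz")
    pad = int(round(config.pad_ms * fs / 1000.0))
    pad = min(pad, x.shape[-1] - 1)
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    sos = sps.butter(config.filter_order, [low, high], btype="bandpass",
                     fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, xp, axis=-1)
    z = sps.hilbert(filtered, axis=-1)
    return z[..., pad : pad + x.shape[-1]] if pad else z


def instantaneous_phase(x: np.ndarray, fs: float,
                        band: tuple[float, float] = (14.5, 70.0),
                        config: PLVConfig | None = None) -> PhaseSeries:
    """Hilbert instantaneous phase and envelope of a band-passed signal.

    The phase is the argument of the analytic signal — the quadrant-aware
    form of arctan(H(x)/x), defined also where x(t) = 0.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ConfigError("signal must be 1-D with at least 8 samples")
    if not np.any(x):
        raise UndefinedPhaseError("phase undefined for an all-zero signal")
    if config is None:
        config = PLVConfig(band=band)
    z = _analytic(x, fs, config)
    return PhaseSeries(phase=np.angle(z), amplitude_envelope=np.abs(z), fs=fs)


def plv_pair(phase_x: PhaseSeries | np.ndarray, phase_y: PhaseSeries | np.ndarray,
             p: int = 1, q: int = 1) -> float:
    """PLV of two phase series: |mean of exp(i(p*phi_x - q*phi_y))|."""
    px = phase_x.phase if isinstance(phase_x, PhaseSeries) else np.asarray(phase_x)
    py = phase_y.phase if isinstance(phase_y, PhaseSeries) else np.asarray(phase_y)
    if px.shape != py.shape:
        raise ConfigError(f"phase series lengths differ: {px.shape} vs {py.shape}")
    return float(np.abs(np.exp(1j * (p * px - q * py)).mean()))


def plv_matrix(segment: Recording, config: PLVConfig | None = None) -> FBN:
    """Average pairwise-PLV matrix over the non-overlapping windows tiling a
    segment; diagonal set to 1.

    All channels of the segment are phase-extracted together, then for each
    window the full pairwise matrix is the Gram matrix of unit phasors.
    """
    if config is None:
        config = PLVConfig()
    fs = segment.fs
    win = int(round(config.window_ms * fs / 1000.0))
    step = int(round(config.step_ms * fs / 1000.0))
    n = segment.n_samples
    if n < win:
        raise InsufficientDataError(
            f"segment of {n} samples is shorter than one {win}-sample window"
        )

    data = segment.data
    if not np.all(np.any(data, axis=1)):
        raise UndefinedPhaseError("segment contains an all-zero channel")
    z = _analytic(data, fs, config)
    phasors = np.exp(1j * np.angle(z))

    mats = []
    for start in range(0, n - win + 1, step):
        block = phasors[:, start : start + win]
        if config.p == 1 and config.q == 1:
            m = np.abs(block @ block.conj().T) / win
        else:
            bp = np.exp(1j * config.p * np.angle(block))
            bq = np.exp(1j * config.q * np.angle(block))
            m = np.abs(bp @ bq.conj().T) / win
        mats.append(m)
    mean = np.mean(mats, axis=0)
    mean = np.clip((mean + mean.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(mean, 1.0)
    return FBN(nodes=segment.labels, weights=mean)


def candidate_fbn(recording_av: Recording, candidate,
                  config: PLVConfig | None = None) -> FBN:
    """The functional network of one candidate's 300 ms frame (3 windows)."""
    start, stop = candidate.frame_span
    if start < 0 or stop > recording_av.n_samples:
        raise InsufficientDataError(
            f"candidate span [{start}, {stop}) outside recording"
        )
    segment = Recording(data=recording_av.data[:, start:stop],
                        fs=recording_av.fs, labels=recording_av.labels,
                        montage=recording_av.montage)
    return plv_matrix(segment, config)
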