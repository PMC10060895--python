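"""Time-domain spike morphology: wave landmarks and the 10-feature block.

A candidate frame is reduced to three landmarks — left trough, apex, right
trough — on the detrended, apex-oriented signal, and then to ten features
in four families (durations, amplitudes, slopes, area).  Each candidate
contributes three such blocks (its AV channel plus the two bipolar
derivations sharing the electrode), 30 values in total.

All quantities are DC-invariant (landmarks are found after mean removal and
the area is measured against the trough-to-trough chord) and degree-1
homogeneous in amplitude for the amplitude/slope/area features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import LandmarkError, MontageError
from .signal_io import Recording, bp_neighbors

logger = logging.getLogger(__name__)

#: Per-channel feature order (fixed; suffixed _AV/_BP1/_BP2 in the 30-block).
CHANNEL_FEATURE_NAMES: tuple[str, ...] = (
    "Dura_left", "Dura_right", "Dura_peaks",
    "Amp_left", "Amp_right", "Amp_peaks",
    "Slope_left", "Slope_right", "Slope_peaks",
    "Area_peaks",
)


def feature_names() -> tuple[str, ...]:
    """The 30 time-domain feature names, AV block first, then BP1/BP2."""
    return tuple(f"{name}_{suffix}"
                 for suffix in ("AV", "BP1", "BP2")
                 for name in CHANNEL_FEATURE_NAMES)


@dataclass(frozen=True)
class WaveLandmarks:
    """Sample indices of the half-wave boundaries within a frame."""

    left_trough: int
    apex: int
    right_trough: int

    def __post_init__(self):
        if not (self.left_trough < self.apex < self.right_trough):
            raise LandmarkError(
                f"landmarks must satisfy left < apex < right, got "
                f"({self.left_trough}, {self.apex}, {self.right_trough})"
            )


@dataclass(frozen=True)
class ChannelFeatures:
    """The ten morphological features of one channel's frame.

    Durations in ms, amplitudes in µV, slopes in µV/ms (rising positive,
    falling negative), area in µV·ms.
    """

    Dura_left: float
    Dura_right: float
    Dura_peaks: float
    Amp_left: float
    Amp_right: float
    Amp_peaks: float
    Slope_left: float
    Slope_right: float
    Slope_peaks: float
    Area_peaks: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in CHANNEL_FEATURE_NAMES])


def _oriented(frame: np.ndarray, apex: int) -> np.ndarray:
    """Detrended frame flipped so the apex deflection is positive."""
    det = frame - frame.mean()
    return det * np.sign(det[apex]) if det[apex] != 0 else det


def locate_landmarks(frame: np.ndarray, apex_hint: int | None = None) -> WaveLandmarks:
    """Find (left trough, apex, right trough) on a detrended frame.

    The apex is the local extremum of absolute detrended amplitude nearest
    ``apex_hint`` (global extremum when no hint).  Troughs are the nearest
    local minima of the apex-oriented signal on each side, falling back to
    the frame edges.  A monotone frame (apex on an edge) has no landmarks.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size < 3 or np.ptp(frame) == 0:
        raise LandmarkError("flat or too-short frame has no apex")
    det = frame - frame.mean()
    absd = np.abs(det)

    if apex_hint is None:
        apex = int(np.argmax(absd))
    else:
        interior = absd[1:-1]
        is_peak = (interior >= absd[:-2]) & (interior >= absd[2:]) & (interior > 0)
        peaks = np.flatnonzero(is_peak) + 1
        if peaks.size == 0:
            apex = int(np.argmax(absd))
        else:
            apex = int(peaks[np.argmin(np.abs(peaks - apex_hint))])

    if apex in (0, frame.size - 1):
        raise LandmarkError("monotone frame: apex lies on the frame edge")

    g = _oriented(frame, apex)

    def nearest_min(direction: int) -> int:
        i = apex + direction
        while 0 < i < frame.size - 1:
            if g[i] <= g[i - 1] and g[i] <= g[i + 1]:
                return i
            i += direction
        return 0 if direction < 0 else frame.size - 1

    return WaveLandmarks(nearest_min(-1), apex, nearest_min(+1))


def channel_features(frame: np.ndarray, fs: float,
                     apex_hint: int | None = None) -> ChannelFeatures:
    """The ten features of one frame (see :class:`ChannelFeatures`).

    Half-wave amplitudes are apex-to-trough excursions on the oriented
    signal; ``Slope_peaks`` is the total excursion over the total duration;
    ``Area_peaks`` integrates |signal - chord| between the troughs, with
    the chord joining the two troughs (DC-invariant baseline).
    """
    lm = locate_landmarks(frame, apex_hint=apex_hint)
    g = _oriented(np.asarray(frame, dtype=float), lm.apex)
    dt_ms = 1000.0 / fs

    dura_l = (lm.apex - lm.left_trough) * dt_ms
    dura_r = (lm.right_trough - lm.apex) * dt_ms
    amp_l = g[lm.apex] - g[lm.left_trough]
    amp_r = g[lm.apex] - g[lm.right_trough]

    span = np.arange(lm.left_trough, lm.right_trough + 1)
    chord = np.interp(span, [lm.left_trough, lm.right_trough],
                      [g[lm.left_trough], g[lm.right_trough]])
    area = np.trapezoid(np.abs(g[span] - chord), dx=dt_ms)

    return ChannelFeatures(
        Dura_left=dura_l,
        Dura_right=dura_r,
        Dura_peaks=dura_l + dura_r,
        Amp_left=amp_l,
        Amp_right=amp_r,
        Amp_peaks=max(amp_l, amp_r),
        Slope_left=amp_l / dura_l,
        Slope_right=-amp_r / dura_r,
        Slope_peaks=(amp_l + amp_r) / (dura_l + dura_r),
        Area_peaks=area,
    )


def candidate_feature_block(candidate, av: Recording, bp: Recording) -> np.ndarray:
    """The 30-vector [AV(10), BP_anterior(10), BP_posterior(10)] of a candidate.

    Frames are cut at the same sample span on all three channels.  A BP
    frame with no resolvable landmarks contributes a zero-filled block
    (logged), so the layout is always fixed.
    """
    pair = candidate.bp_pair or bp_neighbors(candidate.av_channel)
    start, stop = candidate.frame_span
    if start < 0 or stop > av.n_samples:
        raise IndexError(
            f"candidate span [{start}, {stop}) outside recording of "
            f"{av.n_samples} samples"
        )
    apex_rel = candidate.apex_index - start

    blocks = []
    for rec, label, hint in (
        (av, candidate.av_channel, apex_rel),
        (bp, pair.bp_anterior, None),
        (bp, pair.bp_posterior, None),
    ):
        frame = rec.channel(label)[start:stop]
        try:
            blocks.append(channel_features(frame, rec.fs, apex_hint=hint).to_array())
        except LandmarkError:
            logger.debug("no landmarks on %s for candidate at sample %d; "
                           "zero-filling its feature block",
                           label, candidate.apex_index)
            blocks.append(np.zeros(len(CHANNEL_FEATURE_NAMES)))
    return np.concatenate(blocks)
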