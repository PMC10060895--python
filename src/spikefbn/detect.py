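"""Candidate spike detection by triangle template matching.

The screening statistic is the normalized cross-correlation

    C = sum(y f) / sqrt(sum(y^2) sum(f^2))

between a template ``y`` and a signal frame ``f`` of equal length (300 ms by
default).  A frame becomes a candidate when |C| clears the correlation
threshold *and* its morphology (rising slope, falling slope, apex
curvature) clears a fraction of the template's own morphology.  The
universal template is a 300 µV / 60 ms triangle; candidate frames found
with it are clustered (K-means over apex-aligned, unit-peak frames, with
the cluster count grown until some cluster drops below 5% of candidates)
and the surviving centroids are re-matched as *specific* templates at
stricter thresholds.  Nearby detections finally collapse to the
best-correlated one.

Matching is polarity-agnostic (|C|), since clinical spikes are
surface-negative while the canonical template is drawn positive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.cluster import KMeans

from .errors import ConfigError, LandmarkError, TemplateError
from .morphology import locate_landmarks, _oriented
from .signal_io import BipolarPair
from .synth import make_spike_waveform

_CHUNK = 8192  # positions per vectorized block, bounds peak memory


@dataclass(frozen=True)
class MatchConfig:
    """Thresholds and geometry of the matching stages."""

    window_ms: float = 300.0
    universal_amplitude: float = 300.0   # µV
    universal_duration_ms: float = 60.0  # ms
    corr_threshold: float = 0.60
    feat_threshold: float = 0.30
    specific_corr_threshold: float = 0.75
    specific_feat_threshold: float = 0.40
    min_cluster_frac: float = 0.05
    merge_interval_ms: float = 100.0
    scan_stride_ms: float = 10.0
    max_clusters: int = 10
    stop_rule: str = "first"  # first: stop at first offending k; prune: keep going
    kmeans_seed: int = 0

    def __post_init__(self):
        for name in ("corr_threshold", "feat_threshold",
                     "specific_corr_threshold", "specific_feat_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        if self.window_ms < self.universal_duration_ms:
            raise ConfigError("window_ms must cover the universal template")
        if not (0 < self.min_cluster_frac < 0.5):
            raise ConfigError("min_cluster_frac must lie in (0, 0.5)")
        if self.stop_rule not in ("first", "prune"):
            raise ConfigError(f"unknown stop_rule {self.stop_rule!r}")


@dataclass(frozen=True)
class CandidateSpike:
    """One detected frame on an AV channel."""

    av_channel: str | None
    apex_index: int            # absolute sample index in the recording
    frame: np.ndarray          # the 300 ms window, apex-centered
    frame_start: int           # absolute index of frame[0]
    correlation: float         # best-polarity |C|, in [0, 1]
    template_id: str           # "universal" or "cluster-k"
    fs: float
    bp_pair: BipolarPair | None = None

    @property
    def frame_span(self) -> tuple[int, int]:
        """Half-open [start, stop) span of the frame."""
        return self.frame_start, self.frame_start + len(self.frame)


@dataclass(frozen=True)
class MorphScore:
    """Morphological screening features of a frame (apex-oriented)."""

    rising_slope: float   # µV/ms, >= 0
    falling_slope: float  # µV/ms, <= 0
    curvature: float      # |second difference at apex| / apex amplitude


def cross_correlation(frame: np.ndarray, template: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-length 1-D signals.

    Symmetric in its arguments and invariant to positive rescaling of
    either.  An all-zero frame returns 0 by convention; an all-zero
    template is an error.
    """
    frame = np.asarray(frame, dtype=float)
    template = np.asarray(template, dtype=float)
    if frame.shape != template.shape or frame.ndim != 1 or frame.size < 2:
        raise ConfigError("frame and template must be equal-length 1-D, >= 2")
    et = float(template @ template)
    if et == 0:
        raise TemplateError("all-zero template")
    ef = float(frame @ frame)
    if ef == 0:
        return 0.0
    return float(frame @ template) / np.sqrt(et * ef)


_CURVATURE_STENCIL_MS = 5.0


def morph_score(frame: np.ndarray, fs: float) -> MorphScore:
    """Rising/falling slopes (apex to nearest troughs) and apex curvature.

    Curvature is the amplitude-normalized central second difference at the
    apex over a 5 ms stencil — wide enough to measure the spike's own
    sharpness rather than sample-to-sample noise roughness, and stable
    under the 70 Hz acquisition low-pass that rounds the apex.
    """
    lm = locate_landmarks(np.asarray(frame, dtype=float))
    g = _oriented(np.asarray(frame, dtype=float), lm.apex)
    dt_ms = 1000.0 / fs
    rising = (g[lm.apex] - g[lm.left_trough]) / ((lm.apex - lm.left_trough) * dt_ms)
    falling = (g[lm.right_trough] - g[lm.apex]) / ((lm.right_trough - lm.apex) * dt_ms)
    s = max(1, int(round(_CURVATURE_STENCIL_MS * fs / 1000.0)))
    s = min(s, lm.apex, len(g) - 1 - lm.apex)
    second = g[lm.apex - s] - 2 * g[lm.apex] + g[lm.apex + s]
    curvature = abs(second) / (s * dt_ms) ** 2 / abs(g[lm.apex])
    return MorphScore(rising_slope=float(rising), falling_slope=float(falling),
                      curvature=float(curvature))


def _passes_morphology(score: MorphScore, reference: MorphScore,
                       fraction: float) -> bool:
    return (score.rising_slope >= fraction * reference.rising_slope
            and -score.falling_slope >= fraction * -reference.falling_slope
            and score.curvature >= fraction * reference.curvature)


def universal_template(config: MatchConfig, fs: float) -> np.ndarray:
    """The window-length frame holding the centered canonical triangle."""
    win = int(round(config.window_ms * fs / 1000.0))
    tri = make_spike_waveform(config.universal_amplitude,
                              config.universal_duration_ms, fs)
    frame = np.zeros(win)
    start = win // 2 - (len(tri) - 1) // 2
    frame[start : start + len(tri)] = tri
    return frame


def _window_energy(signal: np.ndarray, win: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(signal.astype(float) ** 2)])
    return c[win:] - c[:-win]


def _frame_apices(signal: np.ndarray, win: int, stride: int) -> np.ndarray:
    """Absolute apex index (extremum of |detrended frame|) per scan start."""
    n = signal.size
    starts = np.arange(0, n - win + 1, stride)
    views = sliding_window_view(signal, win)
    apices = np.empty(starts.size, dtype=np.int64)
    for i0 in range(0, starts.size, _CHUNK):
        s = starts[i0 : i0 + _CHUNK]
        block = views[s]
        det = block - block.mean(axis=1, keepdims=True)
        apices[i0 : i0 + s.size] = s + np.argmax(np.abs(det), axis=1)
    return np.unique(apices)


def _scan(signal: np.ndarray, fs: float, template_frame: np.ndarray,
          corr_threshold: float, feat_threshold: float, config: MatchConfig,
          template_id: str, channel: str | None) -> list[CandidateSpike]:
    """Slide the window, align the template apex to each frame apex, and
    keep frames clearing both the correlation and morphology gates."""
    signal = np.asarray(signal, dtype=float)
    win = len(template_frame)
    if signal.size < win:
        return []
    stride = max(1, int(round(config.scan_stride_ms * fs / 1000.0)))

    t_det = template_frame - template_frame.mean()
    t_apex = int(np.argmax(np.abs(t_det)))
    reference = morph_score(template_frame, fs)
    e_t = float(template_frame @ template_frame)
    if e_t == 0:
        raise TemplateError("all-zero template")

    apices = _frame_apices(signal, win, stride)
    # aligned frame start so the template apex coincides with the frame apex
    starts = apices - t_apex
    ok = (starts >= 0) & (starts + win <= signal.size)
    apices, starts = apices[ok], starts[ok]

    energies = _window_energy(signal, win)
    corr = np.zeros(apices.size)
    offsets = np.arange(win)
    for i0 in range(0, starts.size, _CHUNK):
        s = starts[i0 : i0 + _CHUNK]
        frames = signal[s[:, None] + offsets]
        num = frames @ template_frame
        e_f = energies[s]
        nz = e_f > 0
        corr[i0 : i0 + s.size][nz] = num[nz] / np.sqrt(e_t * e_f[nz])

    quality = np.abs(corr)  # polarity-agnostic matching
    passing = np.flatnonzero(quality >= corr_threshold)

    kept: list[tuple[int, int, float]] = []
    for j in passing:
        frame = signal[starts[j] : starts[j] + win]
        try:
            score = morph_score(frame, fs)
        except LandmarkError:
            continue
        if _passes_morphology(score, reference, feat_threshold):
            kept.append((int(apices[j]), int(starts[j]), float(quality[j])))

    # local-maximum suppression: overlapping passes (apices closer than half
    # a window) reduce to the best-correlated one
    kept.sort()
    suppress = win // 2
    groups: list[list[tuple[int, int, float]]] = []
    for item in kept:
        if groups and item[0] - groups[-1][-1][0] < suppress:
            groups[-1].append(item)
        else:
            groups.append([item])

    candidates = []
    half = win // 2
    for group in groups:
        apex, _, q = max(group, key=lambda it: (it[2], -it[0]))
        fstart = apex - half
        if fstart < 0 or fstart + win > signal.size:
            continue
        candidates.append(CandidateSpike(
            av_channel=channel, apex_index=apex,
            frame=signal[fstart : fstart + win].copy(), frame_start=fstart,
            correlation=q, template_id=template_id, fs=fs,
        ))
    return candidates


def scan_universal(signal: np.ndarray, fs: float, config: MatchConfig,
                   channel: str | None = None) -> list[CandidateSpike]:
    """First-pass screening with the canonical triangle template."""
    return _scan(signal, fs, universal_template(config, fs),
                 config.corr_threshold, config.feat_threshold, config,
                 "universal", channel)


def _normalized_frames(candidates: list[CandidateSpike]) -> np.ndarray:
    """Apex-oriented, unit-peak frames (apices are already frame-centered)."""
    rows = []
    for c in candidates:
        g = _oriented(c.frame, len(c.frame) // 2)
        peak = np.abs(g).max()
        rows.append(g / peak if peak > 0 else g)
    return np.array(rows)


def _apex_amplitude(candidate: CandidateSpike) -> float:
    det = candidate.frame - candidate.frame.mean()
    return float(np.abs(det).max())


def kmeans_specific_templates(candidates: list[CandidateSpike],
                              config: MatchConfig) -> list[np.ndarray]:
    """Derive specific templates as K-means centroids of candidate frames.

    k grows from 1 until some cluster holds fewer than ``min_cluster_frac``
    of the candidates; undersized clusters are discarded and the remaining
    centroids, rescaled to the mean apex amplitude of their members, become
    the specific templates.  Deterministic under ``kmeans_seed``.
    """
    if len(candidates) == 0:
        raise TemplateError("no candidates to cluster")
    if len(candidates) == 1:
        return [candidates[0].frame.copy()]

    frames = _normalized_frames(candidates)
    amplitudes = np.array([_apex_amplitude(c) for c in candidates])
    n = len(candidates)
    min_count = config.min_cluster_frac * n

    selected_labels = selected_k = None
    for k in range(1, min(config.max_clusters, n) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=config.kmeans_seed)
        labels = km.fit_predict(frames)
        counts = np.bincount(labels, minlength=k)
        selected_labels, selected_k = labels, k
        if counts.min() < min_count and config.stop_rule == "first":
            break

    templates = []
    for j in range(selected_k):
        members = selected_labels == j
        if members.sum() < min_count:
            continue  # discard undersized cluster
        centroid = frames[members].mean(axis=0)
        peak = np.abs(centroid).max()
        if peak == 0:
            continue
        templates.append(centroid / peak * amplitudes[members].mean())
    if not templates:  # every cluster undersized: fall back to one centroid
        templates = [frames.mean(axis=0) * amplitudes.mean()]
    return templates


def match_specific(signal: np.ndarray, templates: list[np.ndarray], fs: float,
                   config: MatchConfig,
                   channel: str | None = None) -> list[CandidateSpike]:
    """Re-match with each specific template at the stricter thresholds and
    pool the results (tagged ``cluster-<i>``)."""
    if not templates:
        raise TemplateError("empty specific-template list")
    out: list[CandidateSpike] = []
    for i, template in enumerate(templates):
        out.extend(_scan(signal, fs, np.asarray(template, dtype=float),
                         config.specific_corr_threshold,
                         config.specific_feat_threshold, config,
                         f"cluster-{i}", channel))
    return out


def merge_candidates(candidates: list[CandidateSpike],
                     config: MatchConfig) -> list[CandidateSpike]:
    """Collapse per-channel candidates closer than ``merge_interval_ms`` to
    the best-correlated one.  Idempotent."""
    by_channel: dict[str | None, list[CandidateSpike]] = {}
    for c in candidates:
        by_channel.setdefault(c.av_channel, []).append(c)

    merged: list[CandidateSpike] = []
    for channel in sorted(by_channel, key=lambda x: (x is None, x)):
        group: list[CandidateSpike] = []
        for c in sorted(by_channel[channel], key=lambda c: c.apex_index):
            gap = int(round(config.merge_interval_ms * c.fs / 1000.0))
            if group and c.apex_index - group[-1].apex_index < gap:
                group.append(c)
            else:
                if group:
                    merged.append(max(group, key=lambda c: (c.correlation,
                                                            -c.apex_index)))
                group = [c]
        if group:
            merged.append(max(group, key=lambda c: (c.correlation,
                                                    -c.apex_index)))
    return merged
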