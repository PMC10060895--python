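"""Template matching: correlation statistic, morphology gates, scanning,
specific-template clustering, and interval merging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import spikefbn as sf
from spikefbn.detect import MatchConfig, universal_template
from spikefbn.errors import ConfigError, LandmarkError, TemplateError

from conftest import make_candidate, triangle_frame


def correlation_oracle(y, f):
    """Direct-summation normalized cross-correlation."""
    num = sum(yi * fi for yi, fi in zip(y, f))
    return num / math.sqrt(sum(v * v for v in y) * sum(v * v for v in f))


class TestCrossCorrelation:
    def test_identity_scale_and_sign(self):
        tri = sf.make_spike_waveform(300, 60, 1000)
        assert sf.cross_correlation(tri, tri) == pytest.approx(1.0, abs=1e-12)
        assert sf.cross_correlation(-tri, tri) == pytest.approx(-1.0, abs=1e-12)
        assert sf.cross_correlation(2.5 * tri, tri) == pytest.approx(1.0, abs=1e-12)

    def test_antisymmetric_construction_matches_oracle(self):
        tri = sf.make_spike_waveform(300, 60, 1000)
        odd = tri.copy()
        odd[len(odd) // 2 :] *= -1
        assert sf.cross_correlation(odd, tri) == pytest.approx(
            correlation_oracle(odd, tri), abs=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, st.integers(2, 64),
                      elements=st.floats(-100, 100, allow_nan=False)))
    def test_matches_direct_summation_on_random_frames(self, frame):
        rng = np.random.default_rng(abs(hash(frame.tobytes())) % 2**31)
        template = rng.normal(size=frame.size)
        if not frame.any():
            assert sf.cross_correlation(frame, template) == 0.0
        else:
            got = sf.cross_correlation(frame, template)
            assert got == pytest.approx(correlation_oracle(frame, template),
                                        abs=1e-12)
            assert -1 - 1e-12 <= got <= 1 + 1e-12

    def test_degenerate_inputs(self):
        tri = sf.make_spike_waveform(300, 60, 1000)
        assert sf.cross_correlation(np.zeros_like(tri), tri) == 0.0
        with pytest.raises(TemplateError):
            sf.cross_correlation(tri, np.zeros_like(tri))
        with pytest.raises(ConfigError):
            sf.cross_correlation(tri, tri[:-1])


class TestMorphScore:
    def test_ideal_triangle_slopes(self):
        score = sf.morph_score(triangle_frame(), 1000.0)
        assert score.rising_slope == pytest.approx(10.0, rel=1e-9)
        assert score.falling_slope == pytest.approx(-10.0, rel=1e-9)
        assert score.curvature > 0

    def test_slopes_scale_with_amplitude_curvature_does_not(self):
        a = sf.morph_score(triangle_frame(), 1000.0)
        b = sf.morph_score(2.0 * triangle_frame(), 1000.0)
        assert b.rising_slope == pytest.approx(2 * a.rising_slope)
        assert b.falling_slope == pytest.approx(2 * a.falling_slope)
        assert b.curvature == pytest.approx(a.curvature)

    def test_flat_frame_has_no_apex(self):
        with pytest.raises(LandmarkError):
            sf.morph_score(np.full(300, 5.0), 1000.0)


class TestScanUniversal:
    def test_self_detection_on_silence(self, fs):
        signal = np.zeros(5000)
        tri = sf.make_spike_waveform(300, 60, fs)
        signal[2000 : 2000 + len(tri)] += tri
        cands = sf.scan_universal(signal, fs, MatchConfig())
        assert len(cands) == 1
        assert abs(cands[0].apex_index - 2030) <= 1
        assert cands[0].correlation == pytest.approx(1.0, abs=1e-9)

    def test_negative_polarity_detected(self, fs):
        signal = np.zeros(5000)
        tri = sf.make_spike_waveform(300, 60, fs)
        signal[2000 : 2000 + len(tri)] -= tri
        cands = sf.scan_universal(signal, fs, MatchConfig())
        assert len(cands) == 1

    def test_alpha_rhythm_not_detected(self, fs):
        t = np.arange(10000) / fs
        signal = 50.0 * np.sin(2 * np.pi * 10.0 * t)
        assert sf.scan_universal(signal, fs, MatchConfig()) == []

    def test_two_separated_spikes_give_two_candidates(self, fs):
        signal = np.zeros(8000)
        tri = sf.make_spike_waveform(300, 60, fs)
        for start in (2000, 4000):
            signal[start : start + len(tri)] += tri
        apices = sorted(c.apex_index for c in
                        sf.scan_universal(signal, fs, MatchConfig()))
        assert len(apices) == 2
        assert abs(apices[0] - 2030) <= 1 and abs(apices[1] - 4030) <= 1

    def test_detects_in_moderate_noise(self, fs):
        rng = np.random.default_rng(0)
        signal = rng.normal(scale=20.0, size=10000)
        tri = sf.make_spike_waveform(300, 60, fs)
        signal[5000 : 5000 + len(tri)] -= tri
        cands = sf.scan_universal(signal, fs, MatchConfig())
        assert any(abs(c.apex_index - 5030) <= 10 for c in cands)


def _candidates_from_frames(frames):
    return [make_candidate(f) for f in frames]


class TestKMeansTemplates:
    def _prototype_frames(self, rng):
        a = triangle_frame(300, 60)
        b = np.zeros(300)  # biphasic wave, positive crest at the frame center
        b[120:240] = 250.0 * np.sin(2 * np.pi * np.arange(120) / 120)
        outlier = 80.0 * np.cos(2 * np.pi * (np.arange(300) - 150) / 30)
        mk = lambda proto: proto + rng.normal(scale=2.0, size=300)
        return ([mk(a) for _ in range(50)] + [mk(b) for _ in range(50)]
                + [mk(outlier) for _ in range(3)])

    def test_five_percent_discard_rule(self):
        rng = np.random.default_rng(1)
        cands = _candidates_from_frames(self._prototype_frames(rng))
        templates = sf.kmeans_specific_templates(cands, MatchConfig())
        assert len(templates) == 2

    def test_identical_frames_give_one_template(self):
        frames = [triangle_frame(300, 60)] * 100
        templates = sf.kmeans_specific_templates(
            _candidates_from_frames(frames), MatchConfig()
        )
        assert len(templates) == 1
        # centroid rescaled to mean member apex amplitude
        det = frames[0] - frames[0].mean()
        got = templates[0] - templates[0].mean()
        np.testing.assert_allclose(got, det, atol=1e-9)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        frames = self._prototype_frames(rng)
        t1 = sf.kmeans_specific_templates(_candidates_from_frames(frames),
                                          MatchConfig(kmeans_seed=5))
        t2 = sf.kmeans_specific_templates(_candidates_from_frames(frames),
                                          MatchConfig(kmeans_seed=5))
        assert len(t1) == len(t2)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a, b)

    def test_single_candidate_is_its_own_template(self):
        cands = _candidates_from_frames([triangle_frame()])
        templates = sf.kmeans_specific_templates(cands, MatchConfig())
        assert len(templates) == 1
        np.testing.assert_array_equal(templates[0], cands[0].frame)


class TestMatchSpecific:
    def test_matches_tagged_with_generating_template(self, fs):
        b = np.zeros(300)
        b[120:240] = 250.0 * np.sin(2 * np.pi * np.arange(120) / 120)
        signal = np.zeros(10000)
        for start in (2000, 5000, 8000):
            signal[start : start + 300] += b
        templates = [triangle_frame(300, 60), b.copy()]
        cands = sf.match_specific(signal, templates, fs, MatchConfig())
        assert len(cands) >= 3
        assert {c.template_id for c in cands} == {"cluster-1"}

    def test_empty_template_list_rejected(self, fs):
        with pytest.raises(TemplateError):
            sf.match_specific(np.zeros(1000), [], fs, MatchConfig())


class TestMergeCandidates:
    def _cand(self, apex, corr):
        return make_candidate(triangle_frame(), apex_index=apex,
                              correlation=corr)

    def test_close_pair_collapses_to_best_correlation(self):
        cands = [self._cand(1000, 0.7), self._cand(1040, 0.9)]
        merged = sf.merge_candidates(cands, MatchConfig())
        assert len(merged) == 1
        assert merged[0].apex_index == 1040

    def test_distant_pair_survives(self):
        cands = [self._cand(1000, 0.7), self._cand(1200, 0.9)]
        assert len(sf.merge_candidates(cands, MatchConfig())) == 2

    def test_channels_merged_independently(self):
        cands = [make_candidate(triangle_frame(), apex_index=1000, channel="C3"),
                 make_candidate(triangle_frame(), apex_index=1040, channel="P3")]
        assert len(sf.merge_candidates(cands, MatchConfig())) == 2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(300, 50000),
                              st.floats(0.6, 1.0)), max_size=20))
    def test_idempotence(self, items):
        cands = [self._cand(a, c) for a, c in items]
        once = sf.merge_candidates(cands, MatchConfig())
        twice = sf.merge_candidates(once, MatchConfig())
        assert [(c.apex_index, c.correlation) for c in once] == \
               [(c.apex_index, c.correlation) for c in twice]


class TestOverGeneration:
    def test_candidates_cover_every_annotation(self, detected, simulated):
        """The candidate stage must over-generate, never under-generate:
        every annotated spike lies near a candidate, and candidates far
        outnumber annotations (as on real recordings)."""
        candidates, labels, counts = detected
        _, annotations = simulated
        assert counts["candidates"] >= len(annotations)
        for channel, apex, _ in annotations.events:
            apices = np.array([c.apex_index for c in candidates
                               if c.av_channel == channel])
            assert apices.size and np.abs(apices - apex).min() <= 100
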