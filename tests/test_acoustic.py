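"""Acoustic features against analytic signals and an independent DSP
oracle (explicit DFT / DCT matrices, separately-constructed mel bank)."""

import math

import numpy as np
import pytest

from adspeech.acoustic import (FrameSpec, SilenceSegmentation, delta,
                               extract_acoustic, f0_frames,
                               mfcc_frames, mfcc_moment_features,
                               pause_and_duration_features,
                               segment_silences, zcr_and_f0_features,
                               zcr_frames)
from adspeech.chat_io import AudioClip, TranscriptDoc, Utterance
from tests.conftest import make_doc

SPEC = FrameSpec()


# ---------------------------------------------------------------------------
# independent MFCC implementation (oracle)
# ---------------------------------------------------------------------------

def mfcc_oracle(samples, rate, spec=SPEC, n_static=14, n_mel=26):
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples = samples / peak * 0.95
    win = int(round(spec.window_s * rate))
    hop = int(round(spec.hop_s * rate))
    n_fft = 1
    while n_fft < win:
        n_fft *= 2
    n_bins = n_fft // 2 + 1
    # explicit DFT basis
    k = np.arange(n_bins)[:, None]
    n = np.arange(n_fft)[None, :]
    cos_b = np.cos(-2 * np.pi * k * n / n_fft)
    sin_b = np.sin(-2 * np.pi * k * n / n_fft)
    hann = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(win) / (win - 1))

    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def imel(m):
        return 700.0 * (10 ** (m / 2595.0) - 1.0)

    edges = np.floor((n_fft + 1) * imel(
        np.linspace(mel(0.0), mel(rate / 2.0), n_mel + 2)) / rate).astype(int)
    fb = np.zeros((n_mel, n_bins))
    for i in range(n_mel):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        for b in range(lo, mid):
            if mid > lo:
                fb[i, b] = (b - lo) / (mid - lo)
        for b in range(mid, hi):
            if hi > mid:
                fb[i, b] = (hi - b) / (hi - mid)
    # orthonormal DCT-II basis
    j = np.arange(n_mel)
    dct_b = np.zeros((n_static, n_mel))
    for c in range(n_static):
        dct_b[c] = np.cos(np.pi * c * (2 * j + 1) / (2 * n_mel))
        dct_b[c] *= math.sqrt((1 if c == 0 else 2) / n_mel)

    out = []
    start = 0
    while start + win <= len(samples):
        frame = samples[start:start + win] * hann
        padded = np.zeros(n_fft)
        padded[:win] = frame
        power = (cos_b @ padded) ** 2 + (sin_b @ padded) ** 2
        logmel = np.log(fb @ power + 1e-10)
        out.append(dct_b @ logmel)
        start += hop
    return np.array(out)


class TestMfcc:
    def test_sine_matches_independent_oracle(self, sine_clip):
        got = mfcc_frames(sine_clip)
        want = mfcc_oracle(sine_clip.samples, sine_clip.rate)
        assert got.shape == want.shape
        scale = np.max(np.abs(want))
        assert np.max(np.abs(got - want)) / scale < 1e-6

    @pytest.mark.parametrize("seed", range(8))
    def test_random_clips_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rate = 8000
        dur = float(rng.uniform(0.3, 1.0))
        samples = rng.uniform(-0.8, 0.8, int(dur * rate))
        clip = AudioClip(samples=samples, rate=rate)
        got = mfcc_frames(clip)
        want = mfcc_oracle(samples, rate)
        scale = np.max(np.abs(want))
        assert np.max(np.abs(got - want)) / scale < 1e-6

    def test_shape_contract_168_finite(self, sine_clip):
        out = mfcc_moment_features(sine_clip)
        assert len(out) == 168
        assert all(math.isfinite(v) for v in out.values())

    def test_periodic_signal_variance_zero(self):
        # period equal to the hop makes every frame identical
        rate = 8000
        hop = int(SPEC.hop_s * rate)
        one = np.sin(2 * np.pi * np.arange(hop) / hop)
        clip = AudioClip(samples=np.tile(one, 200), rate=rate)
        out = mfcc_moment_features(clip)
        for i in range(14):
            assert out[f"mfcc_c{i:02d}_variance"] == pytest.approx(
                0.0, abs=1e-12)
            assert out[f"mfcc_c{i:02d}_skewness"] == 0.0

    def test_too_short_clip_missing(self):
        clip = AudioClip(samples=np.zeros(100), rate=8000)
        out = mfcc_moment_features(clip)
        assert all(math.isnan(v) for v in out.values())

    def test_moments_match_brute_force_on_frame_series(self, sine_clip):
        series = mfcc_frames(sine_clip)
        d = delta(series)
        out = mfcc_moment_features(sine_clip)
        for i in (0, 7, 13):
            x = series[:, i]
            assert out[f"mfcc_c{i:02d}_mean"] == pytest.approx(x.mean())
            assert out[f"mfcc_c{i:02d}_variance"] == pytest.approx(x.var())
            z = (x - x.mean()) / x.std()
            assert out[f"mfcc_c{i:02d}_skewness"] == pytest.approx(
                np.mean(z ** 3))
            assert out[f"mfcc_c{i:02d}_kurtosis"] == pytest.approx(
                np.mean(z ** 4) - 3)
            xd = d[:, i]
            assert out[f"mfcc_d{i:02d}_mean"] == pytest.approx(xd.mean())


class TestZcrF0:
    def test_square_wave_brute_force_crossings(self):
        # 100 Hz square wave: 200 sign changes per second.  With the hop
        # equal to the 10 ms period every frame starts at the same phase,
        # so the per-frame count is constant (variance 0) and each frame's
        # value matches a brute-force count over its samples.
        rate = 16000
        idx = np.arange(2 * rate)
        square = np.where((idx // 80) % 2 == 0, 1.0, -1.0)  # 5 ms half-period
        clip = AudioClip(samples=square, rate=rate)
        zcr = zcr_frames(clip)
        win, hop = int(0.025 * rate), int(0.010 * rate)
        brute = []
        for start in range(0, len(square) - win + 1, hop):
            frame = square[start:start + win]
            brute.append(np.sum(frame[:-1] * frame[1:] < 0) / 0.025)
        assert np.array_equal(zcr, np.array(brute))
        out = zcr_and_f0_features(clip)
        # frame estimate of the 200/s rate, quantized to whole crossings
        assert out["zcr_mean"] == pytest.approx(200.0, rel=0.25)
        assert out["zcr_variance"] == pytest.approx(0.0, abs=1e-9)

    def test_sine_f0_within_5hz(self, sine_clip):
        out = zcr_and_f0_features(sine_clip)
        assert abs(out["f0_median"] - 440.0) <= 5.0
        assert abs(out["f0_mean"] - 440.0) <= 5.0

    def test_silence_only_f0_missing_zcr_zero(self):
        clip = AudioClip(samples=np.zeros(16000), rate=16000)
        out = zcr_and_f0_features(clip)
        assert out["zcr_mean"] == 0.0
        assert math.isnan(out["f0_mean"])

    def test_autocorrelation_oracle_on_tone(self):
        # brute-force best lag on one frame
        rate = 8000
        freq = 200.0
        t = np.arange(rate) / rate
        clip = AudioClip(samples=np.sin(2 * np.pi * freq * t), rate=rate)
        f0 = f0_frames(clip)
        assert f0.size > 0
        assert abs(np.median(f0) - freq) <= 5.0


def _speech_pause_clip(rate=8000):
    """speech 1.0s | silence 1.2s | speech 1.0s | silence 0.3s | speech 1.0s"""
    t = np.arange(rate) / rate
    tone = 0.5 * np.sin(2 * np.pi * 220 * t)
    sil_long = np.zeros(int(1.2 * rate))
    sil_short = np.zeros(int(0.3 * rate))
    samples = np.concatenate([tone, sil_long, tone, sil_short, tone])
    return AudioClip(samples=samples, rate=rate)


class TestPauses:
    def test_segmentation_tiles_duration(self):
        clip = _speech_pause_clip()
        seg = segment_silences(clip)
        assert seg.segments[0][0] == 0.0
        assert seg.segments[-1][1] == pytest.approx(clip.duration)
        assert seg.speech_duration + seg.pause_duration == pytest.approx(
            clip.duration, abs=SPEC.hop_s)

    def test_planted_pauses_recovered(self):
        clip = _speech_pause_clip()
        seg = segment_silences(clip)
        doc = make_doc([["one", "two", "three"]])
        out = pause_and_duration_features(clip, seg, doc)
        assert out["pause_long_count"] == 1
        assert out["pause_short_count"] == 1
        # pause edges are quantized: up to one window length per boundary
        assert out["pause_total_dur"] == pytest.approx(
            1.5, abs=2 * (SPEC.window_s + SPEC.hop_s))
        assert out["dur_total_audio"] == pytest.approx(clip.duration)

    def test_no_pause_clip(self, sine_clip):
        seg = segment_silences(sine_clip)
        doc = make_doc([["a", "b"]])
        out = pause_and_duration_features(sine_clip, seg, doc)
        assert out["pause_long_count"] == 0
        assert out["pause_short_count"] == 0
        assert out["dur_total_speech"] == pytest.approx(
            sine_clip.duration, abs=SPEC.hop_s)

    def test_filler_word_ratio_arithmetic(self, sine_clip):
        seg = segment_silences(sine_clip)
        doc = TranscriptDoc("s", [Utterance(
            speaker="PAR", tokens=["w"] * 30, fillers=3,
            filler_positions=[0, 1, 2])])
        out = pause_and_duration_features(sine_clip, seg, doc)
        assert out["filler_count"] == 3
        assert out["filler_word_ratio"] == pytest.approx(0.1)

    def test_zero_words_ratios_missing(self, sine_clip):
        seg = segment_silences(sine_clip)
        out = pause_and_duration_features(sine_clip, seg, make_doc([]))
        assert math.isnan(out["pause_word_ratio"])
        assert math.isnan(out["filler_word_ratio"])

    def test_segment_invariants_enforced(self):
        with pytest.raises(ValueError):
            SilenceSegmentation([(0.0, 1.0, "speech"), (2.0, 3.0, "pause")])


class TestFamilyContracts:
    def test_187_features_and_counts(self, sine_clip):
        doc = make_doc([["a", "b", "c"]])
        out = extract_acoustic(sine_clip, doc)
        assert len(out) == 187
        fams = {"mfcc_": 168, "zcr_": 4, "f0_": 4, "pause_": 9 - 2,
                "filler_": 2, "dur_": 2}
        for prefix, n in fams.items():
            assert sum(k.startswith(prefix) for k in out) == n, prefix

    def test_amplitude_scaling_invariance(self):
        clip = _speech_pause_clip()
        doc = make_doc([["a", "b", "c"]])
        base = extract_acoustic(clip, doc)
        for factor in (0.5, 2.0):
            scaled = AudioClip(samples=clip.samples * factor / 2.0
                               if factor == 2.0 else clip.samples * factor,
                               rate=clip.rate)
            out = extract_acoustic(scaled, doc)
            for k, v in base.items():
                assert out[k] == pytest.approx(v, rel=1e-9, abs=1e-9), k

    def test_missing_audio_keeps_transcript_fillers(self):
        doc = TranscriptDoc("s", [Utterance(
            speaker="PAR", tokens=["a", "b"], fillers=1,
            filler_positions=[0])])
        out = extract_acoustic(None, doc)
        assert len(out) == 187
        assert out["filler_count"] == 1.0
        assert math.isnan(out["dur_total_audio"])
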