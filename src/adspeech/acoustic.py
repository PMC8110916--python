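"""Acoustic/temporal feature battery (187 features).

Implements the spectral front end directly on numpy/scipy: framed
short-time analysis (25 ms Hann window, 10 ms hop by default), 42 MFCC
coefficients (14 static including the 0th/energy coefficient, plus deltas
and delta-deltas) summarised by four moments each, zero-crossing-rate
moments, autocorrelation-based fundamental-frequency statistics over voiced
frames, and pause/duration features from a relative-energy silence
segmentation.  Clips are peak-normalized before spectral analysis, so all
features are invariant to global amplitude scaling.

Moment conventions: variance is the population variance, kurtosis is
*excess* kurtosis (normal -> 0), and skewness/kurtosis of a constant
per-frame series are 0 by convention.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.fft import dct, rfft

from .chat_io import AudioClip, TranscriptDoc
from .registry import MOMENTS, N_MFCC_STATIC

NAN = float("nan")

#: voiced-frame F0 search range (Hz)
F0_MIN, F0_MAX = 75.0, 500.0
#: normalized-autocorrelation threshold for voicing
VOICING_THRESHOLD = 0.5
#: silence threshold relative to the median frame log-energy (dB)
SILENCE_DB_BELOW_MEDIAN = 20.0
#: minimum silent run counted as a pause (s)
MIN_PAUSE_S = 0.15
#: boundary between short and long pauses (s)
LONG_PAUSE_S = 1.0
N_MEL_FILTERS = 26
_LOG_EPS = 1e-10


@dataclasses.dataclass(frozen=True)
class FrameSpec:
    window_s: float = 0.025
    hop_s: float = 0.010
    window_fn: str = "hann"

    def __post_init__(self):
        if not 0 < self.hop_s <= self.window_s:
            raise ValueError("require 0 < hop <= window length")


@dataclasses.dataclass
class SilenceSegmentation:
    """Non-overlapping (start, end, kind) segments tiling [0, duration]."""

    segments: list[tuple[float, float, str]]  # kind: "speech" | "pause"

    def __post_init__(self):
        prev_end = 0.0
        for start, end, kind in self.segments:
            if kind not in ("speech", "pause") or end < start:
                raise ValueError("bad segment")
            if abs(start - prev_end) > 1e-9:
                raise ValueError("segments must tile the clip")
            prev_end = end

    @property
    def pauses(self) -> list[tuple[float, float]]:
        return [(s, e) for s, e, k in self.segments if k == "pause"]

    @property
    def speech_duration(self) -> float:
        return sum(e - s for s, e, k in self.segments if k == "speech")

    @property
    def pause_duration(self) -> float:
        return sum(e - s for s, e, k in self.segments if k == "pause")


# ---------------------------------------------------------------------------
# framing and per-frame series
# ---------------------------------------------------------------------------

def _normalize_peak(samples: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(samples))
    return samples / peak * 0.95 if peak > 0 else samples


def frame_signal(samples: np.ndarray, rate: int,
                 spec: FrameSpec) -> np.ndarray:
    """(n_frames, win_len) view of the signal; frames fully inside it."""
    win = int(round(spec.window_s * rate))
    hop = int(round(spec.hop_s * rate))
    if len(samples) < win:
        return np.empty((0, win))
    n = 1 + (len(samples) - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(n)[:, None]
    return samples[idx]


def _window(spec: FrameSpec, win_len: int) -> np.ndarray:
    if spec.window_fn == "hann":
        return np.hanning(win_len)
    if spec.window_fn == "hamming":
        return np.hamming(win_len)
    if spec.window_fn == "rect":
        return np.ones(win_len)
    raise ValueError(f"unknown window {spec.window_fn}")


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, rate: int) -> np.ndarray:
    """Triangular mel filterbank, (n_filters, n_fft//2 + 1)."""
    edges_mel = np.linspace(hz_to_mel(0.0), hz_to_mel(rate / 2.0),
                            n_filters + 2)
    edges_bin = np.floor((n_fft + 1) * mel_to_hz(edges_mel) / rate).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        lo, mid, hi = edges_bin[i], edges_bin[i + 1], edges_bin[i + 2]
        for b in range(lo, mid):
            if mid > lo:
                fb[i, b] = (b - lo) / (mid - lo)
        for b in range(mid, hi):
            if hi > mid:
                fb[i, b] = (hi - b) / (hi - mid)
    return fb


def mfcc_frames(clip: AudioClip, spec: FrameSpec = FrameSpec(),
                n_static: int = N_MFCC_STATIC) -> np.ndarray:
    """Static MFCCs per frame, shape (n_frames, n_static); c0 included."""
    samples = _normalize_peak(clip.samples)
    frames = frame_signal(samples, clip.rate, spec)
    if frames.shape[0] == 0:
        return np.empty((0, n_static))
    win = _window(spec, frames.shape[1])
    n_fft = 1 << (frames.shape[1] - 1).bit_length()
    power = np.abs(rfft(frames * win, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(N_MEL_FILTERS, n_fft, clip.rate)
    logmel = np.log(power @ fb.T + _LOG_EPS)
    return dct(logmel, type=2, norm="ortho", axis=1)[:, :n_static]


def delta(series: np.ndarray, width: int = 2) -> np.ndarray:
    """Regression-based temporal derivative with edge replication."""
    if series.shape[0] == 0:
        return series.copy()
    pad = np.pad(series, ((width, width), (0, 0)), mode="edge")
    denom = 2 * sum(n * n for n in range(1, width + 1))
    out = np.zeros_like(series, dtype=float)
    for n in range(1, width + 1):
        out += n * (pad[width + n:pad.shape[0] - width + n]
                    - pad[width - n:-width - n])
    return out / denom


def _moments(series: np.ndarray) -> dict[str, float]:
    x = np.asarray(series, dtype=float)
    mean = float(x.mean())
    var = float(x.var())
    if var < 1e-24:
        skew, kurt = 0.0, 0.0
    else:
        z = (x - mean) / np.sqrt(var)
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4) - 3.0)
    return {"mean": mean, "variance": var, "skewness": skew,
            "kurtosis": kurt}


# ---------------------------------------------------------------------------
# feature families
# ---------------------------------------------------------------------------

def mfcc_moment_features(clip: AudioClip,
                         spec: FrameSpec = FrameSpec()) -> dict[str, float]:
    """Mean/variance/skewness/kurtosis of 42 MFCC coefficients (168)."""
    names = [f"mfcc_{kind}{i:02d}_{m}" for kind in ("c", "d", "dd")
             for i in range(N_MFCC_STATIC) for m in MOMENTS]
    static = mfcc_frames(clip, spec)
    if static.shape[0] < 2:
        return {n: NAN for n in names}
    d = delta(static)
    dd = delta(d)
    out: dict[str, float] = {}
    for kind, series in (("c", static), ("d", d), ("dd", dd)):
        for i in range(N_MFCC_STATIC):
            mom = _moments(series[:, i])
            for m in MOMENTS:
                out[f"mfcc_{kind}{i:02d}_{m}"] = mom[m]
    return out


def zcr_frames(clip: AudioClip, spec: FrameSpec = FrameSpec()) -> np.ndarray:
    """Zero crossings per second, per frame (rectangular counting)."""
    frames = frame_signal(clip.samples, clip.rate, spec)
    if frames.shape[0] == 0:
        return np.empty(0)
    crossings = np.sum(frames[:, :-1] * frames[:, 1:] < 0, axis=1)
    return crossings / spec.window_s


def f0_frames(clip: AudioClip, spec: FrameSpec = FrameSpec()) -> np.ndarray:
    """F0 estimates (Hz) on voiced frames via the normalized
    autocorrelation peak in [F0_MIN, F0_MAX]; parabolic lag interpolation."""
    samples = _normalize_peak(clip.samples)
    frames = frame_signal(samples, clip.rate, spec)
    if frames.shape[0] == 0:
        return np.empty(0)
    frames = frames - frames.mean(axis=1, keepdims=True)
    energies = np.sum(frames ** 2, axis=1)
    energy_floor = max(np.median(energies) * 10 ** (-SILENCE_DB_BELOW_MEDIAN / 10),
                       1e-12)
    lag_min = max(2, int(np.floor(clip.rate / F0_MAX)))
    lag_max = int(np.ceil(clip.rate / F0_MIN))
    if lag_max >= frames.shape[1]:
        lag_max = frames.shape[1] - 1
    if lag_min >= lag_max:
        return np.empty(0)
    out = []
    for frame, e0 in zip(frames, energies):
        if e0 <= energy_floor:
            continue
        ac = np.correlate(frame, frame, mode="full")[len(frame) - 1:]
        ac = ac / ac[0]
        seg = ac[lag_min:lag_max + 1]
        k = int(np.argmax(seg))
        if seg[k] < VOICING_THRESHOLD:
            continue
        lag = lag_min + k
        if 0 < lag < len(ac) - 1:  # parabolic refinement
            y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                lag = lag + 0.5 * (y0 - y2) / denom
        out.append(clip.rate / lag)
    return np.asarray(out)


def zcr_and_f0_features(clip: AudioClip,
                        spec: FrameSpec = FrameSpec()) -> dict[str, float]:
    """ZCR moments (4) + F0 statistics over voiced frames (4)."""
    out: dict[str, float] = {}
    zcr = zcr_frames(clip, spec)
    if zcr.size == 0:
        out.update({f"zcr_{m}": NAN for m in MOMENTS})
    else:
        mom = _moments(zcr)
        out.update({f"zcr_{m}": mom[m] for m in MOMENTS})
    f0 = f0_frames(clip, spec)
    if f0.size == 0:
        out.update({f"f0_{s}": NAN for s in ("mean", "min", "max", "median")})
    else:
        out.update({"f0_mean": float(f0.mean()), "f0_min": float(f0.min()),
                    "f0_max": float(f0.max()),
                    "f0_median": float(np.median(f0))})
    return out


def segment_silences(clip: AudioClip,
                     spec: FrameSpec = FrameSpec()) -> SilenceSegmentation:
    """Relative-energy silence segmentation.

    A frame is silent when its log-energy falls more than
    ``SILENCE_DB_BELOW_MEDIAN`` dB below the clip's median frame
    log-energy; silent runs of at least ``MIN_PAUSE_S`` become pauses.
    The returned segments tile [0, duration].
    """
    frames = frame_signal(clip.samples, clip.rate, spec)
    dur = clip.duration
    if frames.shape[0] == 0:
        return SilenceSegmentation([(0.0, dur, "speech")])
    energies = np.sum(frames ** 2, axis=1)
    log_e = 10.0 * np.log10(energies + _LOG_EPS)
    threshold = np.median(log_e) - SILENCE_DB_BELOW_MEDIAN
    silent = log_e < threshold

    hop = spec.hop_s
    min_frames = max(1, int(round(MIN_PAUSE_S / hop)))
    segments: list[tuple[float, float, str]] = []
    i, n = 0, len(silent)
    while i < n:
        j = i
        while j < n and silent[j] == silent[i]:
            j += 1
        start = i * hop
        end = dur if j == n else j * hop
        kind = "pause" if (silent[i] and j - i >= min_frames) else "speech"
        if segments and segments[-1][2] == kind:
            segments[-1] = (segments[-1][0], end, kind)
        else:
            segments.append((start, end, kind))
        i = j
    if segments[-1][1] < dur:
        s, e, k = segments[-1]
        segments[-1] = (s, dur, k)
    return SilenceSegmentation(segments)


def pause_and_duration_features(clip: AudioClip, seg: SilenceSegmentation,
                                doc: TranscriptDoc) -> dict[str, float]:
    """Pause/filler counts and ratios (9) + duration features (2).

    Fillers come from the transcript (manual annotation is authoritative);
    pauses come from the audio segmentation.  Word-normalized ratios are
    missing when the transcript has no words.
    """
    pauses = seg.pauses
    pause_durs = [e - s for s, e in pauses]
    total_pause = float(sum(pause_durs))
    n_words = len(doc.tokens)
    n_fillers = doc.n_fillers
    speech_dur = seg.speech_duration
    out = {
        "pause_total_dur": total_pause,
        "pause_mean_dur": float(np.mean(pause_durs)) if pause_durs else 0.0,
        "pause_long_count": float(sum(d >= LONG_PAUSE_S for d in pause_durs)),
        "pause_short_count": float(sum(
            MIN_PAUSE_S <= d < LONG_PAUSE_S for d in pause_durs)),
        "pause_word_ratio": len(pauses) / n_words if n_words else NAN,
        "filler_count": float(n_fillers),
        "filler_word_ratio": n_fillers / n_words if n_words else NAN,
        "pause_speech_dur_ratio": (total_pause / speech_dur
                                   if speech_dur > 0 else NAN),
        "pause_dur_word_ratio": total_pause / n_words if n_words else NAN,
        "dur_total_audio": clip.duration,
        "dur_total_speech": speech_dur,
    }
    return out


def extract_acoustic(clip: AudioClip | None, doc: TranscriptDoc,
                     spec: FrameSpec = FrameSpec()) -> dict[str, float]:
    """All 187 acoustic features; missing audio -> all-NaN family values
    except transcript-derived filler counts."""
    if clip is None:
        names = [f"mfcc_{kind}{i:02d}_{m}" for kind in ("c", "d", "dd")
                 for i in range(N_MFCC_STATIC) for m in MOMENTS]
        out = {n: NAN for n in names}
        out.update({f"zcr_{m}": NAN for m in MOMENTS})
        out.update({f"f0_{s}": NAN for s in ("mean", "min", "max", "median")})
        n_words = len(doc.tokens)
        out.update({
            "pause_total_dur": NAN, "pause_mean_dur": NAN,
            "pause_long_count": NAN, "pause_short_count": NAN,
            "pause_word_ratio": NAN,
            "filler_count": float(doc.n_fillers),
            "filler_word_ratio": doc.n_fillers / n_words if n_words else NAN,
            "pause_speech_dur_ratio": NAN, "pause_dur_word_ratio": NAN,
            "dur_total_audio": NAN, "dur_total_speech": NAN,
        })
        return out
    out = mfcc_moment_features(clip, spec)
    out.update(zcr_and_f0_features(clip, spec))
    seg = segment_silences(clip, spec)
    out.update(pause_and_duration_features(clip, seg, doc))
    return out
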