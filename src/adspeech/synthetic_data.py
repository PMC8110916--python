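"""Synthetic picture-description cohorts with planted group effects.

Generates CHAT transcripts, schematic audio (tone segments with inserted
silences) and metadata for a balanced two-group cohort (AD vs non-AD),
age/sex matched across groups in 5-year bands.  Group differences are
planted through per-subject generation parameters whose group means are
calibrated so that the extracted features reproduce the reference group
means of the feature-differentiation analysis: content-unit mention ratios
(0.27 vs 0.45 overall, 0.28/0.47 objects, 0.15/0.30 actions), the
pronoun:(pronoun+noun) ratio (0.35 vs 0.23), average word length (3.57 vs
3.78 letters), non-dictionary-word proportion (0.11 vs 0.08), adverb use,
filler/pause intensity, and utterance repetition (driving average
utterance cosine distance 0.91 vs 0.94).

MMSE is a linear function of the realized per-subject latents plus
Gaussian noise, clipped to [0, 30], so features correlate with MMSE with
the planted signs.  One global seed drives all randomness; per-subject
substreams are derived by counter, so cohorts are reproducible
byte-for-byte.

The audio is deliberately schematic — pure tones and silences exercise the
MFCC/ZCR/F0/pause code paths with checkable ground truth; it does not
mimic real speech spectra.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .chat_io import (AudioClip, TranscriptDoc, Utterance, parse_chat,
                      load_audio, load_metadata, save_audio, serialize_chat)
from .lexicons import load_content_units

#: age-band (lower bound, males, females) pattern per group, mirroring the
#: matched train-set design; cycled proportionally for other cohort sizes.
AGE_BAND_PATTERN = (
    (50, 1, 0), (55, 5, 4), (60, 3, 6), (65, 6, 10), (70, 6, 8), (75, 3, 2),
)  # totals 24 M + 30 F = 54 per group

#: group means (AD, non-AD) of the per-subject generation parameters
DEFAULT_EFFECTS: dict[str, tuple[float, float]] = {
    "p_subject": (0.342, 0.534),
    "p_place": (0.342, 0.534),
    "p_object": (0.28, 0.47),
    "p_action": (0.15, 0.30),
    "pronoun_q": (0.95, 0.50),
    "long_word_rate": (0.60, 0.86),
    "invalid_rate": (0.125, 0.082),
    "adverb_rate": (0.36, 0.22),
    "filler_rate": (0.50, 0.20),
    "short_pause_rate": (0.50, 0.25),
    "long_pause_rate": (0.28, 0.08),
    "repeat_rate": (0.30, 0.12),
}

#: latents entering the MMSE model, with weights (sign handled by the
#: AD->non-AD direction of each latent)
MMSE_LATENTS = {"p_object": 2.0, "p_action": 2.0, "long_word_rate": 2.0,
                "pronoun_q": 1.0, "invalid_rate": 1.0, "adverb_rate": 1.0}
MMSE_INTERCEPT = 14.0
MMSE_SLOPE = 15.0
MMSE_NOISE_SD = 2.0

_JITTER = {
    "p_subject": 0.06, "p_place": 0.06, "p_object": 0.06, "p_action": 0.05,
    "pronoun_q": 0.10, "long_word_rate": 0.12, "invalid_rate": 0.020,
    "adverb_rate": 0.10, "filler_rate": 0.12, "short_pause_rate": 0.12,
    "long_pause_rate": 0.08, "repeat_rate": 0.06,
}

_SUBJ = "<SUBJ>"

#: one utterance template per content unit; each template names only its own
#: unit's synonyms (plus function words and generic vocabulary), so mention
#: probabilities stay independent across units.
UNIT_TEMPLATES: dict[str, list[str]] = {
    "boy": ["the", "boy", "wants", "one"],
    "girl": ["the", "girl", "is", "beside", "him"],
    "woman": ["the", "mother", "is", "busy", "with", "things"],
    "kitchen": ["they", "are", "in", "the", "kitchen"],
    "window": ["the", "window", "is", "open"],
    "curtains": ["the", "curtains", "are", "open"],
    "sink": ["the", "sink", "is", "full"],
    "cupboard": ["the", "cupboard", "is", "open"],
    "exterior": ["you", "can", "see", "the", "garden"],
    "cookie": [_SUBJ, "wants", "a", "cookie"],
    "jar": ["the", "jar", "is", "on", "the", "shelf"],
    "stool": [_SUBJ, "is", "on", "the", "stool"],
    "water": ["the", "water", "is", "running"],
    "dishes": [_SUBJ, "is", "doing", "the", "dishes"],
    "plate": ["a", "plate", "is", "on", "the", "side"],
    "dishcloth": [_SUBJ, "is", "holding", "a", "towel"],
    "taking": [_SUBJ, "is", "taking", "one"],
    "falling": [_SUBJ, "is", "falling", "over"],
    "washing": [_SUBJ, "is", "washing", "something"],
    "overflow": ["it", "is", "overflowing"],
    "asking": [_SUBJ, "is", "asking", "for", "more"],
    "unconcerned": [_SUBJ, "seems", "unconcerned", "about", "it"],
}

GENERIC_UTTERANCES = (
    ["there", "is", "a", "lot", "going", "on"],
    ["it", "is", "a", "busy", "day"],
    ["so", "much", "is", "going", "on"],
)

#: pronoun-rich fragments; their count per subject follows the pronoun
#: latent, raising the pronoun:(pronoun+noun) ratio for impaired speakers
PRONOUN_UTTERANCES = (
    ["he", "wants", "it"],
    ["she", "sees", "him"],
    ["he", "gives", "it", "to", "her"],
    ["she", "helps", "him", "with", "it"],
    ["they", "can", "see", "it"],
    ["it", "gets", "them", "wet"],
)

_LONG_WORDS = ("beautiful", "wonderful", "afternoon", "commotion",
               "situation", "trouble", "problem", "picture", "moment",
               "weather")
_SHORT_WORDS = ("big", "odd", "bad", "fun", "mad", "wet", "hot", "dim",
                "sad", "low")
_ADVERB_POOL = ("just", "really", "also", "still", "again", "now")
_INVALID_WORDS = ("wug", "dax", "blick", "frop", "snib", "gorp")
_PRONOUNS = ("he", "she")
_GENERIC_NOUN = ("the", "person")

N_PADDING_UTTERANCES = 6

#: audio synthesis constants
AUDIO_RATE = 8000
WORD_DUR_RANGE = (0.18, 0.28)
TONE_FREQS = (150.0, 180.0, 210.0, 240.0)
TONE_AMPLITUDE = 0.4
INTER_UTT_GAP = 0.35
SHORT_PAUSE_DUR = 0.35
LONG_PAUSE_DUR = 1.25
PAUSE_MARK_FOR = {SHORT_PAUSE_DUR: "(.)", LONG_PAUSE_DUR: "(...)"}


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    n_per_group: int = 54
    seed: int = 0
    effects: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    make_audio: bool = True
    audio_rate: int = AUDIO_RATE
    mmse_noise_sd: float = MMSE_NOISE_SD

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name, (a, b) in self.effects.items():
            if name.startswith(("p_", "pronoun", "long_word", "invalid",
                                "adverb", "filler", "short_pause",
                                "long_pause", "repeat")):
                if not (0 <= a <= 1 and 0 <= b <= 1):
                    raise ValueError(
                        f"effect target {name}={a, b} outside [0, 1]")


@dataclasses.dataclass
class SubjectRecord:
    subject_id: str
    doc: TranscriptDoc
    clip: AudioClip | None
    label: str
    mmse: int
    age: int
    sex: str
    latents: dict[str, float]


@dataclasses.dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    config: CohortConfig

    def pairs(self) -> list[tuple[TranscriptDoc, AudioClip | None]]:
        return [(s.doc, s.clip) for s in self.subjects]

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "subject_id": s.subject_id, "age": s.age, "sex": s.sex,
            "label": s.label, "mmse": s.mmse} for s in self.subjects]
        ).set_index("subject_id", drop=False)


def _demographics(n_per_group: int) -> list[tuple[int, str]]:
    """(age, sex) list for one group, cycling the matched band pattern."""
    slots: list[tuple[int, str]] = []
    for lo, m, f in AGE_BAND_PATTERN:
        slots += [(lo, "M")] * m + [(lo, "F")] * f
    out = []
    for i in range(n_per_group):
        lo, sex = slots[i % len(slots)]
        out.append((lo + (i * 7) % 5, sex))  # deterministic age within band
    return out


def _draw_latents(rng: np.random.Generator, effects, group_idx: int
                  ) -> dict[str, float]:
    lat = {}
    for name, means in effects.items():
        mu = means[group_idx]
        lat[name] = float(np.clip(rng.normal(mu, _JITTER[name]), 0.0, 1.0))
    return lat


def _mmse_from_latents(lat: dict[str, float], effects,
                       rng: np.random.Generator, noise_sd: float) -> int:
    zs, ws = [], []
    for name, w in MMSE_LATENTS.items():
        a, b = effects[name][0], effects[name][1]
        if a == b:
            continue
        zs.append((lat[name] - a) / (b - a))
        ws.append(w)
    z = float(np.average(zs, weights=ws)) if zs else 0.5
    raw = MMSE_INTERCEPT + MMSE_SLOPE * z + rng.normal(0.0, noise_sd)
    return int(np.clip(round(raw), 0, 30))


def _subject_phrase(rng, q: float) -> list[str]:
    if rng.random() < q:
        return [str(rng.choice(_PRONOUNS))]
    return list(_GENERIC_NOUN)


def _padding_utterance(rng, long_rate: float) -> list[str]:
    pool_a = _LONG_WORDS if rng.random() < long_rate else _SHORT_WORDS
    pool_b = _LONG_WORDS if rng.random() < long_rate else _SHORT_WORDS
    return ["that", "is", "a", str(rng.choice(pool_a)), str(rng.choice(pool_b))]


def _build_transcript(rng: np.random.Generator, lat: dict[str, float],
                      lexicon) -> list[Utterance]:
    token_lists: list[list[str]] = []
    cat_p = {"subject": lat["p_subject"], "place": lat["p_place"],
             "object": lat["p_object"], "action": lat["p_action"]}
    for unit in lexicon.units:
        if rng.random() < cat_p[unit.category]:
            template = UNIT_TEMPLATES[unit.name]
            toks: list[str] = []
            for piece in template:
                if piece == _SUBJ:
                    toks.extend(_subject_phrase(rng, lat["pronoun_q"]))
                else:
                    toks.append(piece)
            token_lists.append(toks)
    for g in GENERIC_UTTERANCES:
        token_lists.append(list(g))
    n_pron = int(rng.binomial(len(PRONOUN_UTTERANCES), lat["pronoun_q"]))
    order = rng.permutation(len(PRONOUN_UTTERANCES))[:n_pron]
    for j in order:
        token_lists.append(list(PRONOUN_UTTERANCES[j]))
    for _ in range(N_PADDING_UTTERANCES):
        token_lists.append(_padding_utterance(rng, lat["long_word_rate"]))
    rng.shuffle(token_lists)

    # utterance repetition (discourse perseveration)
    repeated: list[list[str]] = []
    for toks in token_lists:
        repeated.append(toks)
        if rng.random() < lat["repeat_rate"]:
            repeated.append(list(toks))

    utterances: list[Utterance] = []
    for toks in repeated:
        toks = list(toks)
        # adverb insertion
        if rng.random() < lat["adverb_rate"]:
            pos = int(rng.integers(1, len(toks) + 1))
            toks.insert(pos, str(rng.choice(_ADVERB_POOL)))
        # non-dictionary word insertion (per token)
        out_toks: list[str] = []
        for t in toks:
            out_toks.append(t)
            if rng.random() < lat["invalid_rate"]:
                out_toks.append(str(rng.choice(_INVALID_WORDS)))
        fillers = 0
        filler_positions: list[int] = []
        if rng.random() < lat["filler_rate"]:
            fillers = 1
            filler_positions = [0]
        pause_marks: list[str] = []
        if rng.random() < lat["short_pause_rate"]:
            pause_marks.append("(.)")
        if rng.random() < lat["long_pause_rate"]:
            pause_marks.append("(...)")
        utterances.append(Utterance(
            speaker="PAR", tokens=out_toks, fillers=fillers,
            filler_positions=filler_positions,
            unfilled_pauses=len(pause_marks), pause_marks=pause_marks))
    return utterances


def _tone(rng, dur: float, rate: int) -> np.ndarray:
    freq = float(rng.choice(TONE_FREQS))
    n = int(round(dur * rate))
    t = np.arange(n) / rate
    wave = TONE_AMPLITUDE * np.sin(2 * np.pi * freq * t)
    ramp = min(int(0.005 * rate), n // 2)
    if ramp > 0:
        env = np.ones(n)
        env[:ramp] = np.linspace(0, 1, ramp)
        env[-ramp:] = np.linspace(1, 0, ramp)
        wave *= env
    return wave


def _build_audio(rng: np.random.Generator, utterances: list[Utterance],
                 rate: int) -> AudioClip:
    pieces = [np.zeros(int(0.2 * rate))]
    mark_dur = {"(.)": SHORT_PAUSE_DUR, "(..)": 0.6, "(...)": LONG_PAUSE_DUR}
    for utt in utterances:
        n_speech = len(utt.tokens) + utt.fillers
        for _ in range(max(1, n_speech)):
            dur = float(rng.uniform(*WORD_DUR_RANGE))
            pieces.append(_tone(rng, dur, rate))
        for mark in utt.pause_marks:
            pieces.append(np.zeros(int(mark_dur[mark] * rate)))
        pieces.append(np.zeros(int(INTER_UTT_GAP * rate)))
    samples = np.concatenate(pieces)
    return AudioClip(samples=samples, rate=rate)


def generate_cohort(cfg: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a balanced synthetic cohort under the configured planted
    effects.  Same config (incl. seed) -> byte-identical cohort."""
    cfg = cfg or CohortConfig()
    lexicon = load_content_units()
    demo = _demographics(cfg.n_per_group)
    subjects: list[SubjectRecord] = []
    counter = 0
    for group_idx, label in ((0, "AD"), (1, "non-AD")):
        prefix = "ad" if label == "AD" else "cn"
        for i in range(cfg.n_per_group):
            rng = np.random.Generator(np.random.PCG64(
                np.random.SeedSequence((cfg.seed, counter))))
            counter += 1
            age, sex = demo[i]
            lat = _draw_latents(rng, cfg.effects, group_idx)
            utterances = _build_transcript(rng, lat, lexicon)
            mmse = _mmse_from_latents(lat, cfg.effects, rng,
                                      cfg.mmse_noise_sd)
            sid = f"{prefix}{i:03d}"
            doc = TranscriptDoc(
                subject_id=sid, utterances=utterances,
                meta={"age": age, "sex": sex, "label": label, "mmse": mmse})
            clip = (_build_audio(rng, utterances, cfg.audio_rate)
                    if cfg.make_audio else None)
            subjects.append(SubjectRecord(
                subject_id=sid, doc=doc, clip=clip, label=label,
                mmse=mmse, age=age, sex=sex, latents=lat))
    return SyntheticCohort(subjects=subjects, config=cfg)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Emit ``<id>.cha``, ``<id>.wav`` and ``meta.csv`` in the formats the
    extraction pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        (out / f"{s.subject_id}.cha").write_text(serialize_chat(s.doc))
        if s.clip is not None:
            save_audio(s.clip, out / f"{s.subject_id}.wav")
    cohort.meta_frame().to_csv(out / "meta.csv", index=False)


def read_cohort_dir(transcripts_dir: str | Path,
                    audio_dir: str | Path | None = None,
                    meta_path: str | Path | None = None
                    ) -> list[tuple[TranscriptDoc, AudioClip | None]]:
    """Load a written cohort back as (transcript, audio) pairs."""
    tdir = Path(transcripts_dir)
    adir = Path(audio_dir) if audio_dir is not None else tdir
    meta = (load_metadata(meta_path)
            if meta_path is not None else None)
    pairs = []
    for cha in sorted(tdir.glob("*.cha")):
        sid = cha.stem
        doc = parse_chat(cha.read_text(), subject_id=sid)
        doc.meta.setdefault("label", doc.meta.pop("group", ""))
        if meta is not None and sid in meta.index:
            row = meta.loc[sid]
            doc.meta.update({
                "age": int(row["age"]), "sex": str(row["sex"]),
                "label": str(row["label"])})
            if "mmse" in row and pd.notna(row["mmse"]):
                doc.meta["mmse"] = int(row["mmse"])
        wav = adir / f"{sid}.wav"
        clip = load_audio(wav) if wav.exists() else None
        pairs.append((doc, clip))
    return pairs
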