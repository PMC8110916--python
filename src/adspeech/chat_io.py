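"""Reading CHAT picture-description transcripts and participant audio.

Supports the CHAT subset used in picture-description corpora: ``@`` header
lines (including ``@ID`` metadata), main tiers ``*XXX:\t...``, retracing and
repetition markers ``[/]`` ``[//]``, event codes ``&=...``, filled pauses
``&-um``/``&um``, unfilled pause marks ``(.)`` ``(..)`` ``(...)``,
unintelligible ``xxx``, and scoped-material brackets.  Dependent tiers
(``%mor`` etc.) are ignored.  Only participant-tier utterances are kept: the
battery is defined over the participant's speech alone.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

log = logging.getLogger(__name__)

FILLER_WORDS = ("um", "uh")
#: nominal lengths (s) attributed to the three CHAT pause marks
PAUSE_MARKS = {"(.)": 0.3, "(..)": 0.6, "(...)": 1.2}


class ChatParseError(ValueError):
    """Raised on a malformed tier marker, with the offending line."""


@dataclasses.dataclass
class Utterance:
    speaker: str
    tokens: list[str]
    fillers: int = 0
    filler_positions: list[int] = dataclasses.field(default_factory=list)
    unfilled_pauses: int = 0
    pause_marks: list[str] = dataclasses.field(default_factory=list)
    retraces: int = 0
    unintelligible: int = 0
    raw: str = ""

    def __post_init__(self):
        if self.fillers < 0 or self.unfilled_pauses < 0:
            raise ValueError("filler/pause counts must be non-negative")


@dataclasses.dataclass
class TranscriptDoc:
    subject_id: str
    utterances: list[Utterance]
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        mmse = self.meta.get("mmse")
        if mmse is not None and not (0 <= mmse <= 30):
            raise ValueError(f"MMSE {mmse} outside [0, 30]")

    @property
    def tokens(self) -> list[str]:
        return [t for u in self.utterances for t in u.tokens]

    @property
    def n_fillers(self) -> int:
        return sum(u.fillers for u in self.utterances)

    @property
    def n_unfilled_pauses(self) -> int:
        return sum(u.unfilled_pauses for u in self.utterances)


@dataclasses.dataclass
class AudioClip:
    """Mono waveform, amplitudes in [-1, 1]."""

    samples: np.ndarray
    rate: int

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise ValueError("clip must contain at least one sample")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


_TOKEN_RE = re.compile(r"\S+")
_EVENT_RE = re.compile(r"&=\S+")
_BRACKET_RE = re.compile(r"\[[^\]]*\]")
_PAUSE_RE = re.compile(r"\(\.{1,3}\)")
_WORD_CLEAN_RE = re.compile(r"[^a-z'\-]")


def normalize_tokens(raw_tier: str) -> Utterance:
    """Normalize one main-tier line into an :class:`Utterance` (speaker unset).

    Filled pauses are counted and their positions (w.r.t. the lexical token
    stream) recorded, but they are not part of ``tokens``.  Retraced material
    (the token or ``<...>`` group preceding ``[/]``/``[//]``) is excised from
    the token stream and tallied in ``retraces``.
    """
    text = raw_tier.strip()
    fillers = 0
    filler_positions: list[int] = []
    unfilled = 0
    pause_marks: list[str] = []
    retraces = 0
    unintelligible = 0

    # pause marks first: they contain dots that would be stripped as punctuation
    def _take_pause(m):
        nonlocal unfilled
        unfilled += 1
        pause_marks.append(m.group(0))
        return " "

    text = _PAUSE_RE.sub(_take_pause, text)
    text = _EVENT_RE.sub(" ", text)

    # retracing: excise the group or single token preceding [/] or [//]
    def _excise_retrace(m):
        nonlocal retraces
        retraces += 1
        return " "

    text = re.sub(r"<[^>]*>\s*\[/+\]", _excise_retrace, text)
    text = re.sub(r"\S+\s*\[/+\]", _excise_retrace, text)
    # remaining bracket codes: drop the annotation, keep scoped material
    text = _BRACKET_RE.sub(" ", text)
    text = text.replace("<", " ").replace(">", " ")

    tokens: list[str] = []
    for piece in _TOKEN_RE.findall(text):
        low = piece.lower()
        if low in ("xxx", "yyy", "www"):
            unintelligible += 1
            continue
        m = re.fullmatch(r"&-?(\w+)", low)
        if m:
            if m.group(1) in FILLER_WORDS:
                fillers += 1
                filler_positions.append(len(tokens))
            else:
                log.debug("dropping unknown & code: %s", piece)
            continue
        word = _WORD_CLEAN_RE.sub("", low.replace("(", "").replace(")", ""))
        word = word.strip("'-")
        if word:
            tokens.append(word)
        elif low not in (".", "?", "!", ",", "+...", "+/."):
            log.debug("dropping unknown code: %s", piece)
    return Utterance(
        speaker="", tokens=tokens, fillers=fillers,
        filler_positions=filler_positions, unfilled_pauses=unfilled,
        pause_marks=pause_marks, retraces=retraces,
        unintelligible=unintelligible, raw=raw_tier,
    )


_TIER_RE = re.compile(r"^\*([A-Za-z0-9]+):\s(.*)$", re.DOTALL)


def parse_chat(text: str, participant: str = "PAR",
               subject_id: str = "") -> TranscriptDoc:
    """Parse CHAT-format text into a participant-only :class:`TranscriptDoc`.

    Investigator (and any non-participant) tiers are dropped; dependent
    ``%`` tiers are ignored; ``@ID`` headers matching the participant role
    populate ``meta`` (age, sex, group).  Empty input yields an empty
    document.  A line starting with ``*`` that is not a well-formed tier
    marker raises :class:`ChatParseError` naming the line.
    """
    meta: dict = {}
    utterances: list[Utterance] = []
    # continuation lines (leading tab) are folded into the previous tier
    logical: list[tuple[int, str]] = []
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith(("\t", "    ")) and logical:
            n, prev = logical[-1]
            logical[-1] = (n, prev + " " + line.strip())
        else:
            logical.append((i, line))

    for lineno, line in logical:
        if line.startswith("@"):
            if line.startswith("@ID:"):
                fields = line[4:].strip().rstrip(".").split("|")
                # lang|corpus|code|age|sex|group|SES|role|edu|custom
                if len(fields) >= 8 and fields[2] == participant:
                    age = fields[3].split(";")[0]
                    if age.isdigit():
                        meta["age"] = int(age)
                    if fields[4] in ("male", "M", "m"):
                        meta["sex"] = "M"
                    elif fields[4] in ("female", "F", "f"):
                        meta["sex"] = "F"
                    if fields[5]:
                        meta["group"] = fields[5]
            elif line.startswith("@PID") and not subject_id:
                meta["pid"] = line.split(":", 1)[-1].strip()
            continue
        if line.startswith("%"):
            continue
        if line.startswith("*"):
            m = _TIER_RE.match(line)
            if not m:
                raise ChatParseError(
                    f"malformed tier marker at line {lineno}: {line!r}")
            speaker, content = m.group(1), m.group(2)
            if speaker != participant:
                continue
            utt = normalize_tokens(content)
            utt.speaker = speaker
            utterances.append(utt)
        else:
            raise ChatParseError(
                f"unrecognized line {lineno} (not @header, *tier or %tier): "
                f"{line!r}")
    return TranscriptDoc(subject_id=subject_id, utterances=utterances,
                         meta=meta)


def serialize_chat(doc: TranscriptDoc, participant: str = "PAR") -> str:
    """Write a document back to CHAT text (the supported subset).

    ``parse_chat(serialize_chat(doc))`` reproduces tokens, filler and pause
    counts for any document produced by this package.
    """
    lines = ["@UTF8", "@Begin", "@Languages:\teng"]
    age = doc.meta.get("age", "")
    sex = {"M": "male", "F": "female"}.get(doc.meta.get("sex", ""), "")
    group = doc.meta.get("group", doc.meta.get("label", ""))
    lines.append(
        f"@ID:\teng|adspeech|{participant}|{age};|{sex}|{group}||Participant||")
    for utt in doc.utterances:
        parts: list[str] = []
        pause_iter = iter(utt.pause_marks)
        fill_set = set(utt.filler_positions)
        for i, tok in enumerate(utt.tokens):
            if i in fill_set:
                parts.append("&-um")
            parts.append(tok)
        # fillers positioned at/after end of token stream
        for i in utt.filler_positions:
            if i >= len(utt.tokens):
                parts.append("&-um")
        parts.extend(pause_iter)
        parts.append(".")
        lines.append(f"*{participant}:\t" + " ".join(parts))
    lines.append("@End")
    return "\n".join(lines) + "\n"


def load_audio(path: str | Path) -> AudioClip:
    """Read a PCM WAV file; stereo is mixed to mono by channel mean and
    integer formats are rescaled to [-1, 1]."""
    try:
        rate, data = wavfile.read(str(path))
    except (ValueError, FileNotFoundError, OSError) as exc:
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioClip(samples=np.clip(data, -1.0, 1.0), rate=int(rate))


def save_audio(clip: AudioClip, path: str | Path) -> None:
    """Write a clip as 16-bit PCM WAV."""
    data = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(str(path), clip.rate,
                  (data * np.iinfo(np.int16).max).astype(np.int16))


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Read the cohort metadata CSV (``subject_id,age,sex,label,mmse``)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "age", "sex", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return df.set_index("subject_id", drop=False)
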