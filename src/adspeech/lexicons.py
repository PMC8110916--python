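"""Norm lexicons, the reference wordlist, and the picture content-unit
inventory.

The packaged norm table (``norms_synthetic.csv``) is a constructed,
synthetic stand-in covering the package's controlled vocabulary: published
psycholinguistic norm inventories are licensed separately and are not
bundled.  Any user-supplied CSV with the same schema (word plus numeric
columns) can be loaded in its place for real-data use.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

NORM_COLUMNS = ("imageability", "aoa", "familiarity",
                "valence", "arousal", "dominance")


@dataclasses.dataclass
class NormLexicon:
    """word -> numeric norm maps; lookups are case-insensitive on lemmas."""

    table: pd.DataFrame  # index: word (lower), columns: NORM_COLUMNS

    def __post_init__(self):
        if not np.isfinite(self.table.to_numpy(dtype=float)).all():
            raise ValueError("norm values must be finite")
        self.table.index = self.table.index.str.lower()

    def lookup(self, word: str, norm: str) -> float | None:
        try:
            return float(self.table.at[word.lower(), norm])
        except KeyError:
            return None

    @classmethod
    def from_csv(cls, path: str | Path) -> "NormLexicon":
        df = pd.read_csv(path).set_index("word")
        return cls(table=df)


def load_norms() -> NormLexicon:
    """Load the packaged synthetic norm table."""
    with resources.files("adspeech.data").joinpath(
            "norms_synthetic.csv").open() as fh:
        return NormLexicon(table=pd.read_csv(fh).set_index("word"))


def load_wordlist() -> frozenset[str]:
    """Reference English wordlist used for the non-dictionary-word feature."""
    with resources.files("adspeech.data").joinpath(
            "english_wordlist.txt").open() as fh:
        return frozenset(w.strip().lower() for w in fh if w.strip())


@dataclasses.dataclass(frozen=True)
class ContentUnit:
    name: str
    category: str                 # subject | place | object | action
    synonyms: frozenset[str]      # lemma forms that count as a mention
    anchors: tuple[str, ...]      # words anchoring the unit's embedding


@dataclasses.dataclass
class ContentUnitLexicon:
    units: list[ContentUnit]

    def __post_init__(self):
        names = [u.name for u in self.units]
        if len(set(names)) != len(names):
            raise ValueError("unit names must be unique")
        for u in self.units:
            if not u.synonyms:
                raise ValueError(f"unit {u.name} has no synonyms")
            if u.category not in ("subject", "place", "object", "action"):
                raise ValueError(f"unknown category {u.category}")

    def by_category(self, category: str) -> list[ContentUnit]:
        return [u for u in self.units if u.category == category]

    def all_synonyms(self) -> frozenset[str]:
        return frozenset(s for u in self.units for s in u.synonyms)

    @classmethod
    def from_csv(cls, path) -> "ContentUnitLexicon":
        df = pd.read_csv(path)
        units = [
            ContentUnit(
                name=r["unit"], category=r["category"],
                synonyms=frozenset(str(r["synonyms"]).split("|")),
                anchors=tuple(str(r["anchors"]).split("|")),
            )
            for _, r in df.iterrows()
        ]
        return cls(units=units)


def load_content_units() -> ContentUnitLexicon:
    """The packaged Cookie Theft content-unit inventory."""
    with resources.files("adspeech.data").joinpath(
            "content_units.csv").open() as fh:
        return ContentUnitLexicon.from_csv(fh)
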