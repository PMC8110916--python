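"""Extraction orchestrator: one 509-dimensional named vector per subject.

``extract_features`` wires the pluggable resources (tagger, parser, two
embedding inventories, norm lexicon, wordlist, content-unit lexicon)
through all feature families in registry order.  Features undefined on an
input (e.g. pairwise coherence with a single utterance) are imputed to 0 in
the returned vector; the accompanying ``defined`` mask records which values
were imputed, so downstream analyses can distinguish "zero" from "absent".
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import acoustic, lexicosyntactic, semantic_content
from .acoustic import FrameSpec, segment_silences
from .chat_io import AudioClip, TranscriptDoc
from .embeddings import HashEmbedding
from .lexicons import (ContentUnitLexicon, NormLexicon, load_content_units,
                       load_norms, load_wordlist)
from .registry import FeatureRegistry, get_registry
from .tagging import ChunkParser, LexiconTagger, Parser, Tagger

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ExtractorResources:
    tagger: Tagger
    parser: Parser
    emb_a: HashEmbedding            # "word2vec-style" inventory
    emb_b: HashEmbedding            # "GloVe-style" inventory
    norms: NormLexicon
    wordlist: frozenset[str]
    content_units: ContentUnitLexicon
    frame_spec: FrameSpec = FrameSpec()
    registry: FeatureRegistry = dataclasses.field(default_factory=get_registry)


def default_resources() -> ExtractorResources:
    return ExtractorResources(
        tagger=LexiconTagger(),
        parser=ChunkParser(),
        emb_a=HashEmbedding(dim=50, seed=11),
        emb_b=HashEmbedding(dim=50, seed=23),
        norms=load_norms(),
        wordlist=load_wordlist(),
        content_units=load_content_units(),
    )


def extract_features(doc: TranscriptDoc, clip: AudioClip | None = None,
                     resources: ExtractorResources | None = None
                     ) -> tuple[pd.Series, pd.Series]:
    """Extract the full battery for one subject.

    Returns ``(values, defined)``: both indexed by the 509 registry names;
    ``values`` has undefined features imputed to 0, ``defined`` is the
    boolean mask of features that were actually computable.
    """
    res = resources or default_resources()
    tagged = res.tagger.tag(doc)
    trees = res.parser.parse(tagged)

    raw: dict[str, float] = {}
    raw.update(lexicosyntactic.pos_features(tagged))
    raw.update(lexicosyntactic.syntactic_complexity_features(tagged, trees))
    raw.update(lexicosyntactic.production_rule_features(trees))
    raw.update(lexicosyntactic.lexical_richness(doc.tokens))
    raw.update(lexicosyntactic.coherence_features(doc, res.emb_a))
    raw.update(lexicosyntactic.speech_graph_features(
        [u.tokens for u in doc.utterances]))

    audio_dur = speech_dur = None
    if clip is not None:
        audio_dur = clip.duration
        speech_dur = segment_silences(clip, res.frame_spec).speech_duration
    raw.update(lexicosyntactic.misc_lexical_features(
        tagged, res.norms, res.wordlist,
        audio_duration=audio_dur, speech_duration=speech_dur))

    raw.update(acoustic.extract_acoustic(clip, doc, res.frame_spec))

    raw.update(semantic_content.content_unit_ratios(tagged, res.content_units))
    raw.update(semantic_content.global_coherence_distances(
        tagged, res.content_units, res.emb_a, res.emb_b))

    names = res.registry.names
    missing = set(names) - set(raw)
    if missing:
        raise RuntimeError(f"extractor did not emit: {sorted(missing)[:5]}")
    values = pd.Series([raw[n] for n in names], index=names, dtype=float)
    defined = ~values.isna()
    n_undef = int((~defined).sum())
    if n_undef:
        log.debug("%s: %d features undefined, imputed to 0",
                  doc.subject_id, n_undef)
    return values.fillna(0.0), defined


@dataclasses.dataclass
class CohortTable:
    """Per-subject feature matrix plus labels and demographics.

    ``features``: (n_subjects, 509) DataFrame indexed by subject_id;
    ``meta``: DataFrame with columns label, mmse, age, sex (same index).
    """

    features: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.features.index.equals(self.meta.index):
            raise ValueError("features and meta must share the subject index")

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return (self.meta["label"] == "AD").to_numpy()

    @property
    def mmse(self) -> np.ndarray:
        return self.meta["mmse"].to_numpy(dtype=float)

    @property
    def subject_ids(self) -> list[str]:
        return self.features.index.tolist()

    def to_csv(self, features_path, meta_path) -> None:
        self.features.to_csv(features_path)
        self.meta.to_csv(meta_path)

    @classmethod
    def from_csv(cls, features_path, meta_path) -> "CohortTable":
        feats = pd.read_csv(features_path, index_col=0)
        feats.index = feats.index.astype(str)
        meta = pd.read_csv(meta_path, index_col=0)
        meta.index = meta.index.astype(str)
        return cls(features=feats, meta=meta.loc[feats.index])


def extract_cohort(subjects: list[tuple[TranscriptDoc, AudioClip | None]],
                   resources: ExtractorResources | None = None) -> CohortTable:
    """Extract the battery for a list of (transcript, audio) pairs."""
    res = resources or default_resources()
    rows, metas, ids = [], [], []
    for doc, clip in subjects:
        values, _ = extract_features(doc, clip, res)
        rows.append(values)
        ids.append(doc.subject_id)
        metas.append({
            "label": doc.meta.get("label", doc.meta.get("group", "")),
            "mmse": doc.meta.get("mmse", np.nan),
            "age": doc.meta.get("age", np.nan),
            "sex": doc.meta.get("sex", ""),
        })
    features = pd.DataFrame(rows, index=ids)
    meta = pd.DataFrame(metas, index=ids)
    return CohortTable(features=features, meta=meta)
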