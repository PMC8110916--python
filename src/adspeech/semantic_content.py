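"""Picture-content semantic features (25) against the Cookie Theft
content-unit lexicon.

A content unit counts as *mentioned* when any of its synonym lemmas occurs
among the participant's lemmatized tokens.  Distinct-mention ratios
(overall and for object/action categories) and individual content-lemma
frequencies make up the word-frequency family; global coherence measures
the cosine distance between utterance embeddings and content-unit anchor
embeddings under two embedding inventories.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .embeddings import cosine_similarity, embed_utterance
from .lexicons import ContentUnitLexicon
from .registry import CONTENT_CATEGORIES, CONTENT_FREQ_LEMMAS
from .tagging import PosTaggedDoc

NAN = float("nan")


def mentioned_units(tagged: PosTaggedDoc,
                    lex: ContentUnitLexicon) -> set[str]:
    lemmas = {t.lemma for t in tagged.tokens}
    return {u.name for u in lex.units if u.synonyms & lemmas}


def content_unit_ratios(tagged: PosTaggedDoc,
                        lex: ContentUnitLexicon) -> dict[str, float]:
    """Distinct-mentioned : total content-unit ratios (overall, objects,
    actions) plus per-lemma frequency proportions (10 features)."""
    mentioned = mentioned_units(tagged, lex)
    out: dict[str, float] = {}
    total = len(lex.units)
    out["cu_distinct_total_ratio"] = len(mentioned) / total if total else NAN
    for cat, name in (("object", "cu_distinct_object_ratio"),
                      ("action", "cu_distinct_action_ratio")):
        units = lex.by_category(cat)
        out[name] = (sum(u.name in mentioned for u in units) / len(units)
                     if units else NAN)
    lemma_counts = Counter(t.lemma for t in tagged.tokens)
    n = sum(lemma_counts.values())
    for lemma in CONTENT_FREQ_LEMMAS:
        out[f"cu_freq_{lemma}"] = lemma_counts.get(lemma, 0) / n if n else 0.0
    return out


def _anchor_vector(words, emb) -> np.ndarray | None:
    return emb.embed_tokens(list(words))


def global_coherence_distances(tagged: PosTaggedDoc, lex: ContentUnitLexicon,
                               emb_a, emb_b) -> dict[str, float]:
    """Cosine distances between utterance embeddings and content-unit
    anchors (15 features).

    For each of the two embedding inventories: mean/min/max distance of
    utterances to the all-units anchor, plus the mean distance per content
    category; and one shared statistic, the mean distance of each utterance
    to its nearest single-unit anchor (under inventory A).
    """
    out: dict[str, float] = {}
    names = []
    for inv in ("w2v", "glove"):
        names += [f"gcohere_{inv}_dist_{s}" for s in ("mean", "min", "max")]
        names += [f"gcohere_{inv}_dist_{c}" for c in CONTENT_CATEGORIES]
    names.append("gcohere_nearest_anchor_mean")

    utt_tokens = [[t.word for t in u] for u in tagged.utterances if u]
    if not utt_tokens:
        return {n: NAN for n in names}

    all_anchor_words = [w for u in lex.units for w in u.anchors]
    for inv, emb in (("w2v", emb_a), ("glove", emb_b)):
        vecs = [v for v in (embed_utterance(toks, emb)
                            for toks in utt_tokens) if v is not None]
        anchor = _anchor_vector(all_anchor_words, emb)
        if not vecs or anchor is None:
            out.update({n: NAN for n in names if n.startswith(f"gcohere_{inv}")})
        else:
            dists = [1 - cosine_similarity(v, anchor) for v in vecs]
            out[f"gcohere_{inv}_dist_mean"] = float(np.mean(dists))
            out[f"gcohere_{inv}_dist_min"] = float(np.min(dists))
            out[f"gcohere_{inv}_dist_max"] = float(np.max(dists))
            for cat in CONTENT_CATEGORIES:
                cat_words = [w for u in lex.by_category(cat) for w in u.anchors]
                cvec = _anchor_vector(cat_words, emb)
                if cvec is None:
                    out[f"gcohere_{inv}_dist_{cat}"] = NAN
                else:
                    out[f"gcohere_{inv}_dist_{cat}"] = float(np.mean(
                        [1 - cosine_similarity(v, cvec) for v in vecs]))

    vecs = [v for v in (embed_utterance(toks, emb_a)
                        for toks in utt_tokens) if v is not None]
    unit_vecs = [uv for uv in (_anchor_vector(u.anchors, emb_a)
                               for u in lex.units) if uv is not None]
    if vecs and unit_vecs:
        out["gcohere_nearest_anchor_mean"] = float(np.mean(
            [min(1 - cosine_similarity(v, uv) for uv in unit_vecs)
             for v in vecs]))
    else:
        out["gcohere_nearest_anchor_mean"] = NAN
    return out
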