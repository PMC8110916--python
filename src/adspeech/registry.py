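"""Canonical catalogue of the 509-feature battery.

The extractor emits one value per registry entry, in registry order.  The
battery is split into three top-level categories — lexico-syntactic (297),
acoustic/temporal (187) and picture-content semantic (25) — each subdivided
into families with frozen sizes.  Where the originating literature fixes a
family's *size* but not the identity of its members (e.g. which 15 local
coherence statistics), the registry freezes an explicit choice so that
extraction is reproducible; those choices are documented in the methods note.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import pandas as pd

# ---------------------------------------------------------------------------
# Frozen tag / rule inventories
# ---------------------------------------------------------------------------

#: 36 Penn Treebank word tags + 17 punctuation/auxiliary tags = 53 tracked tags.
PTB_TAGS: tuple[str, ...] = (
    "CC", "CD", "DT", "EX", "FW", "IN", "JJ", "JJR", "JJS", "LS", "MD",
    "NN", "NNP", "NNPS", "NNS", "PDT", "POS", "PRP", "PRP$",
    "RB", "RBR", "RBS", "RP", "SYM", "TO", "UH",
    "VB", "VBD", "VBG", "VBN", "VBP", "VBZ", "WDT", "WP", "WP$", "WRB",
    "$", "#", "''", "``", ",", ".", ":", "-LRB-", "-RRB-",
    "HYPH", "NFP", "AFX", "ADD", "GW", "XX", "_SP", "NIL",
)

#: 18 universal POS tags (the spaCy universal inventory).
UPOS_TAGS: tuple[str, ...] = (
    "ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN", "NUM",
    "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM", "VERB", "X", "SPACE",
)

# 104-rule production inventory.  Rules outside the inventory are tallied into
# an "other" bucket that is not itself a feature.
_S_RULES = [
    "S->NP VP", "S->NP VP PP", "S->NP VP ADVP", "S->NP VP PP PP",
    "S->NP VP NP", "S->VP", "S->VP NP", "S->VP PP",
    "S->EX VP NP", "S->EX VP NP PP", "S->ADVP NP VP", "S->NP ADVP VP",
    "S->INTJ NP VP", "S->NP VP CC VP", "S->NP VP ADVP PP", "S->NP VP NP PP",
    "S->NP VP SBAR", "S->VP SBAR", "S->NP VP ADJP",
]
_NP_RULES = [
    "NP->PRP", "NP->NN", "NP->NNS", "NP->DT NN", "NP->DT NNS",
    "NP->DT JJ NN", "NP->DT JJ NNS", "NP->JJ NN", "NP->JJ NNS",
    "NP->PRP$ NN", "NP->PRP$ NNS", "NP->DT NN NN", "NP->NN NN",
    "NP->DT JJ JJ NN", "NP->CD NN", "NP->CD NNS", "NP->DT CD NN",
    "NP->NP PP", "NP->NP CC NP", "NP->EX", "NP->DT", "NP->WP",
    "NP->WDT", "NP->NP SBAR",
]
_VP_RULES = [
    "VP->VBZ", "VP->VBP", "VP->VBD", "VP->VB", "VP->VBG", "VP->VBN",
    "VP->VBZ NP", "VP->VBP NP", "VP->VBD NP", "VP->VB NP", "VP->VBG NP",
    "VP->VBZ VBG", "VP->VBP VBG", "VP->VBD VBG",
    "VP->VBZ VBG NP", "VP->VBP VBG NP", "VP->VBD VBG NP",
    "VP->VBZ VBN", "VP->VBP VBN", "VP->MD VB", "VP->MD VB NP",
    "VP->TO VB", "VP->TO VB NP",
    "VP->VBZ ADJP", "VP->VBP ADJP", "VP->VBD ADJP",
    "VP->VBZ NP PP", "VP->VBP NP PP", "VP->VBZ VBG PP", "VP->VBP VBG PP",
    "VP->VBZ PP", "VP->VBP PP", "VP->VBD PP", "VP->VBG PP",
    "VP->VBZ ADVP", "VP->VBP ADVP", "VP->VBD ADVP", "VP->VBZ RP",
    "VP->VP CC VP", "VP->MD RB VB",
    "VP->VBZ S", "VP->VBP S", "VP->VBZ SBAR", "VP->VBP SBAR",
    "VP->VBD SBAR", "VP->VB PP", "VP->VBN PP", "VP->VBG NP PP",
]
_OTHER_RULES = [
    "PP->IN NP", "PP->TO NP", "PP->IN NP PP", "PP->IN S",
    "ADVP->RB", "ADVP->RB RB", "ADVP->RBR",
    "ADJP->JJ", "ADJP->RB JJ", "ADJP->JJ CC JJ",
    "SBAR->IN S", "SBAR->WDT S", "SBAR->WP S",
]

PRODUCTION_RULES: tuple[str, ...] = tuple(
    _S_RULES + _NP_RULES + _VP_RULES + _OTHER_RULES
)
assert len(PRODUCTION_RULES) == 104, len(PRODUCTION_RULES)

#: Phrase types with proportion / mean length / per-utterance rate features.
PHRASE_TYPES: tuple[str, ...] = ("NP", "VP", "PP", "ADVP")

#: Content lemmas whose relative frequency is reported individually.
CONTENT_FREQ_LEMMAS: tuple[str, ...] = (
    "cookie", "water", "boy", "girl", "stool", "sink", "jar",
)

#: Content-unit categories of the picture-description lexicon.
CONTENT_CATEGORIES: tuple[str, ...] = ("subject", "place", "object", "action")

#: Statistics taken over per-frame series for spectral moment features.
MOMENTS: tuple[str, ...] = ("mean", "variance", "skewness", "kurtosis")

#: MFCC layout: 14 static (incl. the 0th/energy coefficient) + deltas +
#: delta-deltas = 42 coefficients, each summarised by the 4 moments.
N_MFCC_STATIC = 14

_STATS5 = ("mean", "min", "max", "median", "sd")


def _syntactic_complexity_names() -> list[str]:
    names = [f"sc_utt_len_{s}" for s in _STATS5] + ["sc_utt_len_total"]
    names += [f"sc_tree_depth_{s}" for s in ("mean", "min", "max", "sd")]
    names += [f"sc_tree_nodes_{s}" for s in ("mean", "max", "sd")]
    names += [f"sc_clauses_per_utt_{s}" for s in ("mean", "max", "sd")]
    names += [
        "sc_clauses_per_tunit", "sc_dep_clauses_per_clause",
        "sc_dep_clauses_per_tunit", "sc_tunits_per_utt",
        "sc_mean_len_clause", "sc_mean_len_tunit",
        "sc_vp_per_utt", "sc_vp_per_tunit",
        "sc_coord_per_utt", "sc_coord_per_clause",
        "sc_complex_np_per_utt", "sc_complex_np_per_clause",
        "sc_prop_multi_clause_utt", "sc_prop_single_word_utt",
        "sc_productions_per_utt", "sc_depth_to_len_ratio_mean",
        "sc_np_mod_per_np", "sc_left_branching_ratio",
        "sc_max_np_len", "sc_max_vp_len",
    ]
    assert len(names) == 36, len(names)
    return names


def _rule_feat(rule: str) -> str:
    return "prod_prop_" + rule.replace("->", "_").replace(" ", "_")


def build_registry() -> pd.DataFrame:
    """Construct the registry as a DataFrame with columns
    ``name, family, category, index`` (509 rows)."""
    rows: list[tuple[str, str, str]] = []

    def add(names, family, category):
        rows.extend((n, family, category) for n in names)

    L = "lexicosyntactic"
    # -- lexico-syntactic (297) --
    add(_syntactic_complexity_names(), "syntactic_complexity", L)        # 36
    add([_rule_feat(r) for r in PRODUCTION_RULES], "production_rules", L)  # 104
    phr = []
    for p in PHRASE_TYPES:
        phr += [f"phr_{p}_prop", f"phr_{p}_mean_len", f"phr_{p}_rate"]
    phr.append("phr_ADJP_prop")
    add(phr, "phrasal_ratios", L)                                        # 13
    add([f"norm_{n}_{sc}" for n in ("imageability", "aoa", "familiarity")
         for sc in ("all", "nouns", "verbs", "types")],
        "lexical_norms", L)                                              # 12
    add(["rich_ttr", "rich_mattr", "rich_brunet_w", "rich_honore_r",
         "rich_guiraud_r", "rich_herdan_c"], "lexical_richness", L)      # 6
    add(["wordcat_prop_demonstratives", "wordcat_prop_function",
         "wordcat_prop_light_verbs", "wordcat_prop_inflected_verbs",
         "wordcat_prop_propositions"], "word_category", L)               # 5
    add(["ratio_nouns_nouns_verbs", "ratio_nouns_verbs",
         "ratio_pronouns_pronouns_nouns"], "noun_ratio", L)              # 3
    add(["len_avg_word_length"], "length", L)                            # 1
    add([f"upos_prop_{t}" for t in UPOS_TAGS], "universal_pos", L)       # 18
    add([f"pos_prop_{t}" for t in PTB_TAGS], "pos_tags", L)              # 53
    loc = []
    for series in ("sim_lag1", "dist_lag1", "dist_lag2"):
        loc += [f"cohere_{series}_{s}" for s in _STATS5]
    add(loc, "local_coherence", L)                                       # 15
    add(["uttdist_frac_below_0.5", "uttdist_frac_below_0.3",
         "uttdist_frac_below_0", "uttdist_avg_dist", "uttdist_min_dist"],
        "utterance_distance", L)                                         # 5
    add(["graph_nodes", "graph_edges", "graph_repeated_edges",
         "graph_self_loops_L1", "graph_cycles_L2", "graph_cycles_L3",
         "graph_largest_cc", "graph_largest_scc", "graph_density",
         "graph_diameter", "graph_avg_shortest_path",
         "graph_mean_total_degree", "graph_transitivity"],
        "speech_graph", L)                                               # 13
    add(["cohesion_tense_switch_rate"], "cohesion", L)                   # 1
    add(["rate_words_per_sec_audio", "rate_syllables_per_sec_speech"],
        "rate", L)                                                       # 2
    add(["invalid_prop_non_dictionary"], "invalid_words", L)             # 1
    add([f"sent_{n}_{sc}" for n in ("valence", "arousal", "dominance")
         for sc in ("all", "nouns", "verbs")], "sentiment_norms", L)     # 9

    # -- acoustic/temporal (187) --
    A = "acoustic"
    add(["pause_total_dur", "pause_mean_dur", "pause_long_count",
         "pause_short_count", "pause_word_ratio", "filler_count",
         "filler_word_ratio", "pause_speech_dur_ratio",
         "pause_dur_word_ratio"], "pauses_fillers", A)                   # 9
    add([f"f0_{s}" for s in ("mean", "min", "max", "median")],
        "fundamental_frequency", A)                                      # 4
    add(["dur_total_audio", "dur_total_speech"], "duration", A)          # 2
    add([f"zcr_{m}" for m in MOMENTS], "zcr", A)                         # 4
    mf = []
    for kind in ("c", "d", "dd"):
        for i in range(N_MFCC_STATIC):
            mf += [f"mfcc_{kind}{i:02d}_{m}" for m in MOMENTS]
    add(mf, "mfcc", A)                                                   # 168

    # -- semantic picture-content (25) --
    S = "semantic"
    add(["cu_distinct_total_ratio", "cu_distinct_object_ratio",
         "cu_distinct_action_ratio"]
        + [f"cu_freq_{w}" for w in CONTENT_FREQ_LEMMAS],
        "word_frequency", S)                                             # 10
    gc = []
    for inv in ("w2v", "glove"):
        gc += [f"gcohere_{inv}_dist_{s}" for s in ("mean", "min", "max")]
        gc += [f"gcohere_{inv}_dist_{c}" for c in CONTENT_CATEGORIES]
    gc.append("gcohere_nearest_anchor_mean")
    add(gc, "global_coherence", S)                                       # 15

    df = pd.DataFrame(rows, columns=["name", "family", "category"])
    df["index"] = range(len(df))
    return df


#: Family sizes in registry order; used by the shape-contract checks.
FAMILY_SIZES: dict[str, int] = {
    "syntactic_complexity": 36, "production_rules": 104,
    "phrasal_ratios": 13, "lexical_norms": 12, "lexical_richness": 6,
    "word_category": 5, "noun_ratio": 3, "length": 1,
    "universal_pos": 18, "pos_tags": 53, "local_coherence": 15,
    "utterance_distance": 5, "speech_graph": 13, "cohesion": 1,
    "rate": 2, "invalid_words": 1, "sentiment_norms": 9,
    "pauses_fillers": 9, "fundamental_frequency": 4, "duration": 2,
    "zcr": 4, "mfcc": 168,
    "word_frequency": 10, "global_coherence": 15,
}

CATEGORY_SIZES: dict[str, int] = {
    "lexicosyntactic": 297, "acoustic": 187, "semantic": 25,
}


@dataclasses.dataclass(frozen=True)
class FeatureRegistry:
    """Immutable view over the registry table."""

    table: pd.DataFrame

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    def family(self, name: str) -> str:
        return self.table.set_index("name").loc[name, "family"]

    def names_in_family(self, family: str) -> list[str]:
        return self.table.loc[self.table["family"] == family, "name"].tolist()

    def names_in_category(self, category: str) -> list[str]:
        return self.table.loc[self.table["category"] == category, "name"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def get_registry() -> FeatureRegistry:
    return FeatureRegistry(build_registry())


def load_registry_csv() -> pd.DataFrame:
    """Read the packaged ``registry.csv`` (the external, editable interface)."""
    with resources.files("adspeech.data").joinpath("registry.csv").open() as fh:
        return pd.read_csv(fh, keep_default_na=False)


def write_registry_csv(path: str) -> None:
    build_registry().to_csv(path, index=False)


if __name__ == "__main__":  # pragma: no cover
    import sys

    write_registry_csv(sys.argv[1] if len(sys.argv) > 1 else "registry.csv")
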