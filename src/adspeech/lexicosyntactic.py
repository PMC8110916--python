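"""Lexico-syntactic feature battery (297 features).

Families: POS-tag proportions (fine + universal), word categories, noun
ratios, word length, syntactic complexity, production-rule and phrasal-type
statistics, lexical richness, utterance coherence and pairwise distances,
word-adjacency speech-graph topology, lexical/sentiment norms, invalid
words, tense cohesion and speaking-rate ratios.

Every function returns ``{feature_name: value}`` with ``math.nan`` marking
features undefined on the input; the extraction orchestrator imputes these
to 0 and keeps a defined-mask.  Values are deterministic given the tagger,
parser, embedding provider and lexicons in use.
"""

from __future__ import annotations

import math
from collections import Counter

import networkx as nx
import numpy as np

from .chat_io import TranscriptDoc
from .embeddings import cosine_similarity, embed_utterance
from .lexicons import NormLexicon
from .registry import PRODUCTION_RULES, PTB_TAGS, UPOS_TAGS, PHRASE_TYPES
from .tagging import (DEMONSTRATIVES, FUNCTION_TAGS, NOUN_TAGS, PAST_TAGS,
                      PRESENT_TAGS, PRONOUN_TAGS, VERB_TAGS, ParseTree,
                      PosTaggedDoc, count_syllables)

NAN = float("nan")

LIGHT_VERBS = frozenset(
    {"be", "have", "do", "get", "make", "go", "take", "come", "give"})
#: tags contributing to propositional density (verbs, adjectives, adverbs,
#: prepositions, conjunctions)
_PROPOSITION_TAGS = VERB_TAGS | {"JJ", "JJR", "JJS", "RB", "RBR", "RBS",
                                 "IN", "CC", "MD"}

_STATS5 = ("mean", "min", "max", "median", "sd")


def _series_stats(values, stats=_STATS5) -> dict[str, float]:
    if len(values) == 0:
        return {s: NAN for s in stats}
    arr = np.asarray(values, dtype=float)
    table = {"mean": float(arr.mean()), "min": float(arr.min()),
             "max": float(arr.max()), "median": float(np.median(arr)),
             "sd": float(arr.std())}
    return {s: table[s] for s in stats}


# ---------------------------------------------------------------------------
# POS proportions, word categories, ratios, word length
# ---------------------------------------------------------------------------

def pos_features(tagged: PosTaggedDoc) -> dict[str, float]:
    """53 fine-tag + 18 coarse-tag proportions, 5 word-category
    proportions, 3 noun ratios, and average word length (80 features)."""
    toks = tagged.tokens
    n = len(toks)
    out: dict[str, float] = {}
    fine = Counter(t.tag for t in toks)
    coarse = Counter(t.upos for t in toks)
    for tag in PTB_TAGS:
        out[f"pos_prop_{tag}"] = fine.get(tag, 0) / n if n else NAN
    for tag in UPOS_TAGS:
        out[f"upos_prop_{tag}"] = coarse.get(tag, 0) / n if n else NAN

    if n == 0:
        for name in ("wordcat_prop_demonstratives", "wordcat_prop_function",
                     "wordcat_prop_light_verbs",
                     "wordcat_prop_inflected_verbs",
                     "wordcat_prop_propositions", "ratio_nouns_nouns_verbs",
                     "ratio_nouns_verbs", "ratio_pronouns_pronouns_nouns",
                     "len_avg_word_length"):
            out[name] = NAN
        return out

    out["wordcat_prop_demonstratives"] = sum(
        t.word in DEMONSTRATIVES for t in toks) / n
    out["wordcat_prop_function"] = sum(
        t.tag in FUNCTION_TAGS for t in toks) / n
    out["wordcat_prop_light_verbs"] = sum(
        t.tag in VERB_TAGS and t.lemma in LIGHT_VERBS for t in toks) / n
    out["wordcat_prop_inflected_verbs"] = sum(
        t.tag in (VERB_TAGS - {"VB"}) for t in toks) / n
    out["wordcat_prop_propositions"] = sum(
        t.tag in _PROPOSITION_TAGS for t in toks) / n

    nouns = sum(t.tag in NOUN_TAGS for t in toks)
    verbs = sum(t.tag in VERB_TAGS for t in toks)
    pron = sum(t.tag in PRONOUN_TAGS for t in toks)
    out["ratio_nouns_nouns_verbs"] = nouns / (nouns + verbs) if nouns + verbs else NAN
    out["ratio_nouns_verbs"] = nouns / verbs if verbs else NAN
    out["ratio_pronouns_pronouns_nouns"] = pron / (pron + nouns) if pron + nouns else NAN
    out["len_avg_word_length"] = float(
        np.mean([sum(c.isalpha() for c in t.word) for t in toks]))
    return out


# ---------------------------------------------------------------------------
# Syntactic complexity (36)
# ---------------------------------------------------------------------------

def _clauses(tree: ParseTree) -> int:
    return sum(1 for _ in tree.subtrees("S")) + sum(
        1 for _ in tree.subtrees("SBAR"))


def _tunits(tree: ParseTree) -> int:
    # a coordinated root-level VP opens an additional T-unit
    extra = sum(1 for i, c in enumerate(tree.children)
                if c.label == "CC" and i > 0
                and any(k.label == "VP" for k in tree.children[i + 1:]))
    return 1 + extra


def syntactic_complexity_features(tagged: PosTaggedDoc,
                                  trees: list[ParseTree]) -> dict[str, float]:
    """36 length/depth/clause-based complexity measures."""
    out: dict[str, float] = {}
    lens = [len(u) for u in tagged.utterances if u]
    names_on_empty = _syntactic_names()
    if not lens or not trees:
        return {n: NAN for n in names_on_empty}

    out.update({f"sc_utt_len_{k}": v for k, v in _series_stats(lens).items()})
    out["sc_utt_len_total"] = float(sum(lens))

    depths = [t.depth() - 1 for t in trees]          # root at depth 0
    out.update({f"sc_tree_depth_{k}": v for k, v in _series_stats(
        depths, ("mean", "min", "max", "sd")).items()})
    nodes = [t.n_nodes() for t in trees]
    out.update({f"sc_tree_nodes_{k}": v for k, v in _series_stats(
        nodes, ("mean", "max", "sd")).items()})

    clauses = [_clauses(t) for t in trees]
    out.update({f"sc_clauses_per_utt_{k}": v for k, v in _series_stats(
        clauses, ("mean", "max", "sd")).items()})
    tunits = [_tunits(t) for t in trees]
    tot_cl, tot_tu = sum(clauses), sum(tunits)
    tot_tokens = sum(lens)
    n_utt = len(trees)
    dep_clauses = sum(sum(1 for _ in t.subtrees("SBAR")) for t in trees)
    vps = [sum(1 for _ in t.subtrees("VP")) for t in trees]
    coords = [sum(1 for leaf_tag in _leaf_tags(t) if leaf_tag == "CC")
              for t in trees]
    nps = [list(t.subtrees("NP")) for t in trees]
    complex_nps = [sum(1 for np_ in u if len(np_.leaves()) >= 3) for u in nps]

    out["sc_clauses_per_tunit"] = tot_cl / tot_tu if tot_tu else NAN
    out["sc_dep_clauses_per_clause"] = dep_clauses / tot_cl if tot_cl else NAN
    out["sc_dep_clauses_per_tunit"] = dep_clauses / tot_tu if tot_tu else NAN
    out["sc_tunits_per_utt"] = tot_tu / n_utt
    out["sc_mean_len_clause"] = tot_tokens / tot_cl if tot_cl else NAN
    out["sc_mean_len_tunit"] = tot_tokens / tot_tu if tot_tu else NAN
    out["sc_vp_per_utt"] = sum(vps) / n_utt
    out["sc_vp_per_tunit"] = sum(vps) / tot_tu if tot_tu else NAN
    out["sc_coord_per_utt"] = sum(coords) / n_utt
    out["sc_coord_per_clause"] = sum(coords) / tot_cl if tot_cl else NAN
    out["sc_complex_np_per_utt"] = sum(complex_nps) / n_utt
    out["sc_complex_np_per_clause"] = sum(complex_nps) / tot_cl if tot_cl else NAN
    out["sc_prop_multi_clause_utt"] = sum(c >= 2 for c in clauses) / n_utt
    out["sc_prop_single_word_utt"] = sum(
        len(t.leaves()) == 1 for t in trees) / n_utt
    out["sc_productions_per_utt"] = sum(
        len(t.productions()) for t in trees) / n_utt
    out["sc_depth_to_len_ratio_mean"] = float(np.mean(
        [d / max(1, len(t.leaves())) for d, t in zip(depths, trees)]))
    all_nps = [np_ for u in nps for np_ in u]
    out["sc_np_mod_per_np"] = (float(np.mean(
        [len(np_.leaves()) - 1 for np_ in all_nps])) if all_nps else NAN)
    out["sc_left_branching_ratio"] = float(np.mean(
        [_left_branching(t) for t in trees]))
    out["sc_max_np_len"] = (float(max(len(np_.leaves()) for np_ in all_nps))
                            if all_nps else NAN)
    all_vps = [vp for t in trees for vp in t.subtrees("VP")]
    out["sc_max_vp_len"] = (float(max(len(vp.leaves()) for vp in all_vps))
                            if all_vps else NAN)
    return out


def _leaf_tags(tree: ParseTree) -> list[str]:
    if tree.is_leaf:
        return [tree.label]
    return [tag for c in tree.children for tag in _leaf_tags(c)]


def _left_branching(tree: ParseTree) -> float:
    """Fraction of tokens preceding the first VP constituent."""
    leaves_before = 0
    for child in tree.children:
        if child.label == "VP":
            break
        leaves_before += len(child.leaves()) if not child.is_leaf else 1
    total = len(tree.leaves())
    return leaves_before / total if total else 0.0


def _syntactic_names() -> list[str]:
    from .registry import build_registry
    df = build_registry()
    return df.loc[df["family"] == "syntactic_complexity", "name"].tolist()


# ---------------------------------------------------------------------------
# Production rules and phrasal types (104 + 13)
# ---------------------------------------------------------------------------

def production_rule_features(trees: list[ParseTree]) -> dict[str, float]:
    """Proportion of each inventory production among all productions, plus
    proportion / mean length / per-utterance rate of NP, VP, PP, ADVP and
    ADJP proportion (117 features)."""
    out: dict[str, float] = {}
    rule_names = ["prod_prop_" + r.replace("->", "_").replace(" ", "_")
                  for r in PRODUCTION_RULES]
    phr_names = [f"phr_{p}_{k}" for p in PHRASE_TYPES
                 for k in ("prop", "mean_len", "rate")] + ["phr_ADJP_prop"]
    if not trees:
        return {n: NAN for n in rule_names + phr_names}

    counts: Counter[str] = Counter()
    for t in trees:
        counts.update(t.productions())
    total = sum(counts.values())
    for rule, name in zip(PRODUCTION_RULES, rule_names):
        out[name] = counts.get(rule, 0) / total if total else NAN

    constituents = [st for t in trees for st in t.subtrees()
                    if st.label != "S" or st is not t]  # exclude utterance roots
    n_const = len(constituents)
    n_utt = len(trees)
    for p in PHRASE_TYPES:
        of_type = [c for c in constituents if c.label == p]
        out[f"phr_{p}_prop"] = len(of_type) / n_const if n_const else 0.0
        out[f"phr_{p}_mean_len"] = (float(np.mean(
            [len(c.leaves()) for c in of_type])) if of_type else NAN)
        out[f"phr_{p}_rate"] = len(of_type) / n_utt
    out["phr_ADJP_prop"] = (sum(c.label == "ADJP" for c in constituents)
                            / n_const if n_const else 0.0)
    return out


# ---------------------------------------------------------------------------
# Lexical richness (6)
# ---------------------------------------------------------------------------

#: Honoré denominator guard when every type is a hapax (V1 == V)
HONORE_EPS = 1e-3
#: Brunet's W exponent constant
BRUNET_EXPONENT = -0.165
#: moving-average TTR window
MATTR_WINDOW = 10


def lexical_richness(tokens: list[str]) -> dict[str, float]:
    """Type-token ratio, moving-average TTR, Brunet's W, Honoré's R,
    Guiraud's index and Herdan's C."""
    n = len(tokens)
    if n == 0:
        return {k: NAN for k in ("rich_ttr", "rich_mattr", "rich_brunet_w",
                                 "rich_honore_r", "rich_guiraud_r",
                                 "rich_herdan_c")}
    counts = Counter(t.lower() for t in tokens)
    v = len(counts)
    v1 = sum(1 for c in counts.values() if c == 1)

    ttr = v / n
    if n <= MATTR_WINDOW:
        mattr = ttr
    else:
        low = [t.lower() for t in tokens]
        mattr = float(np.mean([
            len(set(low[i:i + MATTR_WINDOW])) / MATTR_WINDOW
            for i in range(n - MATTR_WINDOW + 1)]))
    brunet = n ** (v ** BRUNET_EXPONENT)
    denom = 1.0 - v1 / v
    honore = 100.0 * math.log(n) / (denom if denom > 0 else HONORE_EPS)
    guiraud = v / math.sqrt(n)
    herdan = math.log(v) / math.log(n) if n > 1 else 1.0
    return {"rich_ttr": ttr, "rich_mattr": mattr, "rich_brunet_w": brunet,
            "rich_honore_r": honore, "rich_guiraud_r": guiraud,
            "rich_herdan_c": herdan}


# ---------------------------------------------------------------------------
# Coherence (15 + 5)
# ---------------------------------------------------------------------------

def coherence_features(doc: TranscriptDoc, emb) -> dict[str, float]:
    """Local coherence over consecutive-utterance embedding similarity and
    pairwise utterance-distance statistics (20 features).

    Utterance vectors are means of token vectors; utterances with no
    embeddable token are skipped.  "Similarity below threshold 0" is read
    literally as negative cosine similarity.
    """
    names = ([f"cohere_sim_lag1_{s}" for s in _STATS5]
             + [f"cohere_dist_lag1_{s}" for s in _STATS5]
             + [f"cohere_dist_lag2_{s}" for s in _STATS5]
             + ["uttdist_frac_below_0.5", "uttdist_frac_below_0.3",
                "uttdist_frac_below_0", "uttdist_avg_dist",
                "uttdist_min_dist"])
    vecs = [v for v in (embed_utterance(u.tokens, emb)
                        for u in doc.utterances) if v is not None]
    if len(vecs) < 2:
        return {n: NAN for n in names}
    out: dict[str, float] = {}
    sims1 = [cosine_similarity(a, b) for a, b in zip(vecs, vecs[1:])]
    out.update({f"cohere_sim_lag1_{k}": v
                for k, v in _series_stats(sims1).items()})
    out.update({f"cohere_dist_lag1_{k}": v
                for k, v in _series_stats([1 - s for s in sims1]).items()})
    dists2 = ([1 - cosine_similarity(a, b) for a, b in zip(vecs, vecs[2:])]
              if len(vecs) >= 3 else [])
    out.update({f"cohere_dist_lag2_{k}": v
                for k, v in _series_stats(dists2).items()})

    pair_sims = [cosine_similarity(vecs[i], vecs[j])
                 for i in range(len(vecs)) for j in range(i + 1, len(vecs))]
    m = len(pair_sims)
    out["uttdist_frac_below_0.5"] = sum(s < 0.5 for s in pair_sims) / m
    out["uttdist_frac_below_0.3"] = sum(s < 0.3 for s in pair_sims) / m
    out["uttdist_frac_below_0"] = sum(s < 0.0 for s in pair_sims) / m
    out["uttdist_avg_dist"] = float(np.mean([1 - s for s in pair_sims]))
    out["uttdist_min_dist"] = float(min(1 - s for s in pair_sims))
    return out


# ---------------------------------------------------------------------------
# Speech graph (13)
# ---------------------------------------------------------------------------

GRAPH_FEATURE_NAMES = (
    "graph_nodes", "graph_edges", "graph_repeated_edges",
    "graph_self_loops_L1", "graph_cycles_L2", "graph_cycles_L3",
    "graph_largest_cc", "graph_largest_scc", "graph_density",
    "graph_diameter", "graph_avg_shortest_path", "graph_mean_total_degree",
    "graph_transitivity",
)


def build_speech_graph(utterance_tokens: list[list[str]]) -> nx.MultiDiGraph:
    """Directed multigraph: one node per word type, one edge per consecutive
    token pair within an utterance (edges do not cross utterances)."""
    g = nx.MultiDiGraph()
    for toks in utterance_tokens:
        low = [t.lower() for t in toks]
        g.add_nodes_from(low)
        g.add_edges_from(zip(low, low[1:]))
    return g


def speech_graph_features(utterance_tokens: list[list[str]]) -> dict[str, float]:
    """The 13 word-adjacency graph statistics.

    Cycle counts follow speech-graph conventions: L1 = distinct self-looping
    nodes, L2 = mutually-linked node pairs, L3 = directed 3-cycles on the
    simple digraph (self-loops excluded).  Path statistics are computed on
    the undirected view of the largest weakly connected component; a
    single-node graph reports 0 for them by convention.
    """
    g = build_speech_graph(utterance_tokens)
    if g.number_of_nodes() == 0:
        return {n: NAN for n in GRAPH_FEATURE_NAMES}
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    mult = Counter((u, v) for u, v, _ in g.edges(keys=True))
    repeated = sum(1 for c in mult.values() if c >= 2)
    l1 = sum(1 for (u, v) in mult if u == v)
    simple_pairs = {(u, v) for (u, v) in mult if u != v}
    l2 = sum(1 for (u, v) in simple_pairs if (v, u) in simple_pairs and u < v)
    # directed triangles via the binary adjacency matrix
    order = sorted(g.nodes())
    idx = {w: i for i, w in enumerate(order)}
    a = np.zeros((n_nodes, n_nodes))
    for (u, v) in simple_pairs:
        a[idx[u], idx[v]] = 1
    l3 = int(round(np.trace(a @ a @ a) / 3))

    und = nx.Graph()
    und.add_nodes_from(g.nodes())
    und.add_edges_from(simple_pairs)
    comps = list(nx.connected_components(und))
    largest_cc = max(len(c) for c in comps)
    simple_di = nx.DiGraph()
    simple_di.add_nodes_from(g.nodes())
    simple_di.add_edges_from(simple_pairs)
    largest_scc = max(
        len(c) for c in nx.strongly_connected_components(simple_di))
    density = (len(simple_pairs) / (n_nodes * (n_nodes - 1))
               if n_nodes > 1 else 0.0)
    big = und.subgraph(max(comps, key=len))
    if big.number_of_nodes() > 1:
        diam = nx.diameter(big)
        aspl = nx.average_shortest_path_length(big)
    else:
        diam, aspl = 0.0, 0.0
    mean_deg = 2.0 * n_edges / n_nodes
    trans = nx.transitivity(und)
    return dict(zip(GRAPH_FEATURE_NAMES, map(float, (
        n_nodes, n_edges, repeated, l1, l2, l3, largest_cc, largest_scc,
        density, diam, aspl, mean_deg, trans))))


# ---------------------------------------------------------------------------
# Norms, invalid words, cohesion, rate (12 + 9 + 1 + 1 + 2)
# ---------------------------------------------------------------------------

def misc_lexical_features(tagged: PosTaggedDoc, norms: NormLexicon,
                          wordlist: frozenset[str],
                          audio_duration: float | None = None,
                          speech_duration: float | None = None
                          ) -> dict[str, float]:
    """Lexical/sentiment norm means, non-dictionary-word proportion,
    tense-switch cohesion and speaking-rate ratios (25 features)."""
    out: dict[str, float] = {}
    toks = tagged.tokens
    nouns = [t for t in toks if t.tag in NOUN_TAGS]
    verbs = [t for t in toks if t.tag in VERB_TAGS]
    types = list({t.lemma: t for t in toks}.values())

    for norm in ("imageability", "aoa", "familiarity"):
        for scope, group in (("all", toks), ("nouns", nouns),
                             ("verbs", verbs), ("types", types)):
            vals = [v for v in (norms.lookup(t.lemma, norm) for t in group)
                    if v is not None]
            out[f"norm_{norm}_{scope}"] = float(np.mean(vals)) if vals else NAN
    for norm in ("valence", "arousal", "dominance"):
        for scope, group in (("all", toks), ("nouns", nouns),
                             ("verbs", verbs)):
            vals = [v for v in (norms.lookup(t.lemma, norm) for t in group)
                    if v is not None]
            out[f"sent_{norm}_{scope}"] = float(np.mean(vals)) if vals else NAN

    n = len(toks)
    out["invalid_prop_non_dictionary"] = (
        sum(t.word not in wordlist for t in toks) / n if n else NAN)

    tenses = []
    for utt in tagged.utterances:
        tense = None
        for t in utt:
            if t.tag in PAST_TAGS:
                tense = "past"
                break
            if t.tag in PRESENT_TAGS:
                tense = "present"
                break
        tenses.append(tense)
    defined = [t for t in tenses if t is not None]
    switches = sum(1 for a, b in zip(defined, defined[1:]) if a != b)
    n_utt = len(tagged.utterances)
    out["cohesion_tense_switch_rate"] = switches / n_utt if n_utt else NAN

    syllables = sum(count_syllables(t.word) for t in toks)
    out["rate_words_per_sec_audio"] = (
        n / audio_duration if audio_duration and audio_duration > 0 else NAN)
    out["rate_syllables_per_sec_speech"] = (
        syllables / speech_duration
        if speech_duration and speech_duration > 0 else NAN)
    return out
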