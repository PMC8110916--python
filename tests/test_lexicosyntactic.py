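"""Lexico-syntactic features against hand counts and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from adspeech.chat_io import TranscriptDoc, Utterance
from adspeech.embeddings import HashEmbedding, cosine_similarity, embed_utterance
from adspeech.lexicosyntactic import (GRAPH_FEATURE_NAMES, coherence_features,
                                      lexical_richness, misc_lexical_features,
                                      pos_features, production_rule_features,
                                      speech_graph_features,
                                      syntactic_complexity_features)
from adspeech.lexicons import load_norms, load_wordlist
from adspeech.tagging import (LexiconTagger, ParseTree, PosTaggedDoc,
                              TaggedToken)
from tests.conftest import make_doc


def tok(word, tag, lemma=None):
    from adspeech.tagging import PTB_TO_UPOS
    return TaggedToken(word=word, tag=tag, upos=PTB_TO_UPOS.get(tag, "X"),
                       lemma=lemma or word)


# ---------------------------------------------------------------------------
# POS proportions
# ---------------------------------------------------------------------------

class TestPosFeatures:
    def test_single_tag_document(self):
        doc = PosTaggedDoc([[tok("cookie", "NN")] * 5])
        out = pos_features(doc)
        assert out["pos_prop_NN"] == 1.0
        assert out["pos_prop_VB"] == 0.0
        assert out["upos_prop_NOUN"] == 1.0

    def test_hand_counted_fixture(self):
        # 20 gold-tagged tokens: 8 NN, 4 VBZ, 3 DT, 3 PRP, 2 JJ
        toks = ([tok("cookie", "NN")] * 8 + [tok("falls", "VBZ", "fall")] * 4
                + [tok("the", "DT")] * 3 + [tok("he", "PRP")] * 3
                + [tok("big", "JJ")] * 2)
        out = pos_features(PosTaggedDoc([toks]))
        assert out["pos_prop_NN"] == 8 / 20
        assert out["pos_prop_VBZ"] == 4 / 20
        assert out["pos_prop_DT"] == 3 / 20
        assert out["ratio_nouns_nouns_verbs"] == 8 / 12
        assert out["ratio_nouns_verbs"] == 8 / 4
        assert out["ratio_pronouns_pronouns_nouns"] == 3 / 11
        # avg word length: (6*8 + 5*4 + 3*3 + 2*3 + 3*2) / 20
        assert out["len_avg_word_length"] == pytest.approx(
            (6 * 8 + 5 * 4 + 3 * 3 + 2 * 3 + 3 * 2) / 20)

    def test_proportions_bounded(self):
        doc = PosTaggedDoc([[tok("a", "DT"), tok("cookie", "NN"),
                             tok("falls", "VBZ", "fall")]])
        out = pos_features(doc)
        props = [v for k, v in out.items() if "prop" in k]
        assert all(0.0 <= v <= 1.0 for v in props)

    def test_zero_tokens_all_missing(self):
        out = pos_features(PosTaggedDoc([[]]))
        assert all(math.isnan(v) for v in out.values())


# ---------------------------------------------------------------------------
# Production rules / phrasal ratios
# ---------------------------------------------------------------------------

class TestProductionRules:
    def test_hand_expanded_single_tree(self):
        tree = ParseTree.from_bracketed(
            "(S (NP (DT the) (NN boy)) (VP (VBZ falls)))")
        out = production_rule_features([tree])
        # 3 productions: S->NP VP, NP->DT NN, VP->VBZ
        assert out["prod_prop_S_NP_VP"] == pytest.approx(1 / 3)
        assert out["prod_prop_NP_DT_NN"] == pytest.approx(1 / 3)
        assert out["prod_prop_VP_VBZ"] == pytest.approx(1 / 3)
        assert out["phr_NP_mean_len"] == 2.0
        assert out["phr_NP_rate"] == 1.0

    def test_no_pp_gives_zero_prop_missing_len(self):
        tree = ParseTree.from_bracketed("(S (NP (NN water)))")
        out = production_rule_features([tree])
        assert out["phr_PP_prop"] == 0.0
        assert math.isnan(out["phr_PP_mean_len"])

    def test_empty_tree_list_missing(self):
        out = production_rule_features([])
        assert all(math.isnan(v) for v in out.values())

    def test_proportions_sum_at_most_one(self):
        trees = [ParseTree.from_bracketed(
            "(S (NP (DT the) (NN boy)) (VP (VBZ falls) (PP (IN on) "
            "(NP (DT the) (NN stool)))))")]
        out = production_rule_features(trees)
        total = sum(v for k, v in out.items() if k.startswith("prod_prop_"))
        assert 0.0 < total <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# Lexical richness (independent brute-force oracle)
# ---------------------------------------------------------------------------

def richness_oracle(tokens):
    """Plain-dict recomputation of the richness indices."""
    n = len(tokens)
    counts = {}
    for t in tokens:
        counts[t.lower()] = counts.get(t.lower(), 0) + 1
    v = len(counts)
    v1 = sum(1 for c in counts.values() if c == 1)
    ttr = v / n
    brunet = n ** (v ** -0.165)
    if v1 == v:
        honore = 100.0 * math.log(n) / 1e-3
    else:
        honore = 100.0 * math.log(n) / (1.0 - v1 / v)
    return ttr, brunet, honore, v / math.sqrt(n)


class TestLexicalRichness:
    def test_abcb_example(self):
        out = lexical_richness(["a", "b", "c", "b"])
        assert out["rich_ttr"] == 0.75
        assert out["rich_honore_r"] == pytest.approx(
            100 * math.log(4) / (1 - 2 / 3))

    def test_single_token_brunet_identity(self):
        assert lexical_richness(["water"])["rich_brunet_w"] == 1.0

    def test_all_distinct_guard_not_infinite(self):
        out = lexical_richness(["a", "b", "c"])
        assert math.isfinite(out["rich_honore_r"])
        assert out["rich_honore_r"] == pytest.approx(
            100 * math.log(3) / 1e-3)

    @given(st.lists(st.sampled_from("abcdefgh"), min_size=1, max_size=60))
    def test_matches_brute_force_oracle(self, tokens):
        out = lexical_richness(tokens)
        ttr, brunet, honore, guiraud = richness_oracle(tokens)
        assert out["rich_ttr"] == pytest.approx(ttr)
        assert out["rich_brunet_w"] == pytest.approx(brunet)
        assert out["rich_honore_r"] == pytest.approx(honore)
        assert out["rich_guiraud_r"] == pytest.approx(guiraud)

    def test_empty_tokens_missing(self):
        assert all(math.isnan(v) for v in lexical_richness([]).values())


# ---------------------------------------------------------------------------
# Speech graph (adjacency-list brute-force oracle, no networkx)
# ---------------------------------------------------------------------------

def graph_oracle(utterance_tokens):
    edges = []
    nodes = set()
    for toks in utterance_tokens:
        low = [t.lower() for t in toks]
        nodes |= set(low)
        edges += list(zip(low, low[1:]))
    n = len(nodes)
    mult = {}
    for e in edges:
        mult[e] = mult.get(e, 0) + 1
    repeated = sum(1 for c in mult.values() if c >= 2)
    l1 = sum(1 for (u, v) in mult if u == v)
    simple = {(u, v) for (u, v) in mult if u != v}
    l2 = sum(1 for (u, v) in simple if (v, u) in simple and u < v)
    l3 = 0
    for a in nodes:
        for b in nodes:
            for c in nodes:
                if (a, b) in simple and (b, c) in simple and (c, a) in simple:
                    l3 += 1
    l3 //= 3
    # undirected reachability by repeated scanning
    und = {frozenset(e) for e in simple}
    adj = {x: set() for x in nodes}
    for e in und:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)

    def component(start):
        seen, stack = {start}, [start]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen

    comps, left = [], set(nodes)
    while left:
        c = component(next(iter(left)))
        comps.append(c)
        left -= c
    largest_cc = max(len(c) for c in comps)

    dadj = {x: set() for x in nodes}
    for (u, v) in simple:
        dadj[u].add(v)

    def reach(start):
        seen, stack = {start}, [start]
        while stack:
            x = stack.pop()
            for y in dadj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen

    reaches = {x: reach(x) for x in nodes}
    largest_scc = max(
        sum(1 for y in nodes if x in reaches[y] and y in reaches[x])
        for x in nodes)
    density = len(simple) / (n * (n - 1)) if n > 1 else 0.0

    big = max(comps, key=len)
    if len(big) > 1:
        dists = []
        diam = 0
        for s in big:
            level = {s: 0}
            frontier = [s]
            while frontier:
                nxt = []
                for x in frontier:
                    for y in adj[x]:
                        if y not in level:
                            level[y] = level[x] + 1
                            nxt.append(y)
                frontier = nxt
            for t2, d in level.items():
                if t2 != s:
                    dists.append(d)
                    diam = max(diam, d)
        aspl = sum(dists) / len(dists)
    else:
        diam, aspl = 0.0, 0.0
    mean_deg = 2 * len(edges) / n
    # transitivity = 3 * triangles / triads on the undirected simple graph
    tri = 0
    for u in nodes:
        for v in adj[u]:
            for w in adj[v]:
                if w != u and w in adj[u]:
                    tri += 1
    triads = sum(len(adj[u]) * (len(adj[u]) - 1) for u in nodes)
    trans = tri / triads if triads else 0.0
    return dict(zip(GRAPH_FEATURE_NAMES, map(float, (
        n, len(edges), repeated, l1, l2, l3, largest_cc, largest_scc,
        density, diam, aspl, mean_deg, trans))))


class TestSpeechGraph:
    def test_two_word_utterance(self):
        out = speech_graph_features([["the", "boy"]])
        assert out["graph_nodes"] == 2
        assert out["graph_edges"] == 1
        assert out["graph_self_loops_L1"] == 0

    def test_immediate_repetition_self_loop(self):
        out = speech_graph_features([["the", "the"]])
        assert out["graph_self_loops_L1"] == 1

    def test_single_node_path_conventions(self):
        out = speech_graph_features([["water"]])
        assert out["graph_diameter"] == 0.0
        assert out["graph_avg_shortest_path"] == 0.0
        assert out["graph_largest_scc"] == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_random_sequences_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        words = list("abcdefgh")
        n_utt = int(rng.integers(1, 4))
        utts = [[words[i] for i in
                 rng.integers(0, len(words), rng.integers(2, 20))]
                for _ in range(n_utt)]
        got = speech_graph_features(utts)
        want = graph_oracle(utts)
        for name in GRAPH_FEATURE_NAMES:
            assert got[name] == pytest.approx(want[name]), name


# ---------------------------------------------------------------------------
# Coherence
# ---------------------------------------------------------------------------

class TestCoherence:
    def test_identical_utterances_zero_distance(self):
        doc = make_doc([["water", "overflowing"]] * 3)
        out = coherence_features(doc, HashEmbedding(dim=16, seed=1))
        assert out["cohere_dist_lag1_mean"] == pytest.approx(0.0, abs=1e-12)
        assert out["uttdist_avg_dist"] == pytest.approx(0.0, abs=1e-12)
        # similarity of identical vectors is 1, never below any threshold
        assert out["uttdist_frac_below_0.5"] == 0.0
        assert out["uttdist_frac_below_0"] == 0.0

    def test_single_utterance_missing(self):
        doc = make_doc([["water"]])
        out = coherence_features(doc, HashEmbedding(dim=16, seed=1))
        assert all(math.isnan(v) for v in out.values())

    def test_orthogonal_embeddings_distance_one(self):
        class AxisEmb:
            def embed_tokens(self, tokens):
                v = np.zeros(3)
                v[hash(tokens[0]) % 2] = 1.0
                return v

        doc = make_doc([["aa"], ["ab"]])
        emb = AxisEmb()
        v1 = emb.embed_tokens(["aa"])
        v2 = emb.embed_tokens(["ab"])
        out = coherence_features(doc, emb)
        expected = 1 - cosine_similarity(v1, v2)
        assert out["cohere_dist_lag1_mean"] == pytest.approx(expected)

    def test_padding_with_empty_utterances_invariant(self):
        base = [["water", "overflowing"], ["the", "boy", "falls"]]
        emb = HashEmbedding(dim=16, seed=3)
        a = coherence_features(make_doc(base), emb)
        b = coherence_features(make_doc(base + [[]]), emb)
        assert a == b

    def test_pairwise_stats_match_brute_force(self):
        rng = np.random.default_rng(7)
        words = ["cookie", "water", "boy", "girl", "stool", "jar"]
        utts = [[words[i] for i in rng.integers(0, 6, 4)] for _ in range(5)]
        emb = HashEmbedding(dim=24, seed=9)
        out = coherence_features(make_doc(utts), emb)
        vecs = [embed_utterance(u, emb) for u in utts]
        sims = [cosine_similarity(vecs[i], vecs[j])
                for i in range(5) for j in range(i + 1, 5)]
        assert out["uttdist_avg_dist"] == pytest.approx(
            np.mean([1 - s for s in sims]))
        assert out["uttdist_min_dist"] == pytest.approx(
            min(1 - s for s in sims))
        assert out["uttdist_frac_below_0.3"] == pytest.approx(
            np.mean([s < 0.3 for s in sims]))


# ---------------------------------------------------------------------------
# Norms / invalid words / cohesion / syntactic complexity
# ---------------------------------------------------------------------------

class TestMiscLexical:
    def test_all_in_dictionary_zero_invalid(self, resources):
        tagger = LexiconTagger()
        doc = make_doc([["the", "boy", "falls"]])
        out = misc_lexical_features(tagger.tag(doc), resources.norms,
                                    resources.wordlist)
        assert out["invalid_prop_non_dictionary"] == 0.0

    def test_unknown_word_counted_invalid(self, resources):
        tagger = LexiconTagger()
        doc = make_doc([["the", "flimble", "falls", "zzyzx"]])
        out = misc_lexical_features(tagger.tag(doc), resources.norms,
                                    resources.wordlist)
        assert out["invalid_prop_non_dictionary"] == pytest.approx(2 / 4)

    def test_single_utterance_no_tense_switch(self, resources):
        tagger = LexiconTagger()
        doc = make_doc([["the", "boy", "falls"]])
        out = misc_lexical_features(tagger.tag(doc), resources.norms,
                                    resources.wordlist)
        assert out["cohesion_tense_switch_rate"] == 0.0

    def test_tense_switch_counted(self, resources):
        tagger = LexiconTagger()
        doc = make_doc([["the", "boy", "falls"], ["the", "boy", "fell"],
                        ["she", "sees", "him"]])
        out = misc_lexical_features(tagger.tag(doc), resources.norms,
                                    resources.wordlist)
        assert out["cohesion_tense_switch_rate"] == pytest.approx(2 / 3)

    def test_rate_features_need_duration(self, resources):
        tagger = LexiconTagger()
        doc = make_doc([["the", "boy"]])
        out = misc_lexical_features(tagger.tag(doc), resources.norms,
                                    resources.wordlist, audio_duration=2.0,
                                    speech_duration=1.0)
        assert out["rate_words_per_sec_audio"] == 1.0
        out2 = misc_lexical_features(tagger.tag(doc), resources.norms,
                                     resources.wordlist)
        assert math.isnan(out2["rate_words_per_sec_audio"])

    def test_norm_means_over_lexicon_words(self):
        norms = load_norms()
        tagger = LexiconTagger()
        doc = make_doc([["cookie", "water"]])
        out = misc_lexical_features(tagger.tag(doc), norms, load_wordlist())
        want = np.mean([norms.lookup("cookie", "imageability"),
                        norms.lookup("water", "imageability")])
        assert out["norm_imageability_all"] == pytest.approx(want)


class TestSyntacticComplexity:
    def test_emits_36_features_and_depth(self):
        tagger = LexiconTagger()
        from adspeech.tagging import ChunkParser
        doc = make_doc([["the", "boy", "falls"], ["she", "sees", "him"]])
        tagged = tagger.tag(doc)
        trees = ChunkParser().parse(tagged)
        out = syntactic_complexity_features(tagged, trees)
        assert len(out) == 36
        assert out["sc_utt_len_mean"] == 3.0
        assert out["sc_utt_len_total"] == 6.0
        assert all(math.isfinite(v) for v in out.values())

    def test_empty_doc_missing(self):
        out = syntactic_complexity_features(PosTaggedDoc([]), [])
        assert len(out) == 36
        assert all(math.isnan(v) for v in out.values())


class TestCaseInvariance:
    def test_richness_case_insensitive(self):
        a = lexical_richness(["The", "the", "BOY"])
        b = lexical_richness(["the", "the", "boy"])
        assert a == b

    def test_graph_case_insensitive(self):
        a = speech_graph_features([["The", "boy", "THE"]])
        b = speech_graph_features([["the", "boy", "the"]])
        assert a == b
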