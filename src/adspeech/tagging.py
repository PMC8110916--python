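"""Pluggable tagging, lemmatization and constituency chunking.

The feature battery needs Penn-Treebank-style fine tags, universal coarse
tags, lemmas and bracketed constituency trees.  Taggers and parsers are
pluggable: any object with the :class:`Tagger` / :class:`Parser` interface
may be supplied, and test fixtures carry gold tags and trees.  The default
implementations are deterministic rule/lexicon systems with no external
model: a closed-class lexicon plus suffix heuristics for tagging, and a
regular NP/VP/PP chunk grammar for parsing.  They are intentionally simple
English-only approximations — adequate for the controlled vocabulary of
synthetic picture descriptions, and replaceable for naturalistic text.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Protocol

from .chat_io import TranscriptDoc

# ---------------------------------------------------------------------------
# Fine (PTB) -> coarse (universal) tag map
# ---------------------------------------------------------------------------

PTB_TO_UPOS = {
    "CC": "CCONJ", "CD": "NUM", "DT": "DET", "EX": "PRON", "FW": "X",
    "IN": "ADP", "JJ": "ADJ", "JJR": "ADJ", "JJS": "ADJ", "LS": "X",
    "MD": "AUX", "NN": "NOUN", "NNS": "NOUN", "NNP": "PROPN",
    "NNPS": "PROPN", "PDT": "DET", "POS": "PART", "PRP": "PRON",
    "PRP$": "PRON", "RB": "ADV", "RBR": "ADV", "RBS": "ADV", "RP": "ADP",
    "SYM": "SYM", "TO": "PART", "UH": "INTJ", "VB": "VERB", "VBD": "VERB",
    "VBG": "VERB", "VBN": "VERB", "VBP": "VERB", "VBZ": "VERB",
    "WDT": "DET", "WP": "PRON", "WP$": "PRON", "WRB": "ADV",
}

NOUN_TAGS = {"NN", "NNS", "NNP", "NNPS"}
VERB_TAGS = {"VB", "VBD", "VBG", "VBN", "VBP", "VBZ"}
PRONOUN_TAGS = {"PRP", "PRP$"}
PAST_TAGS = {"VBD", "VBN"}
PRESENT_TAGS = {"VBZ", "VBP", "VBG"}
FUNCTION_TAGS = {"DT", "IN", "CC", "TO", "MD", "PRP", "PRP$", "WDT", "WP",
                 "WP$", "WRB", "EX", "PDT", "POS", "RP", "UH"}

# ---------------------------------------------------------------------------
# Lexicons for the default tagger
# ---------------------------------------------------------------------------

_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those", "another",
                "some", "any", "no", "every", "each"}
DEMONSTRATIVES = {"this", "that", "these", "those"}
_PRP = {"he", "she", "it", "they", "i", "you", "we", "him", "them", "me",
        "us", "himself", "herself", "itself", "themselves"}
_PRP_POS = {"his", "her", "their", "my", "your", "its", "our"}
_PREPOSITIONS = {"in", "on", "at", "from", "with", "of", "by", "for",
                 "about", "into", "over", "under", "near", "behind",
                 "beside", "through", "outside", "inside", "while",
                 "because", "if", "as"}
_CONJUNCTIONS = {"and", "but", "or", "so", "nor", "yet"}
_MODALS = {"will", "can", "could", "would", "should", "may", "might",
           "must", "shall"}
_ADVERBS = {"very", "not", "just", "here", "now", "then", "also", "too",
            "again", "away", "down", "up", "out", "almost", "really",
            "quite", "maybe", "perhaps", "soon", "still", "always",
            "never", "often", "there"}
# "there" defaults to EX sentence-initially; handled in the tagger
_INTERJECTIONS = {"oh", "well", "um", "uh", "hm", "yeah", "yes", "no"}
_NUMBERS = {"one", "two", "three", "four", "five", "six", "seven", "eight",
            "nine", "ten"}

#: base forms of verbs known to the default tagger
VERB_BASES = {
    "be", "have", "do", "go", "take", "get", "make", "give", "come", "want",
    "see", "look", "stand", "fall", "wash", "dry", "spill", "overflow",
    "reach", "ask", "steal", "run", "eat", "hand", "grab", "wobble", "tip",
    "climb", "watch", "notice", "say", "tell", "think", "know", "try",
    "seem", "happen", "wipe", "hold", "pour", "drip", "slip", "laugh",
    "smile", "point", "help", "finish", "start", "keep", "put", "let",
    "like", "need", "use", "play", "work", "turn", "open", "close", "care",
}

_IRREGULAR_VERBS = {
    # form -> (tag, lemma)
    "is": ("VBZ", "be"), "are": ("VBP", "be"), "am": ("VBP", "be"),
    "was": ("VBD", "be"), "were": ("VBD", "be"), "been": ("VBN", "be"),
    "being": ("VBG", "be"), "be": ("VB", "be"),
    "has": ("VBZ", "have"), "have": ("VBP", "have"), "had": ("VBD", "have"),
    "having": ("VBG", "have"),
    "does": ("VBZ", "do"), "do": ("VBP", "do"), "did": ("VBD", "do"),
    "done": ("VBN", "do"), "doing": ("VBG", "do"),
    "goes": ("VBZ", "go"), "went": ("VBD", "go"), "gone": ("VBN", "go"),
    "took": ("VBD", "take"), "taken": ("VBN", "take"),
    "got": ("VBD", "get"), "gotten": ("VBN", "get"),
    "made": ("VBD", "make"), "gave": ("VBD", "give"),
    "came": ("VBD", "come"), "saw": ("VBD", "see"), "seen": ("VBN", "see"),
    "stood": ("VBD", "stand"), "fell": ("VBD", "fall"),
    "fallen": ("VBN", "fall"), "stole": ("VBD", "steal"),
    "stolen": ("VBN", "steal"), "ran": ("VBD", "run"), "ate": ("VBD", "eat"),
    "said": ("VBD", "say"), "told": ("VBD", "tell"),
    "thought": ("VBD", "think"), "knew": ("VBD", "know"),
    "kept": ("VBD", "keep"), "put": ("VBD", "put"), "let": ("VBD", "let"),
}

_ADJECTIVES = {"little", "big", "small", "tall", "old", "young", "busy",
               "wet", "full", "empty", "high", "open", "nice", "good",
               "bad", "happy", "quiet", "messy", "sunny", "whole", "other",
               "ready", "careless", "unsteady", "oblivious", "distracted",
               "unconcerned", "indifferent", "three-legged",
               "hot", "dim", "sad", "low"}

_IRREGULAR_PLURALS = {"dishes": "dish", "children": "child", "women": "woman",
                      "feet": "foot", "men": "man", "cookies": "cookie",
                      "curtains": "curtain", "glasses": "glass"}

_LEMMA_EXCEPTIONS = {
    "taking": "take", "making": "make", "giving": "give", "coming": "come",
    "having": "have", "using": "use", "wobbling": "wobble",
    "tipping": "tip", "spilling": "spill", "slipping": "slip",
    "running": "run", "grabbing": "grab", "wiping": "wipe",
    "dripping": "drip", "putting": "put", "smiling": "smile",
    "climbing": "climb", "noticing": "notice",
}

_SYLLABLE_EXCEPTIONS = {"cookie": 2, "people": 2, "little": 2, "the": 1,
                        "overflowing": 4, "area": 3, "idea": 3, "quiet": 2,
                        "going": 2, "doing": 2, "being": 2}


def count_syllables(word: str) -> int:
    """Vowel-group heuristic with a small exception list; minimum 1."""
    w = word.lower()
    if w in _SYLLABLE_EXCEPTIONS:
        return _SYLLABLE_EXCEPTIONS[w]
    groups = len(re.findall(r"[aeiouy]+", w))
    if w.endswith("e") and not w.endswith(("le", "ee", "ye")) and groups > 1:
        groups -= 1
    return max(1, groups)


# ---------------------------------------------------------------------------
# Types and interfaces
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TaggedToken:
    word: str
    tag: str        # fine, PTB-style
    upos: str       # coarse, universal
    lemma: str


@dataclasses.dataclass
class PosTaggedDoc:
    utterances: list[list[TaggedToken]]

    @property
    def tokens(self) -> list[TaggedToken]:
        return [t for u in self.utterances for t in u]


@dataclasses.dataclass
class ParseTree:
    """Bracketed constituency tree; leaves are (tag, word) pre-terminals."""

    label: str
    children: list["ParseTree"] = dataclasses.field(default_factory=list)
    word: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.word is not None

    def productions(self) -> list[str]:
        """All internal-node expansions as ``LHS->RHS`` strings
        (pre-terminal expansions to words are excluded)."""
        out = []
        if not self.is_leaf and self.children:
            rhs = " ".join(c.label for c in self.children)
            out.append(f"{self.label}->{rhs}")
            for c in self.children:
                out.extend(c.productions())
        return out

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.word]
        return [w for c in self.children for w in c.leaves()]

    def depth(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + max((c.depth() for c in self.children), default=0)

    def n_nodes(self) -> int:
        return 1 + sum(c.n_nodes() for c in self.children)

    def subtrees(self, label: str | None = None):
        if not self.is_leaf:
            if label is None or self.label == label:
                yield self
            for c in self.children:
                yield from c.subtrees(label)

    def to_bracketed(self) -> str:
        if self.is_leaf:
            return f"({self.label} {self.word})"
        return f"({self.label} " + " ".join(
            c.to_bracketed() for c in self.children) + ")"

    @classmethod
    def from_bracketed(cls, s: str) -> "ParseTree":
        tokens = re.findall(r"\(|\)|[^()\s]+", s)
        pos = 0

        def parse() -> "ParseTree":
            nonlocal pos
            assert tokens[pos] == "(", f"expected '(' at {pos}"
            pos += 1
            label = tokens[pos]
            pos += 1
            children: list[ParseTree] = []
            word = None
            while tokens[pos] != ")":
                if tokens[pos] == "(":
                    children.append(parse())
                else:
                    word = tokens[pos]
                    pos += 1
            pos += 1
            return cls(label=label, children=children, word=word)

        return parse()


class Tagger(Protocol):
    def tag(self, doc: TranscriptDoc) -> PosTaggedDoc: ...


class Parser(Protocol):
    def parse(self, tagged: PosTaggedDoc) -> list[ParseTree]: ...


# ---------------------------------------------------------------------------
# Default rule/lexicon tagger
# ---------------------------------------------------------------------------

class LexiconTagger:
    """Deterministic closed-class-lexicon + suffix-rule tagger."""

    def tag_tokens(self, tokens: list[str]) -> list[TaggedToken]:
        out: list[TaggedToken] = []
        for i, raw in enumerate(tokens):
            w = raw.lower()
            tag, lemma = self._tag_word(w, i, tokens, out)
            out.append(TaggedToken(word=w, tag=tag,
                                   upos=PTB_TO_UPOS.get(tag, "X"),
                                   lemma=lemma))
        return out

    def _tag_word(self, w, i, tokens, done):
        if w in _IRREGULAR_VERBS:
            return _IRREGULAR_VERBS[w]
        if w == "there":
            # existential sentence-initially or before a be-verb, else adverb
            nxt = tokens[i + 1].lower() if i + 1 < len(tokens) else ""
            if i == 0 or nxt in ("is", "are", "was", "were"):
                return "EX", "there"
            return "RB", "there"
        if w == "to":
            return "TO", "to"
        if w in _DETERMINERS:
            return "DT", w
        if w in _PRP:
            return "PRP", w
        if w in _PRP_POS:
            return "PRP$", w
        if w in _MODALS:
            return "MD", w
        if w in _CONJUNCTIONS:
            return "CC", w
        if w in _PREPOSITIONS:
            return "IN", w
        if w in _INTERJECTIONS and i == 0:
            return "UH", w
        if w in _NUMBERS or w.isdigit():
            return "CD", w
        if w in _ADVERBS or (w.endswith("ly") and len(w) > 3):
            return "RB", w[:-2] if w.endswith("ly") and w[:-2] in _ADJECTIVES else w
        if w in _ADJECTIVES:
            return "JJ", w
        if w in VERB_BASES:
            # base form after modal/"to", else finite present plural
            prev = done[-1].tag if done else ""
            return ("VB", w) if prev in ("MD", "TO") else ("VBP", w)
        if w in ("something", "everything", "anything", "nothing",
                 "morning", "evening", "thing", "ceiling"):
            return "NN", w
        # inflected verb forms by suffix on a known base
        if w.endswith("ing"):
            base = _LEMMA_EXCEPTIONS.get(w, w[:-3])
            for cand in (base, base + "e"):
                if cand in VERB_BASES:
                    return "VBG", cand
            return "VBG", base
        if w.endswith("ed") and len(w) > 3:
            for cand in (w[:-2], w[:-1], w[:-3]):
                if cand in VERB_BASES:
                    return "VBD", cand
            return "VBD", w[:-2]
        if w.endswith("s") and not w.endswith("ss"):
            stem = _IRREGULAR_PLURALS.get(w)
            if stem:
                return "NNS", stem
            for cand in (w[:-1], w[:-2] if w.endswith("es") else None):
                if cand and cand in VERB_BASES:
                    return "VBZ", cand
            stem = w[:-2] + "y" if w.endswith("ies") else (
                w[:-2] if w.endswith("es") and w[:-2].endswith(("sh", "ch", "x")) else w[:-1])
            return "NNS", stem
        return "NN", w

    def tag(self, doc: TranscriptDoc) -> PosTaggedDoc:
        return PosTaggedDoc([self.tag_tokens(u.tokens) for u in doc.utterances])


# ---------------------------------------------------------------------------
# Default chunk parser
# ---------------------------------------------------------------------------

class ChunkParser:
    """Regular NP/VP/PP/ADVP/ADJP chunker producing shallow trees.

    Grammar (greedy, left to right):
      NP   := DT? (JJ|CD)* (NN|NNS)+ | PRP | PRP$ NN(S)? | EX | DT
      ADJP := (RB)? JJ+           (outside an NP)
      ADVP := RB+                 (when not absorbed into a VP)
      VP   := MD? RB? V+ (ADJP | NP | ADVP)? (PP)*  with V in VB..VBZ
      PP   := IN|TO NP
    Unattachable tokens become unary chunks of their own tag.
    """

    def parse_utterance(self, toks: list[TaggedToken]) -> ParseTree:
        i = 0
        chunks: list[ParseTree] = []
        n = len(toks)

        def leaf(t: TaggedToken) -> ParseTree:
            return ParseTree(label=t.tag, word=t.word)

        def try_np(j: int) -> tuple[ParseTree, int] | None:
            kids: list[ParseTree] = []
            k = j
            if k < n and toks[k].tag == "PRP":
                return ParseTree("NP", [leaf(toks[k])]), k + 1
            if k < n and toks[k].tag == "EX":
                return ParseTree("NP", [leaf(toks[k])]), k + 1
            if k < n and toks[k].tag in ("DT", "PRP$"):
                kids.append(leaf(toks[k])); k += 1
            while k < n and toks[k].tag in ("JJ", "CD"):
                kids.append(leaf(toks[k])); k += 1
            head = False
            while k < n and toks[k].tag in ("NN", "NNS"):
                kids.append(leaf(toks[k])); k += 1; head = True
            if head:
                return ParseTree("NP", kids), k
            if len(kids) == 1 and kids[0].label == "DT":
                return ParseTree("NP", kids), k
            return None

        def try_pp(j: int) -> tuple[ParseTree, int] | None:
            if j < n and toks[j].tag in ("IN", "TO"):
                got = try_np(j + 1)
                if got:
                    np_, k = got
                    return ParseTree("PP", [leaf(toks[j]), np_]), k
            return None

        def try_vp(j: int) -> tuple[ParseTree, int] | None:
            kids: list[ParseTree] = []
            k = j
            if k < n and toks[k].tag == "MD":
                kids.append(leaf(toks[k])); k += 1
                if k < n and toks[k].tag == "RB":
                    kids.append(leaf(toks[k])); k += 1
            verbs = 0
            while k < n and toks[k].tag in VERB_TAGS:
                kids.append(leaf(toks[k])); k += 1; verbs += 1
                if verbs == 2:
                    break
            if verbs == 0 and not (kids and k < n and toks[k].tag == "VB"):
                return None
            if k < n and toks[k].tag == "RP":
                kids.append(leaf(toks[k])); k += 1
            got = try_np(k) or try_pp(k)
            if got is None and k < n and toks[k].tag == "JJ":
                adjk = [leaf(toks[k])]
                k += 1
                kids.append(ParseTree("ADJP", adjk))
            elif got is None and k < n and toks[k].tag == "RB":
                kids.append(ParseTree("ADVP", [leaf(toks[k])])); k += 1
            elif got:
                sub, k = got
                kids.append(sub)
                more = try_pp(k)
                if more:
                    sub2, k = more
                    kids.append(sub2)
            return ParseTree("VP", kids), k

        while i < n:
            got = try_pp(i) or try_vp(i) or try_np(i)
            if got:
                sub, i = got
                chunks.append(sub)
                continue
            t = toks[i]
            if t.tag == "RB":
                kids = [leaf(t)]
                i += 1
                while i < n and toks[i].tag == "RB":
                    kids.append(leaf(toks[i])); i += 1
                chunks.append(ParseTree("ADVP", kids))
            elif t.tag == "JJ":
                chunks.append(ParseTree("ADJP", [leaf(t)])); i += 1
            else:
                chunks.append(ParseTree(t.tag, [leaf(t)])); i += 1
        return ParseTree("S", chunks)

    def parse(self, tagged: PosTaggedDoc) -> list[ParseTree]:
        return [self.parse_utterance(u) for u in tagged.utterances]
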