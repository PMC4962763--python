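"""Linguistic preprocessing: sentences, tokens, base forms, PoS, abbreviations.

The recognizers only need light linguistic signal — token boundaries, a verb
test for the species false-positive filter, noun base forms for dictionary
lookup, and full-name/abbreviation pairs.  The shipped ``builtin`` backend is
therefore rule-based and fully deterministic; richer taggers can be plugged
into the backend registry without touching the recognizers.

Abbreviation pairing follows the Schwartz–Hearst long-form/short-form
algorithm: a parenthesized short form is attached to the preceding long form
when every short-form character can be matched left-to-right (right-to-left
during search) inside the long form, with the first character anchored to the
start of a long-form word.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable

from .bioc_io import Passage

logger = logging.getLogger(__name__)

__all__ = [
    "Token",
    "Sentence",
    "AbbrevPair",
    "split_sentences",
    "tokenize_and_tag",
    "extract_abbreviations",
    "lemmatize",
    "register_backend",
]


@dataclass
class Token:
    surface: str
    base: str
    pos: str
    offset: int  # document-level
    length: int

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class Sentence:
    offset: int  # document-level
    length: int
    text: str
    tokens: list[Token] = field(default_factory=list)

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class AbbrevPair:
    full: str
    short: str
    full_span: tuple[int, int]  # (offset, length), document-level
    short_span: tuple[int, int]


# ---------------------------------------------------------------------------
# Sentence splitting

# Dotted tokens that never end a sentence (species-style "E." guarded below).
_NON_FINAL_ABBREV = {
    "i.e", "e.g", "al", "et", "fig", "figs", "vs", "cf", "sp", "spp",
    "approx", "ca", "no", "nos", "dr", "st", "var", "subsp",
}

_BOUNDARY_RE = re.compile(r"[.!?]+")
_NEXT_SENT_RE = re.compile(r"\s+[\"'(\[]?[A-Z0-9]")


def split_sentences(passage: Passage) -> list[Sentence]:
    """Split passage text into sentences with document-level spans.

    Periods after single capital letters ("E. coli") and after common Latin
    or figure abbreviations do not split.  Sentences jointly cover all
    non-whitespace text of the passage.
    """
    text = passage.text
    if not text.strip():
        return []
    breaks: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        if end < len(text) and not _NEXT_SENT_RE.match(text, end):
            continue
        if "." in m.group():
            before = text[: m.start()]
            tail = re.search(r"(\S+)$", before)
            word = tail.group(1).lstrip("([\"'") if tail else ""
            if re.fullmatch(r"[A-Z]", word):  # "E." in "E. coli"
                continue
            if word.lower().rstrip(".") in _NON_FINAL_ABBREV:
                continue
        breaks.append(end)
    if not breaks or breaks[-1] < len(text.rstrip()):
        breaks.append(len(text))
    sentences: list[Sentence] = []
    start = 0
    for end in breaks:
        chunk = text[start:end]
        lead = len(chunk) - len(chunk.lstrip())
        stripped = chunk.strip()
        if stripped:
            sentences.append(
                Sentence(
                    offset=passage.offset + start + lead,
                    length=len(stripped),
                    text=stripped,
                )
            )
        start = end
    return sentences


# ---------------------------------------------------------------------------
# Tokenization, base forms, PoS

# Single capital + period stays one token ("E."), words keep ' and /
# connectors, hyphens separate (so "anti-BACH" exposes "BACH" at a token
# boundary), any other symbol is its own token.
_TOKEN_RE = re.compile(
    r"[A-Za-z]\.(?![A-Za-z0-9])|[A-Za-z0-9]+(?:['/][A-Za-z0-9]+)*|[^\sA-Za-z0-9]"
)

_IRREGULAR_LEMMAS = {
    "mice": "mouse", "men": "man", "women": "woman", "children": "child",
    "feet": "foot", "teeth": "tooth", "larvae": "larva", "fungi": "fungus",
    "bacteria": "bacterium", "flies": "fly", "viruses": "virus",
    "is": "be", "are": "be", "was": "be", "were": "be", "been": "be",
    "being": "be", "am": "be", "has": "have", "had": "have",
    "did": "do", "done": "do", "grew": "grow", "grown": "grow",
    "showed": "show", "shown": "show", "took": "take", "taken": "take",
    "found": "find", "made": "make", "bound": "bind", "gave": "give",
    "species": "species", "analyses": "analysis",
}

# Small open-class verb lexicon; the species FP filter only needs to know
# that a candidate token is used as a verb.
_VERB_STEMS = {
    "be", "have", "do", "bind", "express", "encode", "regulate", "activate",
    "inhibit", "induce", "treat", "grow", "show", "suggest", "indicate",
    "observe", "measure", "detect", "isolate", "direct", "neutralize",
    "purify", "use", "describe", "report", "increase", "decrease",
    "phosphorylate", "transform", "infect", "enroll", "develop", "conserve",
    "extend", "prepare", "compare", "recognize", "improve", "find", "make",
    "take", "give", "study",
}

_CLOSED_CLASS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "these": "DT",
    "that": "DT", "those": "DT",
    "in": "IN", "of": "IN", "for": "IN", "with": "IN", "on": "IN",
    "at": "IN", "by": "IN", "to": "TO", "from": "IN", "as": "IN",
    "when": "WRB", "which": "WDT", "and": "CC", "or": "CC", "but": "CC",
    "we": "PRP", "it": "PRP", "they": "PRP", "he": "PRP", "she": "PRP",
    "i": "PRP", "its": "PRP$", "their": "PRP$", "our": "PRP$",
    "not": "RB", "also": "RB", "many": "JJ", "all": "DT",
}


def lemmatize(word: str) -> str:
    """Heuristic base form: irregular table, then plural/inflection suffixes."""
    low = word.lower()
    if low in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[low]
    if len(low) > 3:
        if low.endswith("ies"):
            return low[:-3] + "y"
        if low.endswith(("ches", "shes", "sses", "xes", "zes")):
            return low[:-2]
        if low.endswith("s") and not low.endswith(("ss", "us", "is")):
            return low[:-1]
        if low.endswith("ed") and len(low) > 4:
            stem = low[:-2]
            return stem if stem in _VERB_STEMS else (
                stem + "e" if stem + "e" in _VERB_STEMS else low)
        if low.endswith("ing") and len(low) > 5:
            stem = low[:-3]
            return stem if stem in _VERB_STEMS else (
                stem + "e" if stem + "e" in _VERB_STEMS else low)
    return low


def _pos_tag(surface: str, base: str) -> str:
    low = surface.lower()
    if low in _CLOSED_CLASS:
        return _CLOSED_CLASS[low]
    if surface.isdigit() or re.fullmatch(r"\d+(\.\d+)?", surface):
        return "CD"
    if not surface[0].isalnum():
        return surface[0]
    if base in _VERB_STEMS:
        if low.endswith("ing"):
            return "VBG"
        if low.endswith("ed") or low in ("was", "were", "grew", "took",
                                         "gave", "found", "made", "bound"):
            return "VBD"
        if low.endswith("s") and low != base:
            return "VBZ"
        return "VB"
    if surface[0].isupper():
        return "NNP"
    if low.endswith("s") and base != low:
        return "NNS"
    return "NN"


def _builtin_backend(sentence: Sentence) -> list[Token]:
    tokens: list[Token] = []
    for m in _TOKEN_RE.finditer(sentence.text):
        surface = m.group()
        base = lemmatize(surface)
        tokens.append(
            Token(
                surface=surface,
                base=base or surface.lower(),
                pos=_pos_tag(surface, base),
                offset=sentence.offset + m.start(),
                length=len(surface),
            )
        )
    return tokens


_BACKENDS: dict[str, Callable[[Sentence], list[Token]]] = {
    "builtin": _builtin_backend,
}


def register_backend(name: str, fn: Callable[[Sentence], list[Token]]) -> None:
    """Register an alternative tokenizer/tagger backend."""
    _BACKENDS[name] = fn


def tokenize_and_tag(sentence: Sentence, backend: str = "builtin") -> list[Token]:
    """Tokenize and tag one sentence, storing tokens on the sentence.

    A failing or unknown backend falls back to the builtin rules with a
    logged warning, so the pipeline never dies on backend trouble.
    """
    fn = _BACKENDS.get(backend)
    if fn is None:
        logger.warning("unknown NLP backend %r; falling back to builtin", backend)
        fn = _builtin_backend
    try:
        tokens = fn(sentence)
    except Exception:  # noqa: BLE001 - backend isolation is the contract
        logger.warning("NLP backend %r failed; falling back to builtin",
                       backend, exc_info=True)
        tokens = _builtin_backend(sentence)
    sentence.tokens = tokens
    return tokens


# ---------------------------------------------------------------------------
# Schwartz–Hearst abbreviation pairing

_PAREN_RE = re.compile(r"\(([^()]+)\)")


def _valid_short_form(short: str) -> bool:
    if not 2 <= len(short) <= 10:
        return False
    if len(short.split()) > 2:
        return False
    if not short[0].isalnum():
        return False
    return any(c.isalpha() for c in short)


def _find_best_long_form(short: str, long: str) -> int | None:
    """Return start index of the long form within ``long``, or None."""
    s = len(short) - 1
    l = len(long) - 1
    while s >= 0:
        c = short[s].lower()
        if not c.isalnum():
            s -= 1
            continue
        while l >= 0 and (
            long[l].lower() != c
            or (s == 0 and l > 0 and long[l - 1].isalnum())
        ):
            l -= 1
        if l < 0:
            return None
        s -= 1
        l -= 1
    return l + 1


def extract_abbreviations(sentence: Sentence) -> list[AbbrevPair]:
    """Extract (long form, short form) definition pairs from one sentence."""
    pairs: list[AbbrevPair] = []
    text = sentence.text
    for m in _PAREN_RE.finditer(text):
        short = m.group(1).strip()
        if not _valid_short_form(short):
            continue
        before = text[: m.start()].rstrip()
        if not before:
            continue
        # Candidate window: min(|short| + 5, |short| * 2) words before "(".
        max_words = min(len(short) + 5, len(short) * 2)
        words = before.split()
        window = " ".join(words[-max_words:])
        win_start = len(before) - len(window)
        start = _find_best_long_form(short, window)
        if start is None:
            continue
        long_form = window[start:]
        if len(long_form) <= len(short) or long_form.lower() == short.lower():
            continue
        if short.lower() in (w.lower() for w in long_form.split()):
            continue
        full_off = win_start + start
        short_off = m.start(1) + (len(m.group(1)) - len(m.group(1).lstrip()))
        pairs.append(
            AbbrevPair(
                full=long_form,
                short=short,
                full_span=(sentence.offset + full_off, len(long_form)),
                short_span=(sentence.offset + short_off, len(short)),
            )
        )
    return pairs
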