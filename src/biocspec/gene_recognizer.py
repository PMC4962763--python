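"""Gene/protein mention recognition with a pluggable backend.

The shipping backend is dictionary matching against the gene lexicon
(longest non-overlapping token-boundary matches after case/hyphen/space and
Greek-letter normalization), with organism-code prefix stripping so that
"hBACH" is found through the lexicon entry "BACH".  Statistical taggers can
be registered as additional backends; the recognizer contract is simply
"produce document-level gene mention spans".

After recognition, :func:`refine` applies a three-step cleanup: mentions
with no lexicon match are dropped, the surviving surface forms become a
per-article dictionary, and an exact-match re-scan recovers occurrences of
those names that the backend overlooked elsewhere in the article.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable

from .bioc_io import Document, Passage
from .lexicon import GeneLexicon, OrganismCodeList
from .nlp_pre import split_sentences, tokenize_and_tag

__all__ = ["GeneMention", "recognize_genes", "refine", "register_gene_backend"]


@dataclass
class GeneMention:
    offset: int  # document-level
    length: int
    text: str
    candidate_ids: frozenset[str] = frozenset()
    assigned_id: str | None = None
    infons: dict[str, str] = field(default_factory=dict)

    @property
    def end(self) -> int:
        return self.offset + self.length

    @property
    def span(self) -> tuple[int, int]:
        return (self.offset, self.length)


def _strip_prefix(surface: str, lex: GeneLexicon,
                  codes: OrganismCodeList | None) -> frozenset[str] | None:
    """Try organism-code prefix removal before lexicon lookup."""
    if codes is None:
        return None
    for code_len in (4, 3, 2, 1):
        if len(surface) <= code_len + 1:
            continue
        if not codes.get(surface[:code_len]):
            continue
        if not surface[code_len].isupper():
            continue
        ids = lex.lookup(surface[code_len:])
        if ids:
            return ids
    return None


def _dictionary_backend(doc: Document, lex: GeneLexicon,
                        codes: OrganismCodeList | None) -> list[GeneMention]:
    mentions: list[GeneMention] = []
    max_tokens = max(2 * lex.max_variant_tokens - 1, 4)
    for passage in doc.passages:
        for sent in split_sentences(passage):
            tokens = tokenize_and_tag(sent)
            i = 0
            while i < len(tokens):
                if not tokens[i].surface[0].isalnum():
                    i += 1
                    continue
                hit = None
                for j in range(min(i + max_tokens, len(tokens)), i, -1):
                    start = tokens[i].offset
                    end = tokens[j - 1].end
                    surface = passage.local_slice(start, end - start)
                    ids = lex.lookup(surface)
                    if ids is None:
                        ids = _strip_prefix(surface, lex, codes)
                    if ids:
                        hit = GeneMention(offset=start, length=end - start,
                                          text=surface, candidate_ids=ids)
                        break
                if hit is None:
                    i += 1
                else:
                    mentions.append(hit)
                    i = j
    return mentions


_GENE_BACKENDS: dict[str, Callable] = {"dictionary": _dictionary_backend}


def register_gene_backend(name: str, fn: Callable) -> None:
    _GENE_BACKENDS[name] = fn


def recognize_genes(doc: Document, lex: GeneLexicon,
                    backend: str = "dictionary",
                    codes: OrganismCodeList | None = None) -> list[GeneMention]:
    """Produce gene mentions with candidate Entrez IDs.

    Raises a configuration error for unknown backend names; the backend
    decides how spans are found, the lexicon supplies candidate IDs.
    """
    if backend not in _GENE_BACKENDS:
        raise ValueError(
            f"unknown gene recognizer backend {backend!r}; "
            f"registered: {sorted(_GENE_BACKENDS)}")
    return _GENE_BACKENDS[backend](doc, lex, codes)


_WORD_BOUNDARY = r"(?<![A-Za-z0-9]){}(?![A-Za-z0-9])"


def refine(doc: Document, mentions: list[GeneMention],
           lex: GeneLexicon) -> list[GeneMention]:
    """Drop unmatched mentions, then re-scan the article for missed names.

    Surviving surface forms make up a per-article dictionary; an exact-match
    scan over every passage adds occurrences the recognizer overlooked,
    inheriting the candidate IDs of the identical surface form.  Existing
    spans take precedence, so the re-scan never creates overlaps.  The
    operation is idempotent.
    """
    kept = [m for m in mentions if m.candidate_ids]
    surfaces: dict[str, frozenset[str]] = {}
    for m in kept:
        surfaces[m.text] = m.candidate_ids | surfaces.get(m.text, frozenset())
    occupied = [(m.offset, m.end) for m in kept]

    def free(start: int, end: int) -> bool:
        return all(end <= o or e <= start for o, e in occupied)

    added: list[GeneMention] = []
    for passage in doc.passages:
        for surface in sorted(surfaces, key=lambda s: (-len(s), s)):
            pattern = re.compile(_WORD_BOUNDARY.format(re.escape(surface)))
            for m in pattern.finditer(passage.text):
                start = passage.offset + m.start()
                end = passage.offset + m.end()
                if not free(start, end):
                    continue
                added.append(GeneMention(
                    offset=start, length=end - start, text=surface,
                    candidate_ids=surfaces[surface],
                    infons={"recovered_by": "refine"},
                ))
                occupied.append((start, end))
    return sorted(kept + added, key=lambda m: (m.offset, -m.length))
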