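"""Species mention recognition and normalization to NCBI Taxonomy IDs.

Two kinds of species evidence are produced:

* **Full species terms** ("Escherichia coli", "patients", "Drosophila"),
  found by token-boundary longest-match dictionary scanning.  The article is
  scanned from its information-richest to information-poorest parts
  (introduction first, titles last), so that ambiguous terms such as
  "E. coli" (taxonomy 562 or 110766) can be settled by the *majority rule*:
  pick the candidate ID already confirmed most often earlier in the scan.
  Remaining ties fall back to a curated model-organism preference list.

* **Prefixed species**: short organism codes embedded at the start of gene
  symbols ("h" in hLysoPLA -> human 9606, "Sc" in ScUAP1 -> budding yeast
  4932), resolved against length-stratified organism code lists with a
  consistency check against any author-defined full name for the gene.

Per-article state covers author abbreviation definitions promoted into the
dictionary, blacklists of rejected definition pairs and of gene mentions
whose full name contradicts a prefix code, and the history of successfully
normalized IDs that drives the majority rule.

The *sentence mode* processes the article line by line with none of that
article-level state; it exists to quantify (and test) what the
article-level model buys.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .bioc_io import (Annotation, Document, Passage, build_section_index,
                      processing_order)
from .lexicon import IDPreference, Lexicons, OrganismCodeList, SpeciesLexicon
from .nlp_pre import (AbbrevPair, Sentence, extract_abbreviations,
                      split_sentences, tokenize_and_tag)

logger = logging.getLogger(__name__)

__all__ = [
    "ArticleSpeciesState",
    "SpeciesCandidate",
    "extend_dictionary",
    "match_candidates",
    "disambiguate",
    "filter_false_positives",
    "resolve_prefix",
    "recognize",
]


@dataclass
class ArticleSpeciesState:
    """Per-article memory shared by the species recognition passes."""

    extended_terms: dict[str, tuple[str, ...]] = field(default_factory=dict)
    term_blacklist: set[tuple[str, str]] = field(default_factory=set)
    gene_blacklist: set[tuple[int, int]] = field(default_factory=set)
    id_history: Counter = field(default_factory=Counter)

    @property
    def blacklisted_shorts(self) -> set[str]:
        return {short for _, short in self.term_blacklist}


@dataclass
class SpeciesCandidate:
    """A dictionary hit, possibly still ambiguous between taxonomy IDs."""

    offset: int
    length: int
    text: str
    ids: tuple[str, ...]
    is_general_or_genus: bool = False
    single_token_pos: str | None = None  # PoS when the hit is one token
    sentence_span: tuple[int, int] = (0, 0)

    @property
    def end(self) -> int:
        return self.offset + self.length


def extend_dictionary(doc: Document, pairs: list[AbbrevPair],
                      lex: SpeciesLexicon) -> ArticleSpeciesState:
    """Promote author-defined abbreviations whose long form is a species term.

    For every (full, short) definition pair found in the article, the base
    form of the long form is looked up in the species dictionary.  A hit adds
    both the long form and the abbreviation to the per-article dictionary
    with the term's taxonomy IDs — this is how "AMV", defined as "avian
    myeloblastosis virus", becomes recognizable.  A miss blacklists the pair
    for this article so the short form is never matched.
    """
    state = ArticleSpeciesState()
    for pair in pairs:
        entry = lex.lookup(pair.full)
        if entry is not None:
            state.extended_terms.setdefault(pair.full, entry.ids)
            state.extended_terms.setdefault(pair.short, entry.ids)
            state.term_blacklist.discard((pair.full, pair.short))
        elif pair.short not in state.extended_terms:
            state.term_blacklist.add((pair.full, pair.short))
    return state


def _lookup(surface: str, state: ArticleSpeciesState | None,
            lex: SpeciesLexicon):
    """Surface lookup: per-article extensions first, then the static lexicon."""
    if state is not None:
        if surface in state.blacklisted_shorts:
            return None
        ids = state.extended_terms.get(surface)
        if ids is None and len(surface) > 4:
            for term, term_ids in state.extended_terms.items():
                if len(term) > 4 and term.lower() == surface.lower():
                    ids = term_ids
                    break
        if ids is not None:
            return ids, False
    entry = lex.lookup(surface)
    if entry is None:
        return None
    return entry.ids, (entry.is_general_term or entry.is_genus)


def _prepared_sentences(passage: Passage) -> list[Sentence]:
    sentences = split_sentences(passage)
    for s in sentences:
        tokenize_and_tag(s)
    return sentences


def match_candidates(passage: Passage, state: ArticleSpeciesState | None,
                     lex: SpeciesLexicon, gene_mentions=(),
                     sentences: list[Sentence] | None = None,
                     genus_requires_gene: bool = True) -> list[SpeciesCandidate]:
    """Token-boundary longest-match scan of one passage.

    General terms ("patients") and genus names ("Drosophila") are only
    retained when at least one gene mention occurs in the same sentence;
    they are species evidence *for a gene*, not species mentions per se.
    """
    if sentences is None:
        sentences = _prepared_sentences(passage)
    out: list[SpeciesCandidate] = []
    # Hyphen/space variants can tokenize to 2k-1 tokens for a k-word term.
    max_tokens = max(2 * lex.max_term_tokens - 1, 4)
    for sent in sentences:
        tokens = sent.tokens
        has_gene = any(g.offset < sent.end and sent.offset < g.offset + g.length
                       for g in gene_mentions)
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
                found = _lookup(surface, state, lex)
                if found is None:
                    continue
                ids, gated = found
                hit = SpeciesCandidate(
                    offset=start,
                    length=end - start,
                    text=surface,
                    ids=tuple(ids),
                    is_general_or_genus=gated,
                    single_token_pos=tokens[i].pos if j == i + 1 else None,
                    sentence_span=(sent.offset, sent.length),
                )
                break
            if hit is None:
                i += 1
                continue
            i = j  # consume matched tokens; overlapping shorter hits discarded
            if hit.is_general_or_genus and genus_requires_gene and not has_gene:
                continue
            out.append(hit)
    return out


def filter_false_positives(candidates: list[SpeciesCandidate],
                           gene_mentions=()) -> list[SpeciesCandidate]:
    """Drop verb-tagged single-token hits and hits inside gene mentions."""
    kept = []
    for c in candidates:
        if c.single_token_pos is not None and c.single_token_pos.startswith("VB"):
            continue
        if any(g.offset <= c.offset and c.end <= g.offset + g.length
               for g in gene_mentions):
            continue
        kept.append(c)
    return kept


def disambiguate(candidate: SpeciesCandidate, state: ArticleSpeciesState,
                 pref: IDPreference) -> tuple[str, str]:
    """Pick one taxonomy ID; returns ``(id, how)``.

    ``how`` is ``unique`` (single candidate), ``majority`` (ID most often
    confirmed earlier in this article), ``preference`` (ranked model-organism
    list) or ``fallback`` (smallest numeric ID, for determinism only).
    """
    ids = candidate.ids
    if len(ids) == 1:
        return ids[0], "unique"
    counts = {i: state.id_history[i] for i in ids}
    top = max(counts.values())
    leaders = sorted(i for i, c in counts.items() if c == top)
    if top > 0 and len(leaders) == 1:
        return leaders[0], "majority"
    best = pref.best(ids)
    if best is not None:
        return best, "preference"
    return min(ids, key=int), "fallback"


def resolve_prefix(gene, codes: OrganismCodeList, pairs: list[AbbrevPair],
                   state: ArticleSpeciesState) -> Annotation | None:
    """Resolve an organism-code prefix embedded in one gene mention.

    Codes are tried longest-first (4 down to 1 characters).  A code matches
    only when the character following it inside the gene name is uppercase;
    a remainder of length one is rejected as a false positive.  When the
    article defines a full name for the gene mention (via an abbreviation
    pair), the prefix is emitted only if that full name equals one of the
    code's species names — otherwise the gene is blacklisted, which is how
    "CaMKII" defined as "calcium/calmodulin-dependent protein kinase II"
    escapes the "Ca" organism code.
    """
    span = (gene.offset, gene.length)
    if span in state.gene_blacklist:
        return None
    text = gene.text
    defined_full = next((p.full for p in pairs if p.short == text), None)
    for code_len in (4, 3, 2, 1):
        if len(text) <= code_len:
            continue
        entries = codes.get(text[:code_len])
        if not entries:
            continue
        if not text[code_len].isupper():
            continue
        if len(text) - code_len == 1:
            continue
        if defined_full is not None:
            matching = [
                e for e in entries
                if defined_full.lower() in {n.lower() for n in e.full_names}
            ]
            if not matching:
                state.gene_blacklist.add(span)
                logger.debug("gene %r blacklisted: full name %r matches no "
                             "species name of code %r", text, defined_full,
                             text[:code_len])
                return None
            entries = matching
        tax = next((e.taxonomy_id for e in entries if e.taxonomy_id), None)
        if tax is None:
            continue
        return Annotation(
            id="",
            offset=gene.offset,
            length=code_len,
            text=text[:code_len],
            type="species_prefix",
            norm_ids=[tax],
        )
    return None


def _emit(candidate: SpeciesCandidate, tax_id: str, how: str,
          counter: list[int]) -> Annotation:
    counter[0] += 1
    return Annotation(
        id=f"S{counter[0]}",
        offset=candidate.offset,
        length=candidate.length,
        text=candidate.text,
        type="species",
        norm_ids=[tax_id],
        infons={"disambiguated_by": how},
    )


def recognize(doc: Document, lexicons: Lexicons, *, mode: str = "article",
              gene_mentions=(), genus_requires_gene: bool = True
              ) -> list[Annotation]:
    """Run full-name and prefixed species recognition over one document.

    ``mode="article"`` (default) uses the section-ordered scan with
    per-article dictionary extension, blacklists and the majority rule.
    ``mode="sentence"`` processes sentences independently with no
    article-level state (disambiguation falls directly to the preference
    list).  Gene mentions, when provided, gate general/genus terms, feed the
    false-positive filter and are the substrate for prefix resolution.
    """
    if mode not in ("article", "sentence"):
        raise ValueError(f"unknown species recognition mode: {mode!r}")
    genes = sorted(gene_mentions, key=lambda g: (g.offset, -g.length))
    counter = [0]
    annotations: list[Annotation] = []
    index = build_section_index(doc)
    order = processing_order(index, "species")
    sentences = {id(p): _prepared_sentences(p) for p in doc.passages}

    if mode == "article":
        pairs: list[AbbrevPair] = []
        for p in doc.passages:
            for s in sentences[id(p)]:
                pairs.extend(extract_abbreviations(s))
        state = extend_dictionary(doc, pairs, lexicons.species)
        for passage in order:
            cands = match_candidates(
                passage, state, lexicons.species, genes,
                sentences=sentences[id(passage)],
                genus_requires_gene=genus_requires_gene,
            )
            cands = filter_false_positives(cands, genes)
            for cand in cands:
                tax, how = disambiguate(cand, state, lexicons.preference)
                annotations.append(_emit(cand, tax, how, counter))
                state.id_history[tax] += 1
        # Prefixed species: same information-driven order over gene mentions.
        pcount = 0
        for passage in order:
            for gene in (g for g in genes
                         if passage.contains(g.offset, g.length)):
                ann = resolve_prefix(gene, lexicons.codes, pairs, state)
                if ann is not None:
                    pcount += 1
                    ann.id = f"P{pcount}"
                    annotations.append(ann)
                    state.id_history[ann.norm_ids[0]] += 1
    else:
        pcount = 0
        for passage in doc.passages:
            for sent in sentences[id(passage)]:
                local_pairs = extract_abbreviations(sent)
                state = ArticleSpeciesState()
                cands = match_candidates(
                    passage, None, lexicons.species, genes,
                    sentences=[sent],
                    genus_requires_gene=genus_requires_gene,
                )
                cands = filter_false_positives(cands, genes)
                for cand in cands:
                    tax, how = disambiguate(cand, state, lexicons.preference)
                    annotations.append(_emit(cand, tax, how, counter))
                for gene in (g for g in genes
                             if sent.offset <= g.offset and
                             g.offset + g.length <= sent.end):
                    ann = resolve_prefix(gene, lexicons.codes, local_pairs,
                                         state)
                    if ann is not None:
                        pcount += 1
                        ann.id = f"P{pcount}"
                        annotations.append(ann)
    return annotations
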