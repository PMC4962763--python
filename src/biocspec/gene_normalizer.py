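"""Multistage normalization of gene mentions to Entrez Gene IDs.

Full-text articles distribute gene evidence unevenly: the introduction names
the key genes next to their species and full forms, while results sections
reuse bare acronyms.  The normalizer therefore works in three stages:

1. **Stage 1** runs over the information-rich sections in the order
   introduction, discussion, abstract.  A mention with one candidate ID is
   assigned directly; an ambiguous mention is resolved by same-sentence
   species context (a species annotation whose taxonomy matches exactly one
   candidate) or by the majority rule over the IDs already assigned in this
   article.  Everything assigned feeds the running ID history.
2. **Stage 2** collects the assigned (surface, ID) pairs into a per-article
   dictionary and runs a substring tagger over the whole article.  New hits
   inherit the dictionary IDs (species context may narrow them); hits whose
   boundary disagrees with a recognizer mention transfer their ID to the
   recognizer span when determined, or park both spans as a deferred
   conflict.
3. **Stage 3** processes the remaining sections like stage 1, then resolves
   overlaps among all assigned spans by keeping the longest span (ties:
   leftmost).  Mentions that never acquire a single ID are dropped, with a
   logged count.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .bioc_io import (Annotation, Document, build_section_index,
                      processing_order)
from .lexicon import GeneLexicon, Lexicons
from .nlp_pre import Sentence, split_sentences
from .gene_recognizer import GeneMention, recognize_genes, refine
from . import species_recognizer

logger = logging.getLogger(__name__)

__all__ = ["NormalizationState", "stage1", "stage2", "stage3", "normalize"]

Span = tuple[int, int]


@dataclass
class NormalizationState:
    assigned: dict[Span, str] = field(default_factory=dict)
    id_history: Counter = field(default_factory=Counter)
    article_gene_dict: dict[str, frozenset[str]] = field(default_factory=dict)
    deferred_conflicts: set[tuple[Span, Span]] = field(default_factory=set)
    # Tagger hits parked by stage 2 (ambiguous boundary conflicts and
    # ambiguous standalone hits) that stage 3 still has to settle.
    pending: list[GeneMention] = field(default_factory=list)
    dropped: int = 0


def _sentences_by_passage(doc: Document) -> dict[int, list[Sentence]]:
    return {id(p): split_sentences(p) for p in doc.passages}


def _sentence_of(sentences: list[Sentence], offset: int) -> Sentence | None:
    for s in sentences:
        if s.offset <= offset < s.end:
            return s
    return None


def _species_in_sentence(species_annotations, sent: Sentence | None) -> set[str]:
    if sent is None:
        return set()
    return {
        a.norm_ids[0]
        for a in species_annotations
        if a.resolved and a.offset < sent.end and sent.offset < a.end
    }


def _assign(state: NormalizationState, mention: GeneMention, entrez: str,
            how: str) -> None:
    mention.assigned_id = entrez
    mention.infons["assigned_by"] = how
    state.assigned[mention.span] = entrez
    state.id_history[entrez] += 1


def _disambiguate_mention(mention: GeneMention, state: NormalizationState,
                          species_annotations, sentences, doc: Document,
                          lex: GeneLexicon, use_species_context: bool) -> bool:
    """Try to settle one mention; returns True when an ID was assigned."""
    cands = sorted(mention.candidate_ids)
    if not cands or mention.assigned_id is not None:
        return False
    if len(cands) == 1:
        _assign(state, mention, cands[0], "unique")
        return True
    if use_species_context:
        passage = doc.passage_at(mention.offset)
        sent = _sentence_of(sentences[id(passage)], mention.offset)
        taxa = _species_in_sentence(species_annotations, sent)
        if taxa:
            selected = [c for c in cands if lex.id_species.get(c) in taxa]
            if len(selected) == 1:
                _assign(state, mention, selected[0], "species_context")
                return True
    counts = {c: state.id_history[c] for c in cands}
    top = max(counts.values())
    if top > 0:
        leaders = [c for c, n in counts.items() if n == top]
        _assign(state, mention, min(leaders, key=int), "majority")
        return True
    return False


def stage1(doc: Document, mentions: list[GeneMention], species_annotations,
           lex: GeneLexicon, *, use_species_context: bool = True,
           state: NormalizationState | None = None,
           sentences=None) -> NormalizationState:
    """Normalize mentions in the introduction/discussion/abstract order."""
    if state is None:
        state = NormalizationState()
    if sentences is None:
        sentences = _sentences_by_passage(doc)
    index = build_section_index(doc)
    for passage in processing_order(index, "gene_stage1"):
        for mention in sorted(
                (m for m in mentions if passage.contains(m.offset, m.length)),
                key=lambda m: m.offset):
            _disambiguate_mention(mention, state, species_annotations,
                                  sentences, doc, lex, use_species_context)
    return state


def stage2(doc: Document, state: NormalizationState,
           mentions: list[GeneMention], species_annotations,
           lex: GeneLexicon, sentences=None) -> NormalizationState:
    """Dictionary tagging of the whole article with the stage-1 results.

    The tagger matches raw substrings (no token-boundary requirement), which
    is also what makes recognizer/tagger boundary disagreements possible;
    those are settled by ID transfer when the ID is determined, or deferred.
    Stage 2 never changes an ID assigned in stage 1.
    """
    if sentences is None:
        sentences = _sentences_by_passage(doc)
    for span, entrez in state.assigned.items():
        mention = next(m for m in mentions if m.span == span)
        state.article_gene_dict.setdefault(mention.text, frozenset())
        state.article_gene_dict[mention.text] |= {entrez}

    by_span = {m.span: m for m in mentions}
    new_spans: list[Span] = []
    for passage in doc.passages:
        hits: list[tuple[int, int, str]] = []
        for surface in sorted(state.article_gene_dict,
                              key=lambda s: (-len(s), s)):
            start = passage.text.find(surface)
            while start != -1:
                hits.append((passage.offset + start, len(surface), surface))
                start = passage.text.find(surface, start + 1)
        for offset, length, surface in sorted(hits, key=lambda h: (h[0], -h[1])):
            ids = state.article_gene_dict[surface]
            span = (offset, length)
            exact = by_span.get(span)
            if exact is not None:
                if exact.assigned_id is None:
                    if len(ids) == 1:
                        _assign(state, exact, next(iter(ids)), "stage2_dict")
                    else:
                        exact.candidate_ids = exact.candidate_ids | ids
                continue
            overlapping = [m for m in mentions
                           if m.offset < offset + length and offset < m.end]
            if overlapping:
                target = overlapping[0]
                determined = _determine(ids, species_annotations, sentences,
                                        doc, offset, lex)
                if determined is not None:
                    if target.assigned_id is None:
                        _assign(state, target, determined, "stage2_transfer")
                else:
                    state.deferred_conflicts.add((target.span, span))
                    pending = GeneMention(offset=offset, length=length,
                                          text=surface, candidate_ids=ids,
                                          infons={"source": "stage2_tagger"})
                    state.pending.append(pending)
                continue
            if any(offset < s + l and s < offset + length
                   for s, l in new_spans):
                continue
            new = GeneMention(offset=offset, length=length, text=surface,
                              candidate_ids=ids,
                              infons={"source": "stage2_tagger"})
            determined = _determine(ids, species_annotations, sentences, doc,
                                    offset, lex)
            if determined is not None:
                _assign(state, new, determined, "stage2_dict")
            mentions.append(new)
            by_span[new.span] = new
            new_spans.append((offset, length))
    return state


def _determine(ids: frozenset[str], species_annotations, sentences,
               doc: Document, offset: int, lex: GeneLexicon) -> str | None:
    """Single ID from a dictionary hit, via species context if needed."""
    if len(ids) == 1:
        return next(iter(ids))
    try:
        passage = doc.passage_at(offset)
    except Exception:
        return None
    sent = _sentence_of(sentences[id(passage)], offset)
    taxa = _species_in_sentence(species_annotations, sent)
    selected = [c for c in sorted(ids) if lex.id_species.get(c) in taxa]
    if len(selected) == 1:
        return selected[0]
    return None


def stage3(doc: Document, state: NormalizationState,
           mentions: list[GeneMention], species_annotations,
           lex: GeneLexicon, *, use_species_context: bool = True,
           sentences=None) -> list[Annotation]:
    """Process remaining sections, resolve overlaps, emit final annotations."""
    if sentences is None:
        sentences = _sentences_by_passage(doc)
    index = build_section_index(doc)
    ordered = processing_order(index, "remaining") + \
        processing_order(index, "gene_stage1")
    for passage in ordered:
        for mention in sorted(
                (m for m in mentions if passage.contains(m.offset, m.length)),
                key=lambda m: m.offset):
            _disambiguate_mention(mention, state, species_annotations,
                                  sentences, doc, lex, use_species_context)
    for pending in state.pending:
        _disambiguate_mention(pending, state, species_annotations, sentences,
                              doc, lex, use_species_context)

    candidates = [m for m in mentions + state.pending
                  if m.assigned_id is not None]
    state.dropped = sum(1 for m in mentions if m.assigned_id is None)
    if state.dropped:
        logger.info("dropping %d gene mention(s) never normalized",
                    state.dropped)
    # Longest span wins inside any overlapping group; ties leftmost.
    accepted: list[GeneMention] = []
    for m in sorted(candidates, key=lambda m: (-m.length, m.offset)):
        if all(m.end <= a.offset or a.end <= m.offset for a in accepted):
            accepted.append(m)
    accepted.sort(key=lambda m: m.offset)
    annotations = []
    for n, m in enumerate(accepted, start=1):
        annotations.append(Annotation(
            id=f"G{n}", offset=m.offset, length=m.length, text=m.text,
            type="gene", norm_ids=[m.assigned_id],
            infons={"assigned_by": m.infons.get("assigned_by", "")},
        ))
    return annotations


def normalize(doc: Document, lexicons: Lexicons, *,
              species_mode: str = "article",
              gene_backend: str = "dictionary",
              genus_requires_gene: bool = True,
              use_species_context: bool = True,
              gene_mentions: list[GeneMention] | None = None,
              species_annotations: list[Annotation] | None = None) -> Document:
    """Full pipeline: recognize genes and species, then normalize the genes.

    Attaches the species, species-prefix and gene annotations to the
    document's passages and returns the document.  Precomputed gene mentions
    or species annotations can be injected instead of being recomputed.
    """
    if gene_mentions is None:
        gene_mentions = refine(
            doc,
            recognize_genes(doc, lexicons.genes, backend=gene_backend,
                            codes=lexicons.codes),
            lexicons.genes)
    if species_annotations is None:
        species_annotations = species_recognizer.recognize(
            doc, lexicons, mode=species_mode, gene_mentions=gene_mentions,
            genus_requires_gene=genus_requires_gene)
    sentences = _sentences_by_passage(doc)
    state = stage1(doc, gene_mentions, species_annotations, lexicons.genes,
                   use_species_context=use_species_context,
                   sentences=sentences)
    stage2(doc, state, gene_mentions, species_annotations, lexicons.genes,
           sentences=sentences)
    gene_annotations = stage3(doc, state, gene_mentions, species_annotations,
                              lexicons.genes,
                              use_species_context=use_species_context,
                              sentences=sentences)
    for ann in species_annotations + gene_annotations:
        doc.passage_at(ann.offset).annotations.append(ann)
    for passage in doc.passages:
        passage.annotations.sort(key=lambda a: (a.offset, -a.length))
    return doc
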