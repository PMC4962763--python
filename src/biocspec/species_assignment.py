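"""Species assignment: give every gene mention a taxonomy ID.

Three heuristic rules are applied in strict precedence order:

1. **Prefix** — a resolved organism-code prefix on the gene mention itself
   ("h" on hBACH) assigns its taxonomy ID.
2. **Same sentence** — the nearest species term to the left of the gene
   mention in its sentence; when every species term sits to the right, the
   nearest one on the right.  Distance is the character gap between span
   boundaries.
3. **Focus species** — the species mentioned most often in the article.
   Count ties are broken by the fixed organism order human, mouse, rat,
   yeast, fly, E. coli (9606, 10090, 10116, 4932, 7227, 562), then by the
   smallest numeric ID.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from .bioc_io import Document
from .nlp_pre import split_sentences

logger = logging.getLogger(__name__)

__all__ = ["Assignment", "AssignmentResult", "assign", "focus_species"]

#: Count tie-break order: human, mouse, rat, yeast, fly, E. coli.
FOCUS_TIE_ORDER = ("9606", "10090", "10116", "4932", "7227", "562")


@dataclass
class Assignment:
    offset: int
    length: int
    text: str
    taxonomy_id: str | None
    rule_used: str | None  # "prefix" | "sentence" | "focus" | None


@dataclass
class AssignmentResult:
    assignments: list[Assignment]

    def by_text(self) -> dict[str, Assignment]:
        """First assignment per surface form (convenience for small fixtures)."""
        out: dict[str, Assignment] = {}
        for a in self.assignments:
            out.setdefault(a.text, a)
        return out


def focus_species(species_annotations) -> str | None:
    """Most frequent taxonomy ID over all species and prefix instances.

    Permutation-invariant in its input.  Returns None (no focus) when no
    species annotation exists.
    """
    counts = Counter(a.norm_ids[0] for a in species_annotations if a.resolved)
    if not counts:
        return None
    top = max(counts.values())
    leaders = [i for i, c in counts.items() if c == top]
    for preferred in FOCUS_TIE_ORDER:
        if preferred in leaders:
            return preferred
    return min(leaders, key=int)


def assign(doc: Document, genes, species_annotations, *,
           use_prefix_rule: bool = True) -> AssignmentResult:
    """Assign one taxonomy ID per gene mention via rules 1 -> 2 -> 3.

    ``use_prefix_rule=False`` ablates rule 1, reproducing the behavior of
    species taggers that cannot see prefixed species.
    """
    prefixes = [a for a in species_annotations if a.type == "species_prefix"]
    full = [a for a in species_annotations
            if a.type == "species" and a.resolved]
    focus = focus_species(species_annotations)
    sentences = {id(p): split_sentences(p) for p in doc.passages}

    results: list[Assignment] = []
    for gene in sorted(genes, key=lambda g: g.offset):
        tax: str | None = None
        rule: str | None = None
        if use_prefix_rule:
            for p in prefixes:
                if p.offset == gene.offset and p.length < gene.length:
                    tax, rule = p.norm_ids[0], "prefix"
                    break
        if tax is None:
            tax = _same_sentence_species(doc, sentences, gene, full)
            if tax is not None:
                rule = "sentence"
        if tax is None and focus is not None:
            tax, rule = focus, "focus"
        if tax is None:
            logger.info("gene mention %r at %d left without a species "
                        "(no species evidence in article)", gene.text,
                        gene.offset)
        results.append(Assignment(offset=gene.offset, length=gene.length,
                                  text=gene.text, taxonomy_id=tax,
                                  rule_used=rule))
    return AssignmentResult(assignments=results)


def _same_sentence_species(doc, sentences, gene, full_species) -> str | None:
    passage = doc.passage_at(gene.offset)
    sent = next((s for s in sentences[id(passage)]
                 if s.offset <= gene.offset < s.end), None)
    if sent is None:
        return None
    gene_end = gene.offset + gene.length
    in_sent = [a for a in full_species
               if sent.offset <= a.offset and a.end <= sent.end
               and (a.end <= gene.offset or a.offset >= gene_end)]
    if not in_sent:
        return None
    left = [a for a in in_sent if a.end <= gene.offset]
    if left:
        best = min(left, key=lambda a: (gene.offset - a.end, a.offset))
        return best.norm_ids[0]
    right = [a for a in in_sent if a.offset >= gene_end]
    best = min(right, key=lambda a: (a.offset - gene_end, a.offset))
    return best.norm_ids[0]
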