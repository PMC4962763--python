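"""Multistage gene normalization: stages, conflicts, overlap resolution."""

import pytest

from biocspec.bioc_io import Annotation, Document, Passage
from biocspec.gene_normalizer import (NormalizationState, normalize, stage1,
                                      stage2, stage3)
from biocspec.gene_recognizer import GeneMention, recognize_genes, refine
from biocspec import species_recognizer


def _doc(*passages):
    doc = Document(id="n")
    offset = 0
    for section, text in passages:
        doc.passages.append(Passage(offset=offset, text=text,
                                    section_type=section))
        offset += len(text) + 1
    return doc


def _species(doc, text, tax):
    # helper: gold-style species annotation located by surface search
    for p in doc.passages:
        if text in p.text:
            off = p.offset + p.text.index(text)
            return Annotation(id="s", offset=off, length=len(text),
                              text=text, type="species", norm_ids=[tax])
    raise AssertionError(text)


def _mentions(doc, lexicons):
    return refine(doc, recognize_genes(doc, lexicons.genes,
                                       codes=lexicons.codes), lexicons.genes)


class TestStage1:
    def test_species_context_selects_candidate(self, lexicons):
        doc = _doc(("introduction", "In human, TP53 was studied."))
        mentions = _mentions(doc, lexicons)
        species = [_species(doc, "human", "9606")]
        state = stage1(doc, mentions, species, lexicons.genes)
        assert mentions[0].assigned_id == "7157"
        assert state.assigned[mentions[0].span] == "7157"

    def test_majority_rule_highest_frequency(self, lexicons):
        doc = _doc(("introduction", "TP53 again."))
        mentions = _mentions(doc, lexicons)
        state = NormalizationState()
        state.id_history.update({"24842": 3, "7157": 1})
        stage1(doc, mentions, [], lexicons.genes, state=state)
        assert mentions[0].assigned_id == "24842"

    def test_undisambiguated_mention_left_unassigned(self, lexicons):
        doc = _doc(("introduction", "TP53 alone."))
        mentions = _mentions(doc, lexicons)
        stage1(doc, mentions, [], lexicons.genes)
        assert mentions[0].assigned_id is None


class TestStage2:
    def test_dictionary_hit_inherits_id_without_rematching(self, lexicons):
        doc = _doc(("introduction", "In human, TP53 was studied."),
                   ("results", "TP53 levels rose."))
        mentions = _mentions(doc, lexicons)
        species = [_species(doc, "human", "9606")]
        state = stage1(doc, mentions, species, lexicons.genes)
        stage2(doc, state, mentions, species, lexicons.genes)
        results_mention = [m for m in mentions if m.offset > 27][0]
        assert results_mention.assigned_id == "7157"
        assert results_mention.infons["assigned_by"] == "stage2_dict"

    def test_determined_id_transfers_to_recognizer_boundary(self, lexicons):
        doc = _doc(("introduction", "In human, BACH was studied."),
                   ("results", "The hBACH enzyme was active."))
        mentions = _mentions(doc, lexicons)
        species = [_species(doc, "human", "9606")]
        state = stage1(doc, mentions, species, lexicons.genes)
        stage2(doc, state, mentions, species, lexicons.genes)
        hbach = [m for m in mentions if m.text == "hBACH"][0]
        assert hbach.assigned_id == "23476"
        assert hbach.infons["assigned_by"] == "stage2_transfer"

    def test_stage2_never_changes_stage1_assignment(self, lexicons):
        doc = _doc(("introduction", "In human, TP53 was studied."),
                   ("discussion", "In rat, TP53 was confirmed."))
        mentions = _mentions(doc, lexicons)
        species = [_species(doc, "human", "9606"),
                   _species(doc, "rat", "10116")]
        state = stage1(doc, mentions, species, lexicons.genes)
        before = dict(state.assigned)
        stage2(doc, state, mentions, species, lexicons.genes)
        for span, entrez in before.items():
            assert state.assigned[span] == entrez

    def test_ambiguous_boundary_conflict_deferred(self, lexicons):
        # TP53 assigned to different IDs in two sentences -> ambiguous
        # article dictionary; the tagger hit inside hTP53 must be deferred.
        doc = _doc(("introduction",
                    "In human, TP53 was studied. In rat, TP53 differed."),
                   ("results", "The hTP53 variant was assayed."))
        mentions = _mentions(doc, lexicons)
        species = [_species(doc, "human", "9606"),
                   _species(doc, "rat", "10116")]
        state = stage1(doc, mentions, species, lexicons.genes)
        assert sorted(state.assigned.values()) == ["24842", "7157"]
        stage2(doc, state, mentions, species, lexicons.genes)
        assert state.deferred_conflicts
        assert state.pending and state.pending[0].text == "TP53"


class TestStage3:
    def test_longest_span_wins_on_overlap(self, lexicons):
        doc = _doc(("introduction",
                    "In human, TP53 was studied. In rat, TP53 differed."),
                   ("results", "The hTP53 variant was assayed."))
        mentions = _mentions(doc, lexicons)
        species = [_species(doc, "human", "9606"),
                   _species(doc, "rat", "10116")]
        state = stage1(doc, mentions, species, lexicons.genes)
        stage2(doc, state, mentions, species, lexicons.genes)
        anns = stage3(doc, state, mentions, species, lexicons.genes)
        in_results = [a for a in anns if a.offset >= doc.passages[1].offset]
        assert [a.text for a in in_results] == ["hTP53"]
        spans = sorted((a.offset, a.end) for a in anns)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_never_normalized_mentions_dropped_and_counted(self, lexicons):
        doc = _doc(("introduction", "TP53 alone was mentioned."))
        mentions = _mentions(doc, lexicons)
        state = stage1(doc, mentions, [], lexicons.genes)
        stage2(doc, state, mentions, [], lexicons.genes)
        anns = stage3(doc, state, mentions, [], lexicons.genes)
        assert anns == []
        assert state.dropped == 1


class TestNormalize:
    def test_full_text_all_gold_ids_assigned(self, lexicons, scenario):
        doc, gold = scenario("full_text_basic")
        normalize(doc, lexicons)
        genes = [a for a in doc.all_annotations() if a.type == "gene"]
        assert [(a.offset, a.norm_ids) for a in genes] == \
            [(a.offset, a.norm_ids) for a in sorted(gold.genes,
                                                    key=lambda a: a.offset)]

    def test_title_mention_assigned_despite_poor_context(self, lexicons,
                                                         scenario):
        # Structural order would start at the title with empty history; the
        # stage ordering must still normalize the title mention.
        doc, gold = scenario("full_text_basic")
        normalize(doc, lexicons)
        title = doc.passages[0]
        title_genes = [a for a in title.annotations if a.type == "gene"]
        assert [(a.text, a.norm_ids) for a in title_genes] == \
            [("TP53", ["7157"])]

    def test_final_annotations_single_id_nonoverlapping(self, lexicons,
                                                        scenario):
        for name in ("full_text_basic", "overlap_conflict", "prefix_genes"):
            doc, _ = scenario(name)
            normalize(doc, lexicons)
            genes = sorted((a for a in doc.all_annotations()
                            if a.type == "gene"), key=lambda a: a.offset)
            for a in genes:
                assert len(a.norm_ids) == 1
            for a, b in zip(genes, genes[1:]):
                assert a.end <= b.offset

    def test_abstract_only_document_degenerates_gracefully(self, lexicons):
        doc = _doc(("abstract", "In human, TP53 was studied."))
        normalize(doc, lexicons)
        genes = [a for a in doc.all_annotations() if a.type == "gene"]
        assert [(a.text, a.norm_ids) for a in genes] == [("TP53", ["7157"])]

    def test_document_without_genes_unchanged(self, lexicons):
        doc = _doc(("abstract", "Plain text with no entities at all."))
        normalize(doc, lexicons)
        assert list(doc.all_annotations()) == []

    def test_single_pass_determinism(self, lexicons, scenario):
        from biocspec.bioc_io import write_collection
        outs = []
        for _ in range(2):
            doc, _ = scenario("overlap_conflict")
            normalize(doc, lexicons)
            outs.append(write_collection([doc]))
        assert outs[0] == outs[1]
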