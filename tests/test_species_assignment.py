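"""Heuristic species assignment for gene mentions (rules 1-3)."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biocspec.bioc_io import Annotation, Document, Passage
from biocspec.gene_recognizer import GeneMention
from biocspec.species_assignment import (FOCUS_TIE_ORDER, assign,
                                         focus_species)


def _species_anns(ids):
    return [Annotation(id=f"s{i}", offset=i * 10, length=3, text="xxx",
                       type="species", norm_ids=[tax])
            for i, tax in enumerate(ids)]


class TestFocusSpecies:
    def test_unique_maximum(self):
        assert focus_species(_species_anns(["562"] * 5)) == "562"

    @pytest.mark.parametrize("ids,expected", [
        (["9606", "9606", "10090", "10090"], "9606"),   # human before mouse
        (["10116", "4932"], "10116"),                   # rat before yeast
        (["7227", "562"], "7227"),                      # fly before E. coli
    ])
    def test_printed_tie_order(self, ids, expected):
        assert focus_species(_species_anns(ids)) == expected

    def test_ties_outside_printed_order_use_smallest_id(self):
        assert focus_species(_species_anns(["99999", "11866"])) == "11866"

    def test_no_species_signals_no_focus(self):
        assert focus_species([]) is None

    @given(st.lists(st.sampled_from(FOCUS_TIE_ORDER + ("11866", "3702")),
                    min_size=1, max_size=12))
    @settings(max_examples=200, derandomize=True)
    def test_permutation_invariance(self, ids):
        anns = _species_anns(ids)
        assert focus_species(anns) == focus_species(list(reversed(anns)))


class TestAssignRules:
    def test_hbach_sentence_rules(self, recognized):
        doc, gold, mentions, species = recognized("hbach_sentence")
        result = assign(doc, mentions, species).by_text()
        assert (result["hBACH"].taxonomy_id,
                result["hBACH"].rule_used) == ("9606", "prefix")
        assert (result["BACH"].taxonomy_id,
                result["BACH"].rule_used) == ("562", "sentence")

    def test_prefix_rule_ablation_reproduces_contrast(self, recognized):
        doc, gold, mentions, species = recognized("hbach_sentence")
        result = assign(doc, mentions, species,
                        use_prefix_rule=False).by_text()
        assert result["hBACH"].taxonomy_id == "562"
        assert result["hBACH"].rule_used == "sentence"

    def test_nearest_left_beats_right(self, lexicons):
        doc = Document(id="a", passages=[Passage(
            offset=0, section_type="abstract",
            text="In human cells the TP53 gene, unlike in mouse, differs.")])
        gene = GeneMention(offset=19, length=4, text="TP53")
        species = [
            Annotation(id="s1", offset=3, length=5, text="human",
                       type="species", norm_ids=["9606"]),
            Annotation(id="s2", offset=41, length=5, text="mouse",
                       type="species", norm_ids=["10090"]),
        ]
        res = assign(doc, [gene], species).assignments[0]
        assert (res.taxonomy_id, res.rule_used) == ("9606", "sentence")

    def test_only_right_species_taken(self, lexicons):
        doc = Document(id="a", passages=[Passage(
            offset=0, section_type="abstract",
            text="The TP53 gene differs between mouse and human cells.")])
        gene = GeneMention(offset=4, length=4, text="TP53")
        species = [
            Annotation(id="s1", offset=30, length=5, text="mouse",
                       type="species", norm_ids=["10090"]),
            Annotation(id="s2", offset=40, length=5, text="human",
                       type="species", norm_ids=["9606"]),
        ]
        res = assign(doc, [gene], species).assignments[0]
        assert (res.taxonomy_id, res.rule_used) == ("10090", "sentence")

    def test_focus_fallback_across_sentences(self, lexicons):
        doc = Document(id="a", passages=[Passage(
            offset=0, section_type="abstract",
            text="Drosophila was studied. The TP53 gene was cloned.")])
        gene = GeneMention(offset=28, length=4, text="TP53")
        species = [Annotation(id="s1", offset=0, length=10,
                              text="Drosophila", type="species",
                              norm_ids=["7227"])]
        res = assign(doc, [gene], species).assignments[0]
        assert (res.taxonomy_id, res.rule_used) == ("7227", "focus")

    def test_genus_in_sentence_beats_focus_elsewhere(self, recognized):
        # DmERK-A argument: the genus name in the gene's sentence wins over
        # "rat" mentioned elsewhere in the article.
        doc, gold, mentions, species = recognized("genus_model")
        result = assign(doc, mentions, species).by_text()
        for surface, (tax, rule) in gold.assignments.items():
            assert (result[surface].taxonomy_id,
                    result[surface].rule_used) == (tax, rule)

    def test_rule_precedence_is_strict(self, recognized):
        # A prefixed gene never falls through to rules 2/3 even though a
        # different species sits in the same sentence.
        doc, gold, mentions, species = recognized("hbach_sentence")
        result = assign(doc, mentions, species).by_text()
        assert result["hBACH"].rule_used == "prefix"

    def test_no_species_at_all_leaves_unassigned(self, lexicons):
        doc = Document(id="a", passages=[Passage(
            offset=0, section_type="abstract", text="The TP53 gene.")])
        gene = GeneMention(offset=4, length=4, text="TP53")
        res = assign(doc, [gene], []).assignments[0]
        assert res.taxonomy_id is None and res.rule_used is None
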