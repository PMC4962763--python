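"""Species recognition: extension, matching, disambiguation, prefixes."""

import pytest

from biocspec.bioc_io import Document, Passage
from biocspec.gene_recognizer import GeneMention
from biocspec.nlp_pre import AbbrevPair
from biocspec.species_recognizer import (ArticleSpeciesState, SpeciesCandidate,
                                         disambiguate, extend_dictionary,
                                         filter_false_positives,
                                         match_candidates, recognize,
                                         resolve_prefix)
from biocspec.bioc_io import write_collection


def _doc(text, section="abstract", doc_id="t"):
    return Document(id=doc_id,
                    passages=[Passage(offset=0, text=text,
                                      section_type=section)])


def _pair(full, short):
    return AbbrevPair(full=full, short=short, full_span=(0, len(full)),
                      short_span=(0, len(short)))


class TestExtendDictionary:
    def test_species_long_form_promotes_abbreviation(self, lexicons):
        doc = _doc("x")
        state = extend_dictionary(
            doc, [_pair("avian myeloblastosis virus", "AMV")],
            lexicons.species)
        assert state.extended_terms["AMV"] == ("11866",)
        assert not state.term_blacklist

    def test_non_species_pair_blacklisted(self, lexicons):
        state = extend_dictionary(
            _doc("x"), [_pair("analysis of variance", "ANOVA")],
            lexicons.species)
        assert ("analysis of variance", "ANOVA") in state.term_blacklist

    def test_extension_overrides_static_ambiguity(self, lexicons):
        # "E. coli" is statically ambiguous; a definition pins it to 562.
        state = extend_dictionary(
            _doc("x"), [_pair("Escherichia coli", "E. coli")],
            lexicons.species)
        assert state.extended_terms["E. coli"] == ("562",)
        passage = _doc("Growth of E. coli was tested.").passages[0]
        cands = match_candidates(passage, state, lexicons.species)
        assert [(c.text, c.ids) for c in cands] == [("E. coli", ("562",))]


class TestMatching:
    def test_unambiguous_full_name(self, lexicons):
        passage = _doc("Escherichia coli cultures grew").passages[0]
        cands = match_candidates(passage, None, lexicons.species)
        assert [(c.text, c.ids) for c in cands] == \
            [("Escherichia coli", ("562",))]

    def test_general_term_requires_gene_in_sentence(self, lexicons):
        passage = _doc("The patients improved").passages[0]
        assert match_candidates(passage, None, lexicons.species) == []
        passage2 = _doc("The patients had TP53").passages[0]
        gene = GeneMention(offset=17, length=4, text="TP53")
        cands = match_candidates(passage2, None, lexicons.species,
                                 gene_mentions=[gene])
        assert [(c.text, c.ids) for c in cands] == [("patients", ("9606",))]

    def test_longest_match_wins(self, lexicons):
        passage = _doc("Drosophila melanogaster larvae hatched").passages[0]
        cands = match_candidates(passage, None, lexicons.species)
        assert [c.text for c in cands] == ["Drosophila melanogaster"]


class TestDisambiguate:
    def test_majority_beats_preference(self, lexicons):
        state = ArticleSpeciesState()
        state.id_history.update({"110766": 2})
        cand = SpeciesCandidate(offset=0, length=7, text="E. coli",
                                ids=("562", "110766"))
        assert disambiguate(cand, state, lexicons.preference) == \
            ("110766", "majority")

    def test_preference_on_empty_history(self, lexicons):
        cand = SpeciesCandidate(offset=0, length=7, text="E. coli",
                                ids=("562", "110766"))
        assert disambiguate(cand, ArticleSpeciesState(),
                            lexicons.preference) == ("562", "preference")

    def test_unambiguous_short_circuit(self, lexicons):
        state = ArticleSpeciesState()
        state.id_history.update({"562": 10})
        cand = SpeciesCandidate(offset=0, length=5, text="human",
                                ids=("9606",))
        assert disambiguate(cand, state, lexicons.preference) == \
            ("9606", "unique")

    def test_numeric_fallback_outside_preference(self):
        from biocspec.lexicon import IDPreference
        cand = SpeciesCandidate(offset=0, length=1, text="x",
                                ids=("300", "200"))
        assert disambiguate(cand, ArticleSpeciesState(),
                            IDPreference()) == ("200", "fallback")


class TestFalsePositiveFilter:
    def test_verb_candidate_removed(self):
        cand = SpeciesCandidate(offset=0, length=5, text="binds",
                                ids=("1",), single_token_pos="VBZ")
        assert filter_false_positives([cand]) == []

    def test_candidate_inside_gene_removed(self):
        cand = SpeciesCandidate(offset=10, length=4, text="BACH", ids=("1",))
        gene = GeneMention(offset=9, length=5, text="hBACH")
        assert filter_false_positives([cand], [gene]) == []

    def test_candidate_straddling_gene_kept(self):
        # "human BACH": the species word precedes the gene span.
        cand = SpeciesCandidate(offset=0, length=5, text="human", ids=("9606",))
        gene = GeneMention(offset=6, length=4, text="BACH")
        assert filter_false_positives([cand], [gene]) == [cand]

    def test_popeye_retained_when_gene_recognizer_missed_it(self, lexicons):
        # Documented FP mode: a gene family name listed as a fish common name
        # survives when no gene annotation covers it.
        passage = _doc("Three genes of the Popeye family exist").passages[0]
        cands = match_candidates(passage, None, lexicons.species)
        cands = filter_false_positives(cands, [])
        assert [(c.text, c.ids) for c in cands] == [("Popeye", ("269452",))]


class TestResolvePrefix:
    def run(self, lexicons, gene_text, pairs=()):
        gene = GeneMention(offset=0, length=len(gene_text), text=gene_text)
        state = ArticleSpeciesState()
        ann = resolve_prefix(gene, lexicons.codes, list(pairs), state)
        return ann, state

    def test_human_prefix(self, lexicons):
        ann, _ = self.run(lexicons, "hLysoPLA")
        assert (ann.text, ann.norm_ids) == ("h", ["9606"])
        assert (ann.offset, ann.length) == (0, 1)

    def test_two_letter_code_tried_before_one_letter(self, lexicons):
        ann, _ = self.run(lexicons, "ScUAP1")
        assert (ann.text, ann.norm_ids) == ("Sc", ["4932"])

    def test_single_char_remainder_rejected(self, lexicons):
        ann, _ = self.run(lexicons, "hA")
        assert ann is None

    def test_lowercase_follow_letter_rejected(self, lexicons):
        ann, _ = self.run(lexicons, "human")
        assert ann is None

    def test_full_name_mismatch_blacklists_gene(self, lexicons):
        pair = _pair("calcium/calmodulin-dependent protein kinase II",
                     "CaMKII")
        ann, state = self.run(lexicons, "CaMKII", pairs=[pair])
        assert ann is None
        assert (0, 6) in state.gene_blacklist

    def test_full_name_match_emits_prefix(self, lexicons):
        pair = _pair("Saccharomyces cerevisiae", "ScUAP1")
        ann, _ = self.run(lexicons, "ScUAP1", pairs=[pair])
        assert ann.norm_ids == ["4932"]

    def test_blacklisted_gene_never_reprocessed(self, lexicons):
        gene = GeneMention(offset=0, length=8, text="hLysoPLA")
        state = ArticleSpeciesState()
        state.gene_blacklist.add((0, 8))
        assert resolve_prefix(gene, lexicons.codes, [], state) is None


class TestRecognize:
    def test_article_mode_majority_reaches_title(self, recognized):
        doc, gold, mentions, species = recognized("ecoli_majority")
        by_text = {}
        for a in species:
            by_text.setdefault(a.text, []).append(a)
        assert all(a.norm_ids == ["562"] for a in by_text["E. coli"])
        assert {a.infons["disambiguated_by"] for a in by_text["E. coli"]} == \
            {"majority"}

    def test_sentence_mode_uses_preference_only(self, recognized):
        doc, gold, mentions, species = recognized("ecoli_majority",
                                                  mode="sentence")
        ambiguous = [a for a in species if a.text == "E. coli"]
        assert all(a.norm_ids == ["562"] for a in ambiguous)
        assert {a.infons["disambiguated_by"] for a in ambiguous} == \
            {"preference"}

    def test_majority_property_unambiguous_first(self, lexicons):
        # Any ambiguous mention preceded (in processing order) by an
        # unambiguous mention of one of its candidates resolves to it.
        doc = Document(id="m", passages=[
            Passage(offset=0, text="Growth of cultures", section_type="title"),
            Passage(offset=19,
                    text="Escherichia coli was grown. E. coli doubled.",
                    section_type="abstract"),
        ])
        anns = recognize(doc, lexicons)
        ecoli = [a for a in anns if a.text == "E. coli"]
        assert ecoli and all(a.norm_ids == ["562"] for a in ecoli)

    def test_empty_document_yields_nothing(self, lexicons):
        doc = _doc("Nothing of note happened here today.")
        assert recognize(doc, lexicons) == []

    def test_single_id_invariant_and_no_overlap(self, recognized):
        for name in ("ecoli_majority", "full_text_basic", "genus_model"):
            _, _, _, species = recognized(name)
            spans = sorted((a.offset, a.end) for a in species
                           if a.type == "species")
            for ann in species:
                assert len(ann.norm_ids) == 1
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_prefixes_are_strict_prefixes_of_genes(self, recognized):
        for name in ("prefix_genes", "genus_model", "hbach_sentence"):
            _, _, mentions, species = recognized(name)
            for ann in species:
                if ann.type != "species_prefix":
                    continue
                assert any(m.offset == ann.offset and ann.length < m.length
                           for m in mentions)

    def test_determinism_byte_identical(self, lexicons, scenario):
        outputs = []
        for _ in range(2):
            doc, _ = scenario("full_text_basic")
            from biocspec.gene_recognizer import recognize_genes, refine
            mentions = refine(doc, recognize_genes(doc, lexicons.genes,
                                                   codes=lexicons.codes),
                              lexicons.genes)
            anns = recognize(doc, lexicons, gene_mentions=mentions)
            for a in anns:
                doc.passage_at(a.offset).annotations.append(a)
            outputs.append(write_collection([doc]))
        assert outputs[0] == outputs[1]
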