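"""Synthetic BioC documents with gold annotations, plus mini-lexicons.

Every pipeline stage is testable without downloading the full SPECIES
dictionary, Entrez Gene or KEGG organism codes: :func:`write_mini_lexicons`
emits small lexicons in the production TSV schema, and :func:`generate`
builds scenario documents whose sections, mentions and ambiguities isolate
one behavior each (majority-rule disambiguation, prefixed species,
author-defined abbreviations, general-term gating, genus-to-model
normalization, stage-2 boundary conflicts, a basic full text, and the
published hBACH sentence).  Gold annotations are produced by construction.

Entrez Gene IDs in the gene lexicon are fixture-local synthetic integers
with declared species; taxonomy IDs are the real NCBI Taxonomy IDs for the
organisms involved.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .bioc_io import Annotation, Document, Passage

__all__ = ["Scenario", "GoldAnnotations", "SCENARIO_NAMES", "generate",
           "write_mini_lexicons", "write_config"]

SCENARIO_NAMES = (
    "ecoli_majority",
    "prefix_genes",
    "abbrev_definition",
    "general_terms",
    "genus_model",
    "overlap_conflict",
    "full_text_basic",
    "hbach_sentence",
)

#: The sentence printed from PMID 10578051, embedded verbatim.
HBACH_SENTENCE = (
    "The cDNA isolated for hBACH, when expressed in Escherichia coli, "
    "directed the expression of palmitoyl-CoA hydrolase activity and a "
    "44-kDa protein immunoreactive to the anti-BACH antibody, which in "
    "turn neutralized the hydrolase activity."
)

_FILLERS = (
    "Samples were stored at -80 degrees before further analysis.",
    "All experiments were repeated three times.",
    "Data were collected following standard protocols.",
    "Statistical significance was assessed with standard tests.",
)


@dataclass
class Scenario:
    name: str
    seed: int = 0
    params: dict = field(default_factory=dict)


@dataclass
class GoldAnnotations:
    """Gold annotations by construction, plus which pools a scenario isolates."""

    species: list[Annotation] = field(default_factory=list)
    genes: list[Annotation] = field(default_factory=list)
    #: gene surface -> (taxonomy ID, rule) for species-assignment scenarios
    assignments: dict[str, tuple[str, str]] = field(default_factory=dict)
    #: annotation pools the scenario makes end-to-end guarantees for
    pools: tuple[str, ...] = ("species",)


class _DocBuilder:
    """Accumulates passages with contiguous document-level offsets."""

    def __init__(self, doc_id: str) -> None:
        self.doc = Document(id=doc_id)
        self._offset = 0

    def add(self, section_type: str, text: str) -> Passage:
        passage = Passage(offset=self._offset, text=text,
                          section_type=section_type)
        self.doc.passages.append(passage)
        self._offset += len(text) + 1
        return passage


def _span(passage: Passage, substr: str, occurrence: int = 1) -> tuple[int, int]:
    """Document-level span of the n-th occurrence of ``substr``."""
    start = -1
    for _ in range(occurrence):
        start = passage.text.index(substr, start + 1)
    return passage.offset + start, len(substr)


def _gold(passage: Passage, substr: str, ann_type: str, tax_id: str,
          occurrence: int = 1, length: int | None = None) -> Annotation:
    offset, full_len = _span(passage, substr, occurrence)
    return Annotation(id="", offset=offset,
                      length=length if length is not None else full_len,
                      text=substr[:length] if length is not None else substr,
                      type=ann_type, norm_ids=[tax_id])


def _filler(rng: random.Random, n: int) -> str:
    return " ".join(rng.choice(_FILLERS) for _ in range(n))


# ---------------------------------------------------------------------------
# Scenario builders


def _ecoli_majority(rng: random.Random, params: dict):
    b = _DocBuilder("ecoli_majority")
    title = b.add("title", "Protein production in E. coli")
    abstract = b.add("abstract",
                     "Escherichia coli was used as an expression host. "
                     "Yields were measured after induction.")
    intro = b.add("introduction",
                  "Escherichia coli is a widely used bacterial host. "
                  "Expression systems were compared in this work.")
    results = b.add(
        "results",
        "Expression in E. coli increased over time. "
        "Cultures of E. coli grew rapidly. "
        + _filler(rng, params.get("fillers", 1)))
    gold = GoldAnnotations(species=[
        _gold(title, "E. coli", "species", "562"),
        _gold(abstract, "Escherichia coli", "species", "562"),
        _gold(intro, "Escherichia coli", "species", "562"),
        _gold(results, "E. coli", "species", "562", occurrence=1),
        _gold(results, "E. coli", "species", "562", occurrence=2),
    ])
    return b.doc, gold


def _prefix_genes(rng: random.Random, params: dict):
    b = _DocBuilder("prefix_genes")
    abstract = b.add(
        "abstract",
        "The hLysoPLA enzyme was purified from tissue extracts. "
        "The ScUAP1 protein was analyzed in parallel. "
        "Calcium/calmodulin-dependent protein kinase II (CaMKII) was "
        "monitored as a control. The hA fragment was discarded. "
        + _filler(rng, params.get("fillers", 1)))
    gold = GoldAnnotations(
        species=[
            _gold(abstract, "hLysoPLA", "species_prefix", "9606", length=1),
            _gold(abstract, "ScUAP1", "species_prefix", "4932", length=2),
        ],
        genes=[
            _gold(abstract, "hLysoPLA", "gene", "10434"),
            _gold(abstract, "ScUAP1", "gene", "855239"),
            _gold(abstract, "CaMKII", "gene", "815"),
            _gold(abstract, "hA", "gene", "99001"),
        ],
        pools=("species", "genes"),
    )
    return b.doc, gold


def _abbrev_definition(rng: random.Random, params: dict):
    b = _DocBuilder("abbrev_definition")
    abstract = b.add(
        "abstract",
        "The myb gene is the transforming oncogene of the avian "
        "myeloblastosis virus (AMV). AMV infection transforms myeloid "
        "cells. " + _filler(rng, params.get("fillers", 1)))
    gold = GoldAnnotations(
        species=[
            _gold(abstract, "avian myeloblastosis virus", "species", "11866"),
            _gold(abstract, "AMV", "species", "11866", occurrence=1),
            _gold(abstract, "AMV", "species", "11866", occurrence=2),
        ],
        genes=[_gold(abstract, "myb", "gene", "4602")],
        pools=("species", "genes"),
    )
    return b.doc, gold


def _general_terms(rng: random.Random, params: dict):
    b = _DocBuilder("general_terms")
    abstract = b.add(
        "abstract",
        "The patients showed elevated TP53 expression. "
        "Many patients were enrolled in the study. "
        "In Drosophila, the ERK-A kinase is conserved. "
        "Drosophila is a genus of flies. "
        + _filler(rng, params.get("fillers", 1)))
    gold = GoldAnnotations(
        species=[
            _gold(abstract, "patients", "species", "9606", occurrence=1),
            _gold(abstract, "Drosophila", "species", "7227", occurrence=1),
        ],
        genes=[
            _gold(abstract, "TP53", "gene", "7157"),
            _gold(abstract, "ERK-A", "gene", "3725001"),
        ],
        pools=("species", "genes"),
    )
    return b.doc, gold


def _genus_model(rng: random.Random, params: dict):
    b = _DocBuilder("genus_model")
    abstract = b.add(
        "abstract",
        "Protein kinases were characterized in the rat brain. "
        "In Drosophila, the DmERK-A gene encodes an extracellular "
        "signal-regulated kinase. "
        + _filler(rng, params.get("fillers", 1)))
    gold = GoldAnnotations(
        species=[
            _gold(abstract, "rat", "species", "10116"),
            _gold(abstract, "Drosophila", "species", "7227"),
            _gold(abstract, "DmERK-A", "species_prefix", "7227", length=2),
        ],
        assignments={
            "DmERK-A": ("7227", "prefix"),
            "extracellular signal-regulated kinase": ("7227", "sentence"),
        },
    )
    return b.doc, gold


def _overlap_conflict(rng: random.Random, params: dict):
    b = _DocBuilder("overlap_conflict")
    b.add("title", "Regulation of acyl-CoA thioesterase activity")
    intro = b.add("introduction",
                  "In human, BACH was studied in detail. "
                  "Its role remains unclear.")
    results = b.add(
        "results",
        "The hBACH enzyme showed increased activity in later assays. "
        + _filler(rng, params.get("fillers", 1)))
    gold = GoldAnnotations(
        species=[
            _gold(intro, "human", "species", "9606"),
            _gold(results, "hBACH", "species_prefix", "9606", length=1),
        ],
        genes=[
            _gold(intro, "BACH", "gene", "23476"),
            _gold(results, "hBACH", "gene", "23476"),
        ],
        pools=("species", "genes"),
    )
    return b.doc, gold


def _full_text_basic(rng: random.Random, params: dict):
    b = _DocBuilder("full_text_basic")
    title = b.add("title", "Analysis of TP53 in human tissues")
    abstract = b.add("abstract",
                     "TP53 expression was measured in samples from patients.")
    intro = b.add("introduction",
                  "The TP53 gene has been studied in human and mouse.")
    b.add("methods",
          "Samples were prepared for analysis. "
          + _filler(rng, params.get("fillers", 1)))
    results = b.add("results", "TP53 levels increased in rat livers.")
    discussion = b.add("discussion",
                       "These findings extend earlier work on TP53.")
    conclusion = b.add("conclusion",
                       "TP53 remains a key regulator of stress responses.")
    gold = GoldAnnotations(
        species=[
            _gold(title, "human", "species", "9606"),
            _gold(abstract, "patients", "species", "9606"),
            _gold(intro, "human", "species", "9606"),
            _gold(intro, "mouse", "species", "10090"),
            _gold(results, "rat", "species", "10116"),
        ],
        genes=[
            _gold(title, "TP53", "gene", "7157"),
            _gold(abstract, "TP53", "gene", "7157"),
            _gold(intro, "TP53", "gene", "7157"),
            _gold(results, "TP53", "gene", "7157"),
            _gold(discussion, "TP53", "gene", "7157"),
            _gold(conclusion, "TP53", "gene", "7157"),
        ],
        pools=("species", "genes"),
    )
    return b.doc, gold


def _hbach_sentence(rng: random.Random, params: dict):
    b = _DocBuilder("hbach_sentence")
    b.add("title", "Molecular characterization of a brain acyl-CoA hydrolase")
    abstract = b.add("abstract",
                     HBACH_SENTENCE + " " + _filler(rng, params.get("fillers", 1)))
    gold = GoldAnnotations(
        species=[
            _gold(abstract, "Escherichia coli", "species", "562"),
            _gold(abstract, "hBACH", "species_prefix", "9606", length=1),
        ],
        assignments={
            "hBACH": ("9606", "prefix"),
            "BACH": ("562", "sentence"),
        },
    )
    return b.doc, gold


_BUILDERS = {
    "ecoli_majority": _ecoli_majority,
    "prefix_genes": _prefix_genes,
    "abbrev_definition": _abbrev_definition,
    "general_terms": _general_terms,
    "genus_model": _genus_model,
    "overlap_conflict": _overlap_conflict,
    "full_text_basic": _full_text_basic,
    "hbach_sentence": _hbach_sentence,
}


def generate(scenario: Scenario) -> tuple[Document, GoldAnnotations]:
    """Build the scenario's document and gold annotations deterministically."""
    builder = _BUILDERS.get(scenario.name)
    if builder is None:
        raise ValueError(
            f"unknown scenario {scenario.name!r}; valid names: "
            f"{', '.join(SCENARIO_NAMES)}")
    rng = random.Random(scenario.seed)
    doc, gold = builder(rng, dict(scenario.params))
    for n, ann in enumerate(gold.species, start=1):
        ann.id = f"gs{n}"
    for n, ann in enumerate(gold.genes, start=1):
        ann.id = f"gg{n}"
    return doc, gold


# ---------------------------------------------------------------------------
# Mini-lexicons

_SPECIES_ROWS = (
    ("Escherichia coli", "562", ""),
    ("E. coli", "562;110766", ""),
    ("human", "9606", ""),
    ("Homo sapiens", "9606", ""),
    ("man", "9606", ""),
    ("patients", "9606", "general"),
    ("patient", "9606", "general"),
    ("boy", "9606", "general"),
    ("children", "9606", "general"),
    ("mouse", "10090", ""),
    ("Mus musculus", "10090", ""),
    ("rat", "10116", ""),
    ("Rattus norvegicus", "10116", ""),
    ("Drosophila", "7227", "genus"),
    ("Drosophila melanogaster", "7227", ""),
    ("Saccharomyces cerevisiae", "4932", ""),
    ("yeast", "4932", ""),
    ("avian myeloblastosis virus", "11866", ""),
    ("Zea mays", "381124", ""),
    ("Arabidopsis thaliana", "3702", ""),
    ("K cat", "9685", ""),
    ("Popeye", "269452", ""),
)

# Organism codes; "Ca" ships without a taxonomy ID (curation-pending row
# exercising the full-name blacklist path).
_CODE_ROWS = (
    ("H", "9606", "human;Homo sapiens"),
    ("h", "9606", "human;Homo sapiens"),
    ("m", "10090", "mouse;Mus musculus"),
    ("Zm", "381124", "Zea mays"),
    ("Sc", "4932", "Saccharomyces cerevisiae"),
    ("Dm", "7227", "Drosophila melanogaster"),
    ("Ca", "", "Coleophora albicans"),
    ("hum", "9606", "human;Homo sapiens"),
    ("hsa", "9606", "human;Homo sapiens"),
    ("Ath", "3701", "Arabidopsis thaliana"),
    ("ath", "3702", "Arabidopsis thaliana"),
)

# Entrez IDs are fixture-local synthetic integers (species declared per ID).
_GENE_ROWS = (
    ("BACH", "23476:9606;5000562:562"),
    ("LysoPLA", "10434:9606"),
    ("UAP1", "855239:4932"),
    ("CaMKII", "815:9606"),
    ("TP53", "7157:9606;24842:10116"),
    ("myb", "4602:9606"),
    ("ERK-A", "3725001:7227"),
    ("extracellular signal-regulated kinase", "116590:10116"),
    ("TrpR", "7000562:562"),
    ("hA", "99001:9606"),
)

_ID_PREFERENCE = ("9606", "10090", "10116", "4932", "7227", "3702",
                  "562", "11866", "381124", "110766")


def write_mini_lexicons(directory: str | Path) -> dict[str, Path]:
    """Write the fixture lexicons into ``directory``; returns the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "species_lexicon": d / "species_lexicon.tsv",
        "organism_codes": d / "organism_codes.tsv",
        "gene_lexicon": d / "gene_lexicon.tsv",
        "id_preference": d / "id_preference.txt",
    }
    paths["species_lexicon"].write_text(
        "".join(f"{t}\t{ids}\t{flags}\n" for t, ids, flags in _SPECIES_ROWS),
        encoding="utf-8")
    paths["organism_codes"].write_text(
        "".join(f"{c}\t{t}\t{n}\n" for c, t, n in _CODE_ROWS),
        encoding="utf-8")
    paths["gene_lexicon"].write_text(
        "".join(f"{v}\t{ids}\n" for v, ids in _GENE_ROWS), encoding="utf-8")
    paths["id_preference"].write_text(
        "".join(f"{i}\n" for i in _ID_PREFERENCE), encoding="utf-8")
    return paths


def write_config(directory: str | Path) -> Path:
    """Write the lexicons plus a ready-to-use YAML config; returns its path."""
    paths = write_mini_lexicons(directory)
    cfg = Path(directory) / "config.yaml"
    lines = ["lexicons:\n"]
    for key, path in paths.items():
        lines.append(f"  {key}: {path}\n")
    lines += ["mode: article\n", "genus_requires_gene: true\n",
              "gene_backend: dictionary\n", "use_prefix_rule: true\n",
              "species_context_in_stage1: true\n"]
    cfg.write_text("".join(lines), encoding="utf-8")
    return cfg
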