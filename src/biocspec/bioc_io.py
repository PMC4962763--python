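"""Reading and writing BioC XML, and section-aware passage access.

BioC is the XML interchange format used by biomedical text-mining pipelines:
a ``collection`` holds ``document`` elements, each document holds ``passage``
elements with a document-level character ``offset``, and passages carry
``annotation`` elements whose ``location`` records document-level spans.
Key/value metadata travels in ``infon`` elements.

The classes here form the in-memory model used by every downstream module.
Offsets are 0-based document-level character offsets and spans are half-open
``[offset, offset + length)``.  A :class:`SectionIndex` buckets passages by a
normalized section label so recognizers can walk the article in an
information-driven order (introduction first, titles last) instead of the
structural order of the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from lxml import etree

__all__ = [
    "Annotation",
    "Passage",
    "Document",
    "SectionIndex",
    "BioCError",
    "BioCParseError",
    "BioCValidationError",
    "SECTION_TYPES",
    "normalize_section_label",
    "read_collection",
    "write_collection",
    "build_section_index",
    "processing_order",
]

#: Closed vocabulary of normalized section labels.
SECTION_TYPES = (
    "title",
    "abstract",
    "introduction",
    "methods",
    "results",
    "discussion",
    "conclusion",
    "other",
)

#: Infon keys used to carry normalized identifiers.
TAXONOMY_INFON = "NCBI Taxonomy"
ENTREZ_INFON = "Entrez Gene"

# Substring synonym table for heterogeneous real-world section headings.
# Checked in order; first hit wins ("results and discussion" -> results).
_SECTION_SYNONYMS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("title", ("title", "front")),
    ("abstract", ("abstract",)),
    ("introduction", ("introduction", "background", "intro")),
    ("methods", ("method", "material", "experimental procedure", "study design")),
    ("results", ("result", "finding")),
    ("discussion", ("discussion",)),
    ("conclusion", ("conclusion", "concluding remark", "summary")),
)


class BioCError(ValueError):
    """Base class for BioC I/O failures."""


class BioCParseError(BioCError):
    """Malformed XML input."""


class BioCValidationError(BioCError):
    """Structurally valid XML that violates the BioC data contract."""


def normalize_section_label(label: str | None) -> str:
    """Map a raw passage section label onto the closed vocabulary.

    Matching is case-insensitive and by substring, because real BioC corpora
    carry headings such as ``"INTRODUCTION"``, ``"Results and Discussion"``
    or ``"Concluding remarks"``.  Unknown labels map to ``"other"``.
    """
    if not label:
        return "other"
    low = label.strip().lower()
    for canonical, needles in _SECTION_SYNONYMS:
        if any(n in low for n in needles):
            return canonical
    return "other"


@dataclass
class Annotation:
    """A typed text span with zero or more normalized database identifiers.

    ``type`` is one of ``species`` / ``species_prefix`` / ``gene``;
    species-side annotations carry NCBI Taxonomy IDs in ``norm_ids``, gene
    annotations carry Entrez Gene IDs.  ``resolved`` is true when exactly one
    identifier remains after disambiguation.
    """

    id: str
    offset: int
    length: int
    text: str
    type: str
    norm_ids: list[str] = field(default_factory=list)
    infons: dict[str, str] = field(default_factory=dict)

    @property
    def end(self) -> int:
        return self.offset + self.length

    @property
    def resolved(self) -> bool:
        return len(self.norm_ids) == 1


@dataclass
class Passage:
    offset: int
    text: str
    section_type: str = "other"
    annotations: list[Annotation] = field(default_factory=list)
    infons: dict[str, str] = field(default_factory=dict)

    @property
    def end(self) -> int:
        return self.offset + len(self.text)

    def contains(self, offset: int, length: int) -> bool:
        return self.offset <= offset and offset + length <= self.end

    def local_slice(self, offset: int, length: int) -> str:
        """Slice passage text using document-level coordinates."""
        return self.text[offset - self.offset : offset - self.offset + length]


@dataclass
class Document:
    id: str
    passages: list[Passage] = field(default_factory=list)
    infons: dict[str, str] = field(default_factory=dict)

    def passage_at(self, offset: int) -> Passage:
        for p in self.passages:
            if p.offset <= offset < p.end or (offset == p.offset == p.end):
                return p
        raise BioCValidationError(
            f"document {self.id!r}: offset {offset} lies in no passage"
        )

    def text_at(self, offset: int, length: int) -> str:
        return self.passage_at(offset).local_slice(offset, length)

    def all_annotations(self) -> Iterator[Annotation]:
        for p in self.passages:
            yield from p.annotations


@dataclass
class SectionIndex:
    """Passages of one document bucketed by normalized section type."""

    document: Document
    by_section: dict[str, list[Passage]]
    is_full_text: bool


def _infons(elem: etree._Element) -> dict[str, str]:
    return {i.get("key", ""): (i.text or "") for i in elem.findall("infon")}


_ID_INFONS = (TAXONOMY_INFON, ENTREZ_INFON)


def _parse_annotation(elem: etree._Element, doc_id: str) -> Annotation:
    infons = _infons(elem)
    loc = elem.find("location")
    if loc is None or loc.get("offset") is None or loc.get("length") is None:
        raise BioCValidationError(
            f"document {doc_id!r}: annotation {elem.get('id')!r} lacks a location"
        )
    norm_ids: list[str] = []
    for key in _ID_INFONS:
        if infons.get(key):
            norm_ids = [v for v in infons.pop(key).split(";") if v]
            break
    ann_type = infons.pop("type", "other")
    text = elem.findtext("text") or ""
    return Annotation(
        id=elem.get("id") or "",
        offset=int(loc.get("offset")),
        length=int(loc.get("length")),
        text=text,
        type=ann_type,
        norm_ids=norm_ids,
        infons=infons,
    )


def read_collection(xml_text: str | bytes) -> list[Document]:
    """Parse a BioC XML collection into :class:`Document` objects.

    Raises :class:`BioCParseError` (naming the line) on malformed XML and
    :class:`BioCValidationError` when a passage lacks an offset.  Unknown
    section labels normalize to ``"other"``.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:  # pragma: no cover - message path
        raise BioCParseError(f"malformed BioC XML at line {exc.lineno}: {exc.msg}") from exc
    docs: list[Document] = []
    for delem in root.findall("document"):
        doc_id = delem.findtext("id") or ""
        doc = Document(id=doc_id, infons=_infons(delem))
        last_offset = -1
        for pelem in delem.findall("passage"):
            infons = _infons(pelem)
            offset_text = pelem.findtext("offset")
            if offset_text is None:
                raise BioCValidationError(
                    f"document {doc_id!r}: passage missing <offset>"
                )
            offset = int(offset_text)
            if offset < 0 or offset <= last_offset:
                raise BioCValidationError(
                    f"document {doc_id!r}: passage offsets must be non-negative "
                    f"and strictly increasing (got {offset} after {last_offset})"
                )
            last_offset = offset
            raw_label = infons.pop("type", None) or infons.pop("section", None)
            passage = Passage(
                offset=offset,
                text=pelem.findtext("text") or "",
                section_type=normalize_section_label(raw_label),
                infons=infons,
            )
            for aelem in pelem.findall("annotation"):
                ann = _parse_annotation(aelem, doc_id)
                if passage.local_slice(ann.offset, ann.length) != ann.text:
                    raise BioCValidationError(
                        f"document {doc_id!r}: annotation {ann.id!r} text does not "
                        "match the passage slice at its span"
                    )
                passage.annotations.append(ann)
            doc.passages.append(passage)
        docs.append(doc)
    return docs


def _serialize_annotation(ann: Annotation, passage: Passage, doc_id: str,
                          parent: etree._Element) -> None:
    if not passage.contains(ann.offset, ann.length) or \
            passage.local_slice(ann.offset, ann.length) != ann.text:
        raise BioCValidationError(
            f"document {doc_id!r}: refusing to serialize annotation "
            f"{ann.id!r}: span does not reproduce its text"
        )
    elem = etree.SubElement(parent, "annotation", id=ann.id)
    etree.SubElement(elem, "infon", key="type").text = ann.type
    id_key = ENTREZ_INFON if ann.type == "gene" else TAXONOMY_INFON
    if ann.norm_ids:
        etree.SubElement(elem, "infon", key=id_key).text = ";".join(ann.norm_ids)
    for key in sorted(ann.infons):
        etree.SubElement(elem, "infon", key=key).text = ann.infons[key]
    etree.SubElement(elem, "location",
                     offset=str(ann.offset), length=str(ann.length))
    etree.SubElement(elem, "text").text = ann.text


def write_collection(docs: Iterable[Document]) -> str:
    """Serialize documents to a BioC XML string (deterministic, no dates)."""
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = "biocspec"
    etree.SubElement(root, "date").text = ""
    etree.SubElement(root, "key").text = "biocspec.key"
    for doc in docs:
        delem = etree.SubElement(root, "document")
        etree.SubElement(delem, "id").text = doc.id
        for key in sorted(doc.infons):
            etree.SubElement(delem, "infon", key=key).text = doc.infons[key]
        for passage in doc.passages:
            pelem = etree.SubElement(delem, "passage")
            etree.SubElement(pelem, "infon", key="type").text = passage.section_type
            for key in sorted(passage.infons):
                etree.SubElement(pelem, "infon", key=key).text = passage.infons[key]
            etree.SubElement(pelem, "offset").text = str(passage.offset)
            etree.SubElement(pelem, "text").text = passage.text
            for ann in passage.annotations:
                _serialize_annotation(ann, passage, doc.id, pelem)
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def build_section_index(doc: Document) -> SectionIndex:
    """Bucket passages by section type, preserving document order per bucket."""
    by_section: dict[str, list[Passage]] = {}
    for passage in doc.passages:
        by_section.setdefault(passage.section_type, []).append(passage)
    is_full_text = any(s not in ("title", "abstract") for s in by_section)
    return SectionIndex(document=doc, by_section=by_section, is_full_text=is_full_text)


# Species scan order for full texts: richest information first, titles last.
# Introduction-first and titles-last mirror how context (abbreviation
# definitions, first unambiguous mentions) is distributed in articles; the
# middle ranks are fixed here for determinism.
_SPECIES_ORDER = ("introduction", "discussion", "abstract",
                  "methods", "results", "conclusion", "other", "title")
_GENE_STAGE1_ORDER = ("introduction", "discussion", "abstract")


def processing_order(index: SectionIndex, mode: str) -> list[Passage]:
    """Ordered passages for a processing mode.

    ``species``
        Full text: introduction, discussion, abstract, methods, results,
        conclusion, other, title.  Abstract-only: abstract, title.
    ``gene_stage1``
        Introduction, discussion and abstract passages only (the
        information-rich sections handled by the first normalization stage).
    ``remaining``
        Every passage not covered by ``gene_stage1``, in document order,
        titles last.
    """
    by = index.by_section
    if mode == "species":
        sections = _SPECIES_ORDER if index.is_full_text else ("abstract", "title")
        return [p for s in sections for p in by.get(s, [])]
    if mode == "gene_stage1":
        return [p for s in _GENE_STAGE1_ORDER for p in by.get(s, [])]
    if mode == "remaining":
        covered = {id(p) for s in _GENE_STAGE1_ORDER for p in by.get(s, [])}
        rest = [p for p in index.document.passages
                if id(p) not in covered and p.section_type != "title"]
        rest += [p for p in by.get("title", []) if id(p) not in covered]
        return rest
    raise ValueError(f"unknown processing mode: {mode!r}")
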