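"""Lexicon loading: species dictionary, organism code lists, gene lexicon.

All lexicons are flat tab-separated files, matching how the upstream
resources (the SPECIES dictionary, KEGG organism codes, Entrez Gene exports)
are distributed; the shipped fixtures use the same schema, so full-scale
dictionaries are drop-in replacements.

File schemas
------------
``species_lexicon.tsv``
    ``term <TAB> taxonomy_ids(';'-separated) <TAB> flags`` — flags is a
    comma-separated subset of ``{general, genus}``.
``organism_codes.tsv``
    ``code <TAB> taxonomy_id <TAB> full_names(';'-separated)`` — codes are
    1–4 characters; the taxonomy ID may be empty for codes pending curation.
``gene_lexicon.tsv``
    ``variant <TAB> entrez_id:taxonomy_id(';'-separated pairs)``.
``id_preference.txt``
    One taxonomy ID per line, ranked model organisms first.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .nlp_pre import lemmatize

__all__ = [
    "SpeciesEntry",
    "SpeciesLexicon",
    "OrganismCodeList",
    "GeneLexicon",
    "IDPreference",
    "Lexicons",
    "LexiconFormatError",
    "load_species_lexicon",
    "load_code_list",
    "load_gene_lexicon",
    "load_id_preference",
    "load_stoplist",
    "default_stoplist",
    "generate_variants",
]

#: Terms at or below this length are treated as abbreviation-like and match
#: case-sensitively; longer terms match case-insensitively.
CASE_SENSITIVE_MAX_LEN = 4


class LexiconFormatError(ValueError):
    """A lexicon file violates its schema (message carries the line number)."""


@dataclass(frozen=True)
class SpeciesEntry:
    ids: tuple[str, ...]
    is_general_term: bool = False
    is_genus: bool = False
    source_term: str = ""  # provenance: original row the entry came from


@dataclass
class SpeciesLexicon:
    """Species term dictionary with flags and a lemma-normalized side index."""

    entries: dict[str, SpeciesEntry] = field(default_factory=dict)
    ci_index: dict[str, SpeciesEntry] = field(default_factory=dict)
    base_form_index: dict[str, SpeciesEntry] = field(default_factory=dict)
    max_term_tokens: int = 1

    def _register(self, term: str, entry: SpeciesEntry) -> None:
        self.entries.setdefault(term, entry)
        if len(term) > CASE_SENSITIVE_MAX_LEN:
            self.ci_index.setdefault(term.lower(), entry)
        base = base_form(term)
        if base != term:
            self.base_form_index.setdefault(base, entry)
            if len(base) > CASE_SENSITIVE_MAX_LEN:
                self.base_form_index.setdefault(base.lower(), entry)
        self.max_term_tokens = max(self.max_term_tokens,
                                   len(re.findall(r"\S+", term)))

    def lookup(self, surface: str) -> SpeciesEntry | None:
        """Resolve a surface string per the case policy, then by base form."""
        entry = self.entries.get(surface)
        if entry is None and len(surface) > CASE_SENSITIVE_MAX_LEN:
            entry = self.ci_index.get(surface.lower())
        if entry is None:
            base = base_form(surface)
            if base != surface:
                entry = self.entries.get(base)
                if entry is None and len(base) > CASE_SENSITIVE_MAX_LEN:
                    entry = self.ci_index.get(base.lower())
            if entry is None:
                entry = self.base_form_index.get(base)
            if entry is None and len(base) > CASE_SENSITIVE_MAX_LEN:
                entry = self.base_form_index.get(base.lower())
        return entry


@dataclass(frozen=True)
class CodeEntry:
    code: str
    taxonomy_id: str | None
    full_names: tuple[str, ...]


@dataclass
class OrganismCodeList:
    """Prefix code -> (taxonomy ID, full species names), bucketed by length."""

    by_length: dict[int, dict[str, list[CodeEntry]]] = field(default_factory=dict)

    def add(self, entry: CodeEntry) -> None:
        bucket = self.by_length.setdefault(len(entry.code), {})
        bucket.setdefault(entry.code, []).append(entry)

    def get(self, code: str) -> list[CodeEntry]:
        return self.by_length.get(len(code), {}).get(code, [])


@dataclass
class GeneLexicon:
    """Gene name variants -> Entrez IDs, each ID carrying its species."""

    variants: dict[str, frozenset[str]] = field(default_factory=dict)
    id_species: dict[str, str] = field(default_factory=dict)
    max_variant_tokens: int = 1
    provenance: dict[str, str] = field(default_factory=dict)

    def lookup(self, surface: str) -> frozenset[str] | None:
        return self.variants.get(normalize_gene_variant(surface))

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class IDPreference:
    ordered_ids: list[str] = field(default_factory=list)
    _rank: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self._rank:
            self._rank = {i: n for n, i in enumerate(self.ordered_ids)}

    def best(self, candidates) -> str | None:
        """Highest-ranked candidate, or None when none is listed."""
        ranked = [c for c in candidates if c in self._rank]
        if not ranked:
            return None
        return min(ranked, key=lambda c: self._rank[c])


@dataclass
class Lexicons:
    """Bundle of all lexicons one pipeline run needs."""

    species: SpeciesLexicon
    codes: OrganismCodeList
    genes: GeneLexicon
    preference: IDPreference

    @classmethod
    def from_dir(cls, directory: str | Path,
                 stoplist: frozenset[str] | None = None) -> "Lexicons":
        d = Path(directory)
        return cls(
            species=load_species_lexicon(d / "species_lexicon.tsv", stoplist),
            codes=load_code_list(d / "organism_codes.tsv"),
            genes=load_gene_lexicon(d / "gene_lexicon.tsv"),
            preference=load_id_preference(d / "id_preference.txt"),
        )


# ---------------------------------------------------------------------------
# Normalization helpers

_GREEK = {
    "alpha": "α", "beta": "β", "gamma": "γ", "delta": "δ", "epsilon": "ε",
    "kappa": "κ", "lambda": "λ", "sigma": "σ", "omega": "ω",
}
_GREEK_REVERSE = {v: k for k, v in _GREEK.items()}


def normalize_gene_variant(name: str) -> str:
    """Case/hyphen/space-insensitive key for gene variant matching."""
    low = name.lower()
    for letter, spelled in _GREEK_REVERSE.items():
        low = low.replace(letter, spelled)
    return re.sub(r"[\s\-_]+", "", low)


def base_form(term: str) -> str:
    """Lemmatize the head (last) word of a term, keeping the rest verbatim."""
    words = term.split()
    if not words:
        return term
    head = lemmatize(words[-1])
    if head == words[-1].lower() and words[-1][0].isupper():
        return term  # lemma changed nothing but case: keep the original
    return " ".join(words[:-1] + [head])


def generate_variants(term: str,
                      stoplist: frozenset[str] = frozenset()) -> set[str]:
    """Mechanical variants of a species term.

    Emits the base (lemma) form, hyphen/space interchanges and, for short
    abbreviated terms, the space-removed form ("K cat" -> "kcat").  Variants
    whose lowercase form is on the stop-list are suppressed; the stop-list
    exists precisely because space-removal can fabricate ordinary English or
    biochemistry words.
    """
    variants: set[str] = set()
    base = base_form(term)
    if base != term:
        variants.add(base)
    if " " in term:
        variants.add(term.replace(" ", "-"))
        words = term.split()
        if len(words) == 2 and any(len(w) <= 2 for w in words):
            joined = term.replace(" ", "")
            variants.add(joined)
            variants.add(joined.lower())
    if "-" in term:
        variants.add(term.replace("-", " "))
    variants.discard(term)
    return {v for v in variants if v.lower() not in stoplist}


# ---------------------------------------------------------------------------
# Loaders

def _rows(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _check_tax_id(value: str, path, lineno: int) -> str:
    if not value.isdigit():
        raise LexiconFormatError(
            f"{path}:{lineno}: non-integer taxonomy ID {value!r}")
    return value


def default_stoplist() -> frozenset[str]:
    """The stop-list shipped with the package."""
    text = (resources.files("biocspec") / "data" /
            "species_variant_stoplist.txt").read_text(encoding="utf-8")
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )


def load_stoplist(path: str | Path) -> frozenset[str]:
    """Load a user stop-list file (same format as the shipped one)."""
    out = set()
    for _, cols in _rows(path):
        out.add(cols[0].strip().lower())
    return frozenset(out)


_KNOWN_FLAGS = {"general", "genus"}


def load_species_lexicon(path: str | Path,
                         stoplist: frozenset[str] | None = None) -> SpeciesLexicon:
    """Load the species dictionary, adding base forms and generated variants."""
    if stoplist is None:
        stoplist = default_stoplist()
    lex = SpeciesLexicon()
    for lineno, cols in _rows(path):
        if len(cols) < 2:
            raise LexiconFormatError(f"{path}:{lineno}: expected >= 2 columns")
        term = cols[0].strip()
        ids = tuple(
            _check_tax_id(v.strip(), path, lineno)
            for v in cols[1].split(";") if v.strip()
        )
        if not ids:
            raise LexiconFormatError(f"{path}:{lineno}: no taxonomy ID for {term!r}")
        flags = {f.strip() for f in (cols[2] if len(cols) > 2 else "").split(",")
                 if f.strip()}
        unknown = flags - _KNOWN_FLAGS
        if unknown:
            raise LexiconFormatError(
                f"{path}:{lineno}: unknown flag(s) {sorted(unknown)}")
        if "genus" in flags and len(ids) != 1:
            raise LexiconFormatError(
                f"{path}:{lineno}: genus term {term!r} must map to exactly one "
                "taxonomy ID (its designated model species)")
        entry = SpeciesEntry(
            ids=ids,
            is_general_term="general" in flags,
            is_genus="genus" in flags,
            source_term=term,
        )
        lex._register(term, entry)
        for variant in sorted(generate_variants(term, stoplist)):
            lex._register(variant, SpeciesEntry(
                ids=ids,
                is_general_term=entry.is_general_term,
                is_genus=entry.is_genus,
                source_term=term,
            ))
    return lex


def load_code_list(path: str | Path) -> OrganismCodeList:
    """Load the length-stratified organism code list."""
    codes = OrganismCodeList()
    for lineno, cols in _rows(path):
        if len(cols) < 3:
            raise LexiconFormatError(f"{path}:{lineno}: expected 3 columns")
        code = cols[0].strip()
        if not 1 <= len(code) <= 4:
            raise LexiconFormatError(
                f"{path}:{lineno}: code {code!r} length outside 1..4")
        tax = cols[1].strip()
        taxonomy_id = _check_tax_id(tax, path, lineno) if tax else None
        names = tuple(n.strip() for n in cols[2].split(";") if n.strip())
        codes.add(CodeEntry(code=code, taxonomy_id=taxonomy_id, full_names=names))
    return codes


def load_gene_lexicon(path: str | Path) -> GeneLexicon:
    """Load gene name variants with their Entrez IDs and species."""
    lex = GeneLexicon()
    for lineno, cols in _rows(path):
        if len(cols) < 2:
            raise LexiconFormatError(f"{path}:{lineno}: expected 2 columns")
        variant = cols[0].strip()
        ids: set[str] = set()
        for pair in cols[1].split(";"):
            pair = pair.strip()
            if not pair:
                continue
            if ":" not in pair:
                raise LexiconFormatError(
                    f"{path}:{lineno}: entry {pair!r} lacks a species "
                    "(expected entrez_id:taxonomy_id)")
            entrez, tax = pair.split(":", 1)
            entrez, tax = entrez.strip(), tax.strip()
            if not tax:
                raise LexiconFormatError(
                    f"{path}:{lineno}: Entrez ID {entrez!r} has no species")
            _check_tax_id(tax, path, lineno)
            lex.id_species[entrez] = tax
            ids.add(entrez)
        key = normalize_gene_variant(variant)
        lex.variants[key] = frozenset(ids) | lex.variants.get(key, frozenset())
        lex.provenance.setdefault(key, variant)
        lex.max_variant_tokens = max(lex.max_variant_tokens,
                                     len(re.findall(r"[A-Za-z0-9]+", variant)))
    return lex


def load_id_preference(path: str | Path) -> IDPreference:
    """Load the ranked taxonomy-ID preference list (no duplicates)."""
    seen: list[str] = []
    for lineno, cols in _rows(path):
        tax = _check_tax_id(cols[0].strip(), path, lineno)
        if tax in seen:
            raise LexiconFormatError(f"{path}:{lineno}: duplicate ID {tax}")
        seen.append(tax)
    return IDPreference(ordered_ids=seen)
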