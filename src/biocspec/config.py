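"""Pipeline configuration: lexicon paths and behavioral toggles (YAML)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .lexicon import (Lexicons, default_stoplist, load_code_list,
                      load_gene_lexicon, load_id_preference, load_species_lexicon,
                      load_stoplist)

__all__ = ["PipelineConfig", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Bad or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    species_lexicon: Path
    organism_codes: Path
    gene_lexicon: Path
    id_preference: Path
    stoplist: Path | None = None
    mode: str = "article"
    genus_requires_gene: bool = True
    gene_backend: str = "dictionary"
    use_prefix_rule: bool = True
    species_context_in_stage1: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        lex = raw.get("lexicons", {})
        missing = [k for k in ("species_lexicon", "organism_codes",
                               "gene_lexicon", "id_preference") if k not in lex]
        if missing:
            raise ConfigurationError(
                f"{path}: missing lexicon path(s): {', '.join(missing)}")
        return cls(
            species_lexicon=Path(lex["species_lexicon"]),
            organism_codes=Path(lex["organism_codes"]),
            gene_lexicon=Path(lex["gene_lexicon"]),
            id_preference=Path(lex["id_preference"]),
            stoplist=Path(lex["stoplist"]) if lex.get("stoplist") else None,
            mode=raw.get("mode", "article"),
            genus_requires_gene=bool(raw.get("genus_requires_gene", True)),
            gene_backend=raw.get("gene_backend", "dictionary"),
            use_prefix_rule=bool(raw.get("use_prefix_rule", True)),
            species_context_in_stage1=bool(
                raw.get("species_context_in_stage1", True)),
        )

    def load_lexicons(self) -> Lexicons:
        """Load all lexicons; raises ConfigurationError for missing files."""
        for path in (self.species_lexicon, self.organism_codes,
                     self.gene_lexicon, self.id_preference):
            if not Path(path).exists():
                raise ConfigurationError(f"lexicon file not found: {path}")
        stoplist = (load_stoplist(self.stoplist) | default_stoplist()
                    if self.stoplist else default_stoplist())
        return Lexicons(
            species=load_species_lexicon(self.species_lexicon, stoplist),
            codes=load_code_list(self.organism_codes),
            genes=load_gene_lexicon(self.gene_lexicon),
            preference=load_id_preference(self.id_preference),
        )
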