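# biocspec

Species and gene/protein mention normalization for biomedical articles in
the BioC XML interchange format.

Literature curators and text-mining pipelines need two linked capabilities:
recognizing **species mentions** and normalizing them to NCBI Taxonomy IDs,
and recognizing **gene/protein mentions** and normalizing them to Entrez
Gene IDs.  The two tasks interact — the main obstacle in gene normalization
is orthology (the same gene name exists in many species), so species
evidence is what disambiguates gene IDs.  `biocspec` implements both sides,
including a form of species evidence most taggers ignore: the **prefixed
species**, a short organism code embedded at the start of a gene symbol
("h" in *h*LysoPLA → human, 9606; "Sc" in *Sc*UAP1 → *Saccharomyces
cerevisiae*, 4932).

## What it does

* **BioC I/O with section awareness.** Articles are read from BioC XML
  (collection → document → passage → annotation), passages are bucketed by
  normalized section labels, and processing walks the article from its
  information-richest to -poorest parts: introduction first, titles last.
* **Species recognition.** Dictionary longest-match over full species
  terms, extended per article with author-defined abbreviations (the pair
  "avian myeloblastosis virus (AMV)" makes "AMV" a recognizable species
  term for that article).  Ambiguous terms like "E. coli" (562 or 110766)
  are settled by the *majority rule* — the candidate ID already confirmed
  most often earlier in the scan — then by a ranked model-organism
  preference list.  General human terms ("patients", "boy") and genus names
  ("Drosophila" → 7227) are emitted only next to a gene mention in the same
  sentence.  Verb-tagged candidates and candidates inside gene mentions are
  filtered out.
* **Prefixed-species resolution** against 1–4 letter organism code lists,
  longest code first, with a consistency check against author-defined full
  names ("Ca" in CaMKII is calcium, not *Coleophora albicans* — the gene is
  blacklisted).
* **Gene recognition** via a pluggable backend (shipping default:
  dictionary matching with case/hyphen/space and Greek-letter
  normalization, plus organism-code prefix stripping so "hBACH" matches the
  lexicon entry "BACH"), followed by a refinement pass that drops unmatched
  mentions and re-scans the article for overlooked occurrences.
* **Multistage gene normalization.** Stage 1 assigns IDs in the
  introduction/discussion/abstract using species context and the majority
  rule; stage 2 tags the whole article with the per-article dictionary
  built from stage 1, transferring determined IDs across boundary
  disagreements; stage 3 settles the rest and keeps the longest span in any
  overlap.
* **Species assignment** for genes by three strict-precedence rules:
  (1) prefix, (2) nearest same-sentence species (left before right),
  (3) article focus species, with count ties broken human → mouse → rat →
  yeast → fly → *E. coli*.
* **Instance-level exact-match evaluation**: precision/recall/F separately
  for recognition (boundary) and normalization (boundary + ID).

The package ships mini-lexicons and a synthetic-document generator
(`biocspec.fixtures`) in the production TSV schema, so everything runs
without downloads; full-scale dictionaries (SPECIES dictionary, Entrez
Gene, KEGG organism codes) are drop-in replacements.

## Worked example

`examples/species_assignment.py` runs the pipeline on the published
sentence from PMID 10578051 ("The cDNA isolated for hBACH, when expressed
in Escherichia coli, directed the expression ...") and prints:

```
--- with rule 1
  'hBACH'  -> taxonomy 9606 (rule: prefix)
  'BACH'   -> taxonomy 562 (rule: sentence)
--- without rule 1
  'hBACH'  -> taxonomy 562 (rule: sentence)
  'BACH'   -> taxonomy 562 (rule: sentence)
```

The prefix "h" is what keeps the human gene hBACH from being dragged to
*E. coli* (562) by the species term in the same sentence; ablating rule 1
reproduces the behavior of species taggers without prefix support.  The
other scripts in `examples/` demonstrate the majority rule
(`species_recognition.py`), prefixed-species resolution
(`prefixed_species.py`), the multistage normalizer
(`gene_normalization.py`) and the evaluator (`evaluate_predictions.py`).

A thin CLI mirrors the library:

```bash
biocspec fixtures --scenario hbach_sentence --seed 1 --out work
biocspec normalize --in work/hbach_sentence.xml --out work/norm.xml --config work/config.yaml
biocspec assign    --in work/hbach_sentence.xml --out work/assign.tsv --config work/config.yaml
biocspec eval --gold work/hbach_sentence.gold.xml --pred work/norm.xml --mode normalization
```

## Layout

```
src/biocspec/       bioc_io, nlp_pre, lexicon, species_recognizer,
                    gene_recognizer, gene_normalizer, species_assignment,
                    evaluation, fixtures, config, cli
examples/           one narrative script per capability
tests/              pytest suite (unit, property and end-to-end tests)
docs/methods.md     models, parameters, design choices, limitations
```
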