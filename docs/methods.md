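# Methods

This note records the models and procedures `biocspec` implements, the
parameters that matter, the numerical/tie-break choices, what the synthetic
fixtures do and do not emulate, and known limitations.

## Document model and processing order

Articles are BioC collections; passages carry 0-based document-level
character offsets and half-open spans `[offset, offset + length)`.  Raw
section headings are normalized case-insensitively by substring against a
fixed synonym table (e.g. "Background" → introduction, "Concluding
remarks" → conclusion; unknown → other) because real BioC corpora use
heterogeneous headings.

Recognition walks the article by information density rather than
structural order.  For species the full-text order is introduction,
discussion, abstract, methods, results, conclusion, other, title;
abstract-only documents use abstract then title.  Introduction-first and
titles-last are the load-bearing choices (definitions and first
unambiguous mentions cluster early; titles carry the least context); the
ranking of the middle sections is fixed only for determinism.  The gene
normalizer's stage 1 covers introduction, discussion and abstract; the
"remaining" order covers everything else in document order, titles last.
Within a section bucket, passages keep document order.

## Linguistic preprocessing

The builtin backend is rule-based and deterministic; the backend registry
accepts richer taggers, and a backend failure falls back to the builtin
rules with a warning rather than aborting.

* **Sentences** split at `.!?` followed by whitespace and an
  uppercase/digit start, guarded for single-capital-plus-period tokens
  ("E. coli") and a fixed list of non-final abbreviations (i.e., e.g.,
  et al., Fig., sp., ...).  Sentences jointly cover all non-whitespace text.
* **Tokens**: single capital + period is one token ("E."); hyphens are
  boundaries (so "anti-BACH" exposes "BACH" at a token boundary); `'` and
  `/` join word characters.
* **Base forms** come from a small irregular table plus plural/inflection
  suffix rules; the table covers the fixture vocabulary and common
  biomedical irregulars (mice → mouse).  Lemma conventions beyond that are
  not guaranteed.
* **PoS** is heuristic: a closed-class word list, digit detection and a
  small verb lexicon with `-s/-ed/-ing` inflection handling.  The pipeline
  only depends on verb detection (species false-positive filter), so full
  tagger fidelity is deliberately not a requirement.
* **Abbreviations** follow the Schwartz–Hearst long-form/short-form
  algorithm: a parenthesized short form (2–10 characters, at most two
  words, at least one letter) is matched right-to-left into at most
  `min(|short| + 5, 2·|short|)` preceding words; the character matched by
  the short form's first letter must start a word.  The anchor lands on
  the first qualifying word start, so "Calcium/calmodulin-dependent protein
  kinase II (CaMKII)" yields the long form starting at "calmodulin"; the
  downstream consistency checks compare case-insensitively and are
  unaffected.

## Lexicons

All lexicons are TSV (the format the upstream resources are distributed
in): species terms with semicolon-separated taxonomy IDs and
`general`/`genus` flags; organism codes (1–4 characters, full species
names retained, taxonomy ID optionally empty for curation-pending codes);
gene variants as `entrez_id:taxonomy_id` pairs (every Entrez ID must carry
its species); a ranked taxonomy-ID preference list.

Loading expands each species term with its base form and mechanical
variants (hyphen/space interchange; space removal for short abbreviated
terms).  Variants whose lowercase form is on the shipped, user-extensible
stop-list are suppressed — space removal can fabricate ordinary vocabulary
("K cat" → "kcat", the turnover number, which would otherwise be tagged as
the Korat cat breed).  Genus terms must map to exactly one ID: the
"most-frequently-mentioned member species" question is resolved at
lexicon-build time, not at run time.

**Case policy**: terms of length ≤ 4 and per-article author abbreviations
match case-sensitively (protects "AMV", "rat" vs "RAT"); longer terms
match case-insensitively (recall on "Human"/"human").  This balance is a
package decision; no universal rule exists.

## Species recognition

Matching is token-boundary longest-match: a dictionary term may be any
substring of a sentence but must align to token boundaries, which blocks
intra-word hits while allowing multi-word terms.  Shorter matches
overlapped by an accepted longer match are discarded, so emitted species
annotations never overlap.

Per-article state: (1) abbreviation pairs whose long-form base form is a
species term extend the dictionary for that article (the short form
inherits the long form's IDs, overriding static ambiguity — a defined
"E. coli" is pinned to its definition); failed pairs are blacklisted so
their short forms never match.  (2) Every successfully normalized instance
(including prefixes) is appended to the ID history.

Disambiguation of a multi-ID candidate: majority over the ID history
(strictly most frequent, counting instances, not distinct terms, across
all surface forms); ties or empty history fall to the preference list;
IDs absent from the list fall to the smallest numeric ID.  The provenance
(`unique`/`majority`/`preference`/`fallback`) is recorded as an infon.

False-positive filter: single-token candidates tagged as verbs are
dropped, as are candidates fully contained in a gene mention span.

General terms and genus names are retained only when a gene mention occurs
in the same sentence; the gate applies to both flags (toggle
`genus_requires_gene`).

**Prefixed species**: for each gene mention (skipping blacklisted ones),
codes are tried longest-first, 4 down to 1 characters — specific beats
generic ("Sc" before a hypothetical "S").  A code must be followed by an
uppercase letter (uniformly for all code lengths) and leave a remainder of
at least two characters.  If the article defines a full name for the gene,
that name must equal (case-insensitive exact comparison, not substring)
one of the code's species names, else the gene is blacklisted for prefix
matching.  Codes without a curated taxonomy ID can only reject, never emit.

**Sentence mode** processes each sentence with no article state: no
dictionary extension, no blacklists, no ID history (preference-only
disambiguation).  Prefix resolution still runs, using sentence-local
abbreviation pairs, since it needs only the gene mention itself; this is
an interpretation choice.  The mode exists to measure what article-level
processing buys.

## Gene recognition and refinement

The dictionary backend indexes gene variants under a normalization key
(lowercase, hyphens/spaces/underscores removed, spelled-out Greek letters
folded onto the letters) and scans with the same token-boundary
longest-match discipline; single candidates additionally try
organism-code prefix stripping ("hBACH" → "BACH").  Statistical taggers
plug in through the backend registry under the same contract.

Refinement: mentions with no candidate ID are dropped; surviving surface
forms become a per-article dictionary; an exact re-scan (alphanumeric
boundaries) adds overlooked occurrences with the same candidate IDs.
Existing spans take precedence, so the re-scan cannot create overlaps, and
the operation is idempotent.

## Multistage gene normalization

* **Stage 1** (introduction → discussion → abstract): single-candidate
  mentions are assigned directly.  Ambiguous mentions are resolved by
  same-sentence species context — if the taxonomy of exactly one candidate
  matches a species annotation in the sentence — then by the majority rule
  over the IDs already assigned (ties: smallest numeric Entrez ID).
  Mentions it cannot settle are skipped, not guessed.  Species context in
  stage 1 is toggleable (`species_context_in_stage1`, default on).
* **Stage 2** builds the article dictionary from stage-1 assignments and
  tags the whole article with raw substring matching (no token-boundary
  requirement — that is precisely what makes recognizer/tagger boundary
  disagreements representable).  Exact-span hits on unassigned mentions
  inherit the dictionary ID without re-matching; ambiguous hits carry the
  full ID set.  On a boundary disagreement: a determined ID is transferred
  to the recognizer mention (recognizer boundary wins); otherwise both
  spans are deferred.  Stage 2 never changes a stage-1 assignment.
* **Stage 3** processes the remaining sections with stage-1 logic, gives
  deferred hits and leftovers a final chance, then resolves overlaps by
  keeping the longest span (ties: leftmost), implemented greedily by
  descending length.  Mentions never normalized are excluded, with a
  logged count.

## Species assignment and evaluation

Rules apply in strict precedence: prefix; nearest same-sentence species
(character-gap distance between span boundaries, left candidates before
right ones, sentence-bounded — a sentence without species falls through to
rule 3 rather than looking at neighbors); focus species.  Focus is the
most frequent taxonomy ID over all species and prefix instances; count
ties follow 9606, 10090, 10116, 4932, 7227, 562, then smallest ID.  Rule 1
can be ablated (`use_prefix_rule=False`) to emulate taggers without
prefix support.

Evaluation is instance-level exact match: recognition mode keys on
(document, span), normalization mode on (document, span, ID); each gold
instance matches at most one prediction.  Annotations still carrying
several IDs count as non-matches in normalization mode (warned).  Species
and prefix annotations are scored in one pool; recognition mode does not
require type agreement.  Normalization scores are bounded above by
recognition scores on identical inputs.

## Fixtures

The generator emits eight template scenarios (each isolating one
behavior: majority rule, prefixes, abbreviation promotion, general-term
gating, genus-to-model mapping, stage-2 boundary conflict, a basic full
text, and the published hBACH sentence embedded verbatim) with gold
annotations by construction.  Documents are small — one to seven passages,
a handful of mentions — because each scenario is a unit of behavior, not a
corpus; the seed varies only neutral filler sentences, so generation is
byte-deterministic per (name, seed, params).  Taxonomy IDs are real NCBI
IDs; Entrez IDs are fixture-local synthetic integers with declared
species.  The fixtures deliberately do not emulate realistic language
statistics, OCR noise, nested entities, non-English text or full-scale
dictionary ambiguity, so passing tests demonstrate the mechanics of the
algorithms, not corpus-level accuracy on real literature.

## Limitations

* No statistical gene/species tagger ships with the package; the
  dictionary backends bound recall by lexicon coverage.
* The builtin lemmatizer and PoS tagger are heuristic; richer backends
  must be supplied by the user through the registries.
* The organism code list ships with both "Ath" → 3701 (genus-level) and
  "ath" → 3702 (species-level) entries for *Arabidopsis*, mirroring the
  upstream sources, which disagree at that granularity.
* Majority-rule history is article-global across surface forms; corpora
  in which one article genuinely mixes near-homonymous species would need
  a narrower history scope.
* Ingestion is BioC-only (no PDF/plain text), and BioC sentence elements
  are not consumed — sentences are always recomputed.
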