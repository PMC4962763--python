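"""Prefixed-species recognition inside gene symbols.

Authors mark a gene's organism with a short prefix code: "h" in hLysoPLA
means human (9606), "Sc" in ScUAP1 means budding yeast (4932).  The
recognizer checks the organism code lists longest-code-first, requires an
uppercase letter after the code, rejects one-character remainders ("hA"),
and blacklists genes whose author-defined full name contradicts the code
("CaMKII", defined as a protein kinase, is not a Coleophora gene).
"""

import tempfile

from biocspec import Lexicons, fixtures, recognize_genes, refine
from biocspec import recognize_species


def main() -> None:
    with tempfile.TemporaryDirectory() as tmp:
        fixtures.write_mini_lexicons(tmp)
        lexicons = Lexicons.from_dir(tmp)
        doc, _ = fixtures.generate(fixtures.Scenario(name="prefix_genes",
                                                     seed=1))
        mentions = refine(
            doc, recognize_genes(doc, lexicons.genes, codes=lexicons.codes),
            lexicons.genes)
        print("gene mentions:", [m.text for m in mentions])
        annotations = recognize_species(doc, lexicons,
                                        gene_mentions=mentions)
        for ann in annotations:
            if ann.type == "species_prefix":
                gene = next(m for m in mentions if m.offset == ann.offset)
                print(f"  prefix {ann.text!r} of {gene.text!r} -> "
                      f"taxonomy {ann.norm_ids[0]}")
    print("Only hLysoPLA and ScUAP1 yield prefixes: 'hA' has a one-letter "
          "remainder and CaMKII's defined full name fails the species-name "
          "consistency check.")


if __name__ == "__main__":
    main()
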