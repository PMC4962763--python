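import pytest

from biocspec import fixtures
from biocspec.gene_recognizer import recognize_genes, refine
from biocspec.lexicon import Lexicons
from biocspec import species_recognizer


@pytest.fixture(scope="session")
def lexicon_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("lexicons")
    fixtures.write_mini_lexicons(d)
    return d


@pytest.fixture(scope="session")
def lexicons(lexicon_dir) -> Lexicons:
    return Lexicons.from_dir(lexicon_dir)


@pytest.fixture
def scenario():
    def make(name, seed=1, **params):
        return fixtures.generate(
            fixtures.Scenario(name=name, seed=seed, params=params))
    return make


@pytest.fixture
def recognized(lexicons, scenario):
    """Scenario doc + refined gene mentions + species annotations."""
    def run(name, seed=1, mode="article"):
        doc, gold = scenario(name, seed=seed)
        mentions = refine(
            doc, recognize_genes(doc, lexicons.genes, codes=lexicons.codes),
            lexicons.genes)
        species = species_recognizer.recognize(
            doc, lexicons, mode=mode, gene_mentions=mentions)
        return doc, gold, mentions, species
    return run
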