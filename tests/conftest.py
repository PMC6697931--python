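import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from clinrank.annotate import GeneLexicon, DrugLexicon
from clinrank.synth import GeneratorConfig, generate_corpus


@pytest.fixture
def gene_lex() -> GeneLexicon:
    lex = GeneLexicon(kind="gene")
    lex.add("673", "BRAF", ["BRAF", "B-RAF1"])
    lex.add("3845", "KRAS", ["KRAS", "KRAS2"])
    lex.add("7157", "TP53", ["TP53", "p53"])
    return lex


@pytest.fixture
def drug_lex() -> DrugLexicon:
    lex = DrugLexicon(kind="drug")
    lex.add("DB08881", "Vemurafenib", ["Vemurafenib"])
    lex.add("DB01229", "Paclitaxel", ["paclitaxel"])
    lex.add("DB01234", "nab-Paclitaxel", ["nab-paclitaxel"])
    return lex


@pytest.fixture(scope="session")
def small_bundle():
    """A 250-document synthetic corpus shared across read-only tests."""
    return generate_corpus(GeneratorConfig(n_docs=250, seed=11))
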