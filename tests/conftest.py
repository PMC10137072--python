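import pytest
from hypothesis import settings

from levelmap import (
    Category,
    Dictionary,
    DictionaryTerm,
    EvidenceFragment,
    default_dictionary,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dictionary() -> Dictionary:
    return default_dictionary()


@pytest.fixture
def tiny_dictionary() -> Dictionary:
    """A minimal dictionary with one substring term per category plus a
    whole-word trap."""
    return Dictionary(
        [
            DictionaryTerm("pcr", Category.DNA_RNA),
            DictionaryTerm("western blot", Category.PROTEIN),
            DictionaryTerm("metabolomics", Category.METABOLITE),
            DictionaryTerm("gag", Category.DNA_RNA, whole_word_only=True),
        ]
    )


def make_fragment(text: str, fragment_id: str = "f1", **kwargs) -> EvidenceFragment:
    defaults = dict(
        fragment_id=fragment_id,
        target_ensembl_id="ENSG00000000001",
        target_name="GENE1",
        disease_id="EFO_0000001",
        pmid="12345678",
        text=text,
    )
    defaults.update(kwargs)
    return EvidenceFragment(**defaults)


@pytest.fixture
def fragment_factory():
    return make_fragment
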