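import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def sentence_factory():
    """Build a standalone Sentence from raw text."""
    from famhx.docmodel import Sentence

    def make(text: str, index: int = 0) -> Sentence:
        return Sentence(doc_id="t", index=index, start=0, end=len(text), text=text)

    return make


@pytest.fixture(scope="session")
def small_corpus():
    """A 30-note synthetic corpus with gold, shared across tests."""
    from famhx.synthgen import GenConfig, generate_corpus

    return generate_corpus(GenConfig(n_docs=30, seed=11))
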