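"""Deterministic fixture corpora for regression tests and examples.

The fixture is generated on demand from a fixed seed rather than shipped as
a file; repeated calls produce byte-identical corpora.
"""

from __future__ import annotations

from .corpus import Document
from .synth import SynthConfig, generate_corpus

FIXTURE_SEED = 13


def fixture_config(n_documents: int = 400) -> SynthConfig:
    return SynthConfig(n_documents=n_documents, seed=FIXTURE_SEED)


def fixture_corpus(n_documents: int = 400) -> list[Document]:
    """The packaged regression corpus: seed 13, 400 synthetic documents."""
    return generate_corpus(fixture_config(n_documents))
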