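import datetime as dt

import pytest

from adapt_bfdp.keyword_corpus import Document, GeneDocument, KeywordConfig


@pytest.fixture
def keyword_config() -> KeywordConfig:
    return KeywordConfig(
        g1=["oral cancer", "mouth neoplasm"],
        g2=["smoking", "alcohol"],
        g3=["carcinogen", "apoptosis", "dna damage"],
    )


@pytest.fixture
def gene_with_docs() -> GeneDocument:
    return GeneDocument(
        gene_id="G1",
        symbol="ADH7",
        chrom="4",
        start=100_000,
        end=120_000,
        documents=[
            Document(
                doc_id="PM1",
                text="Oral cancers were linked to apoptosis in cultured cells.",
                date=dt.date(2006, 3, 1),
            )
        ],
    )
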