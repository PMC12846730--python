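import numpy as np
import pandas as pd
import pytest

from cminet.datatypes import AbundanceTable, ExpressionMatrix, SampleMetadata


@pytest.fixture
def toy_abundance() -> AbundanceTable:
    data = pd.DataFrame(
        {
            "g__TaxA": [5, 0, 3, 8],
            "g__TaxB": [1, 2, 0, 4],
            "g__TaxC": [0, 0, 7, 1],
        },
        index=["S1", "S2", "S3", "S4"],
    )
    return AbundanceTable(data)


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    data = pd.DataFrame(
        {
            "S1": [4.0, 1.0, 0.5],
            "S2": [3.0, 2.0, 0.0],
            "S3": [2.0, 3.0, 1.5],
            "S4": [1.0, 4.0, 2.0],
        },
        index=["GENE1", "GENE2", "GENE3"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def paired_metadata() -> SampleMetadata:
    data = pd.DataFrame(
        {
            "pair_id": ["P1", "P1", "P2", "P2"],
            "phenotype": ["T", "PT", "T", "PT"],
        },
        index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"),
    )
    return SampleMetadata(data)
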