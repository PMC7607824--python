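import numpy as np
import pandas as pd
import pytest

from phenoclust.phenotypes import (
    ALL_TRAITS,
    CATEGORICAL_TRAITS,
    PhenotypeTable,
    default_schema,
)

#: Column values of an entirely wild-type-looking mutant.
WILD_TYPE = {
    "growth_rate": 80.0,
    "aerial_height": 37.0,
    **{t: "Normal" for t in CATEGORICAL_TRAITS},
}


def make_record(gene_id: str, **overrides) -> dict:
    row = {"gene_id": gene_id, **WILD_TYPE}
    row.update(overrides)
    return row


def make_table(rows) -> PhenotypeTable:
    """Build a PhenotypeTable from make_record dicts."""
    return PhenotypeTable(schema=default_schema(), data=pd.DataFrame(rows))


@pytest.fixture
def wild_type_row():
    return dict(WILD_TYPE)


@pytest.fixture
def toy_table():
    """Three complete records spanning both trait kinds."""
    return make_table(
        [
            make_record("NCU00001", growth_rate=75.0, aerial_height=30.0),
            make_record(
                "NCU00002",
                growth_rate=80.0,
                aerial_height=30.0,
                conidia_number="Reduced",
            ),
            make_record(
                "NCU00003",
                growth_rate=85.0,
                aerial_height=45.0,
                conidia_number="Not Formed",
                ascospore_morphology="Abnormal",
            ),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
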