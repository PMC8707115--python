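from importlib import resources
from pathlib import Path

import pandas as pd
import pytest

from attakaryo import karyomorphometry as km
from attakaryo import phylo_traits as pt
from attakaryo import records as rec

MORPH_NAME_TO_CODE = {
    "Metacentric": "m",
    "Submetacentric": "sm",
    "Subtelocentric": "st",
    "Telocentric": "t",
}

KARYOTABLE_NAMES = (
    "mycocepurus_goeldii",
    "myrmicocrypta_sp",
    "cyphomyrmex_transversus",
    "apterostigma_madidiense",
)


def load_karyotable(name: str) -> pd.DataFrame:
    ref = resources.files("attakaryo.data").joinpath(f"karyotable_{name}.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


@pytest.fixture(scope="session")
def reference_records():
    return rec.load_reference_records()


@pytest.fixture(scope="session")
def karyotables():
    return {name: load_karyotable(name) for name in KARYOTABLE_NAMES}


@pytest.fixture(scope="session")
def reference_tree():
    return pt.load_reference_tree()


@pytest.fixture(scope="session")
def annotated_tree(reference_tree, reference_records):
    traits = pt.TraitTable.from_pairs(rec.records_to_traits(reference_records))
    return pt.attach_traits(reference_tree, traits)


def spread_from_table(df: pd.DataFrame, spread_id: str = "table") -> km.MetaphaseSpread:
    """A noise-free spread whose arm pairs equal a table's mean L/S columns."""
    return km.MetaphaseSpread(
        spread_id=spread_id,
        measurements=tuple(
            km.ArmMeasurement(row.mean_L, row.mean_S) for row in df.itertuples()
        ),
    )
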