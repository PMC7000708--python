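import numpy as np
import pandas as pd
import pytest

from zoosem.composition import HoldingsMatrix


def make_holdings(rows):
    """rows: (institution, species, genus, family, order, vclass, count, iucn, mass)"""
    table = pd.DataFrame(
        rows,
        columns=[
            "institution_id",
            "species_id",
            "genus",
            "family",
            "order",
            "vclass",
            "count",
            "iucn",
            "body_mass_g",
        ],
    )
    return HoldingsMatrix.from_long(table)


@pytest.fixture
def two_species_holdings():
    """One institution: a mammal (2 individuals, LC) and a bird (2, EN)."""
    return make_holdings(
        [
            ("zooA", "spA", "gA", "fA", "oA", "Mammalia", 2, "LC", 3000.0),
            ("zooA", "spB", "gB", "fB", "oB", "Aves", 2, "EN", 500.0),
        ]
    )


@pytest.fixture
def three_zoo_holdings():
    """Three institutions over a four-species pool, hand-enumerable."""
    return make_holdings(
        [
            ("zoo1", "s1", "g1", "f1", "o1", "Mammalia", 2, "LC", 1000.0),
            ("zoo1", "s2", "g1", "f1", "o1", "Aves", 1, "VU", 200.0),
            ("zoo2", "s1", "g1", "f1", "o1", "Mammalia", 3, "LC", 1000.0),
            ("zoo2", "s3", "g2", "f1", "o1", "Reptilia", 2, "EN", 50.0),
            ("zoo3", "s2", "g1", "f1", "o1", "Aves", 4, "VU", 200.0),
            ("zoo3", "s4", "g3", "f2", "o1", "Amphibia", 1, "CR", 10.0),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
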