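import numpy as np
import pytest

from cx3track.scoring import BiomarkerSeries
from cx3track.repertoire import ClonotypeKey, ClonotypeTable


@pytest.fixture
def toy_series():
    return BiomarkerSeries("P1", ((0, 20.0), (3, 25.0), (6, 35.0)))


@pytest.fixture
def baseline_only_series():
    return BiomarkerSeries("P2", ((0, 30.9),))


def make_table(entries, compartment="blood", week=0.0):
    keyed = {
        ClonotypeKey(cdr3, "TRBV5", "TRBJ2-1"): c for cdr3, c in entries.items()
    }
    return ClonotypeTable(compartment, week, keyed)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
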