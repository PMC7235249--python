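import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pamprospector.records import DnaRecord, ProteinRecord, SpacerRecord
from pamprospector import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reference_protein():
    """A 360-residue random reference standing in for a Cas9-scale protein."""
    return syn.random_protein(360, seed=42, id="reference")


@pytest.fixture
def toy_genome():
    # spacer planted at [20, 40) with flank TTCAAGGA immediately 3'
    return DnaRecord(
        "toy", "T" * 20 + "ACGTACGTACGTACGTAAAT" + "TTCAAGGA" + "C" * 12)


@pytest.fixture
def toy_spacer():
    return SpacerRecord("sp1", "ACGTACGTACGTACGTAAAT")


def random_dna_string(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
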