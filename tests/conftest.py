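import numpy as np
import pytest

from pmiscale.io import LabeledExample, SequenceRecord
from pmiscale.scales import builtin_scale


@pytest.fixture(scope="session")
def pmi():
    return builtin_scale("PMIscale")


@pytest.fixture(scope="session")
def kd():
    return builtin_scale("KD")


def make_example(ident: str, label: str, seq: str, segments=()):
    return LabeledExample(SequenceRecord(ident, "", seq), label, tuple(segments))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    from pmiscale.scales import CANONICAL_RESIDUES

    return "".join(rng.choice(list(CANONICAL_RESIDUES), size=length))


@pytest.fixture(scope="session")
def inverted_config():
    """Generator settings with swapped hydrophobicity: TM cores polar,
    SP h-regions hydrophobic — the worst case for a hydropathy scale
    started at Kyte–Doolittle."""
    from pmiscale.synthetic import GeneratorConfig

    zero = {aa: 0.0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
    return GeneratorConfig(
        seed=5,
        composition_tm={**zero, "D": 0.16, "E": 0.16, "N": 0.12, "Q": 0.12, "K": 0.10, "R": 0.10, "S": 0.12, "P": 0.06, "G": 0.06},
        composition_sp_h={**zero, "L": 0.30, "I": 0.25, "V": 0.20, "F": 0.15, "W": 0.05, "Y": 0.05},
    )
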