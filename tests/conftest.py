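import numpy as np
import pytest

from isomirkit.refdata import MatureEntry, ReferenceSet
from isomirkit.simulate import SimConfig, generate_reference


@pytest.fixture
def toy_ref():
    """One mature 'TGAGG' at [2, 7) inside hairpin 'CCTGAGGAAG'.

    Downstream template is 'AAG', so a trailing 'A' is templated while a
    trailing 'T' is a non-templated uridine.
    """
    entry = MatureEntry("toy-miR-1", "TGAGG", "toy-mir-1", 2, 7, "5p")
    return ReferenceSet(entries=[entry], hairpins={"toy-mir-1": "CCTGAGGAAG"})


@pytest.fixture
def twin_ref():
    """Two miRNAs with identical mature sequences (multi-mapping)."""
    hp = "CCCCTGAGGTAGTAGGTTGTATAGTTCCCC"
    mature = hp[4:26]
    entries = [
        MatureEntry("twin-miR-a", mature, "twin-a", 4, 26, "5p"),
        MatureEntry("twin-miR-b", mature, "twin-b", 4, 26, "5p"),
    ]
    return ReferenceSet(entries=entries, hairpins={"twin-a": hp, "twin-b": hp})


@pytest.fixture
def sim_ref():
    return generate_reference(SimConfig(n_mirnas=10, seed=11))


def random_read(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
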