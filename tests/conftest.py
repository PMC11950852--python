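import numpy as np
import pytest

from rapidsim.kinetics import KineticParams
from rapidsim.library import DEFAULT_DESIGN
from rapidsim.selection import LibraryState, PeptideSpecies


@pytest.fixture(scope="session")
def design():
    return DEFAULT_DESIGN


@pytest.fixture()
def two_species_state():
    """Equal-count pool of one slow-off and one fast-off binder."""
    slow = PeptideSpecies(
        id="slow", peptide="ySLOWC", kinetics=KineticParams(5.9e5, 4.2e-3)
    )
    fast = PeptideSpecies(
        id="fast", peptide="yFASTC", kinetics=KineticParams(5.7e5, 45e-3)
    )
    return LibraryState(
        species={"slow": slow, "fast": fast},
        counts={"slow": 100_000, "fast": 100_000},
    )


def rand_index(labels_a, labels_b, ids):
    """Rand index between two labelings over the same id set."""
    import itertools

    agree = total = 0
    for x, y in itertools.combinations(ids, 2):
        same_a = labels_a[x] == labels_a[y]
        same_b = labels_b[x] == labels_b[y]
        agree += same_a == same_b
        total += 1
    return agree / total if total else 1.0
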