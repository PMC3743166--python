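import numpy as np
import pytest

from groovebind import builder

DEFAULT_SEQUENCE = "CGCGAATTCGCG"

#: Published per-run ensemble-averaged NOE distances (A) for the three
#: assigned intermolecular NOEs of a binuclear-Ru / [d(CGCGAATTCGCG)]2
#: complex, ten unrestrained 5 ns MD runs; used as printed-table input for
#: the violation-check logic.
REFERENCE_DNOE_LIMITS = [5.0, 3.5, 3.5]
REFERENCE_DNOE_RUNS = np.array(
    [
        [5.4, 4.2, 5.7, 4.9, 5.0, 4.6, 4.6, 5.5, 5.7, 4.6],
        [2.7, 2.8, 2.9, 2.7, 2.8, 2.7, 2.8, 3.1, 2.8, 2.7],
        [3.2, 3.6, 3.4, 3.0, 3.1, 3.0, 2.9, 3.5, 2.4, 2.9],
    ]
)


@pytest.fixture(scope="session")
def duplex():
    return builder.build_bdna(DEFAULT_SEQUENCE)


@pytest.fixture(scope="session")
def ligand():
    return builder.build_ligand()


@pytest.fixture(scope="session")
def complex_model(duplex, ligand):
    return builder.place_in_minor_groove(duplex, ligand)


@pytest.fixture(scope="session")
def small_ensemble(complex_model):
    return builder.generate_ensemble(complex_model, 10, 0.2, (0.1, 1.0), seed=42)
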