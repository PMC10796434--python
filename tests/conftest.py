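import numpy as np
import pytest

from dacs_augment.core_io import DrugRecord, ResponseMatrix, SynergyRecord, TargetMap
from dacs_augment.fingerprints import Fingerprint
from dacs_augment.synthetic_data import SimConfig, simulate

SMILES_LIBRARY = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("benzene", "c1ccccc1"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("ethanol", "CCO"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    ("naproxen", "COc1ccc2cc(ccc2c1)C(C)C(=O)O"),
]


def make_fp(bits, n_bits=16):
    return Fingerprint(bits=frozenset(bits), n_bits=n_bits, backend="test")


def random_fingerprint(rng, n_bits=64, density=0.3):
    n_set = max(1, int(n_bits * density))
    return make_fp(rng.choice(n_bits, size=n_set, replace=False).tolist(), n_bits=n_bits)


@pytest.fixture
def smiles_csv(tmp_path):
    path = tmp_path / "library.csv"
    lines = ["drug_id,smiles"] + [f"{d},{s}" for d, s in SMILES_LIBRARY]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_library():
    """Four drugs with hand-set 16-bit fingerprints."""
    return {
        "a": DrugRecord("a", fingerprint=make_fp({1, 2, 3})),
        "b": DrugRecord("b", fingerprint=make_fp({2, 3, 4})),
        "c": DrugRecord("c", fingerprint=make_fp({1, 2, 3})),
        "d": DrugRecord("d", fingerprint=make_fp({10, 11})),
    }


@pytest.fixture
def toy_target_map():
    return TargetMap(
        associations={"a": frozenset({"p1", "p2"}), "b": frozenset({"p2", "p3"}),
                      "c": frozenset({"p1", "p2"}), "d": frozenset({"p9"})},
        universe_size=10,
        universe=frozenset(f"p{i}" for i in range(10)))


@pytest.fixture
def toy_responses():
    entries = {}
    for drug, values in [("a", [5.0, 6.0, 7.0, 8.0]), ("b", [5.1, 6.2, 7.1, 8.3]),
                         ("c", [5.0, 6.1, 7.2, 8.1]), ("d", [8.0, 7.0, 6.0, 5.0])]:
        for i, v in enumerate(values):
            entries[(drug, f"cl{i}")] = v
    tissues = {f"cl{i}": ("breast" if i < 2 else "lung") for i in range(4)}
    return ResponseMatrix(entries=entries, cell_line_tissue=tissues)


@pytest.fixture
def toy_synergy():
    return [
        SynergyRecord("a", "b", "cl0", 30.0, "breast"),
        SynergyRecord("a", "d", "cl1", -30.0, "breast"),
        SynergyRecord("b", "c", "cl2", 25.0, "lung"),
        SynergyRecord("c", "d", "cl3", -25.0, "lung"),
    ]


@pytest.fixture(scope="session")
def sim_default():
    """Default planted-cluster bundle, shared read-only across tests."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_noisy():
    return simulate(SimConfig(
        n_clusters=6, drugs_per_cluster=4, within_cluster_bit_overlap=0.75,
        within_cluster_target_overlap=0.75, response_noise_sd=0.4,
        synergy_noise_sd=8.0, cells_per_pair=2, seed=23))
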