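import numpy as np
import pytest

from bicompdta.alignment import AlignmentScheme
from bicompdta.records import AffinityDataset, AffinityRecord, LigandRecord, ProteinRecord
from bicompdta.synthetic import SyntheticSpec, generate_dataset, generate_proteins


@pytest.fixture(scope="session")
def simple_scheme():
    """Match +2 / mismatch -1 with unit gap penalties."""
    return AlignmentScheme.simple(match=2.0, mismatch=-1.0, gap_open=1.0, gap_extend=1.0)


@pytest.fixture(scope="session")
def blosum_scheme():
    return AlignmentScheme.blosum62()


@pytest.fixture(scope="session")
def family_panel():
    """3 families x 10 members, length 400, mutation rate 0.1 (the planted-family study panel)."""
    spec = SyntheticSpec(n_families=3, members_per_family=10,
                         protein_length=400, mutation_rate=0.1, seed=11)
    return generate_proteins(spec)


@pytest.fixture(scope="session")
def small_dataset():
    """A small full-grid dataset for split and pipeline tests."""
    spec = SyntheticSpec(n_families=3, members_per_family=6, protein_length=80,
                         n_ligands=12, noise_sd=0.3, seed=5)
    ds, truth = generate_dataset(spec)
    return ds, truth


@pytest.fixture
def tiny_dataset():
    """Hand-built 2-protein x 2-ligand dataset with 3 affinity records."""
    proteins = [ProteinRecord("p1", "MKVLAA"), ProteinRecord("p2", "MKWWAA")]
    ligands = [LigandRecord("l1", "CCO"), LigandRecord("l2", "CN=O")]
    records = [
        AffinityRecord("p1", "l1", 7.0),
        AffinityRecord("p1", "l2", 5.5),
        AffinityRecord("p2", "l1", 6.2),
    ]
    return AffinityDataset(proteins=proteins, ligands=ligands, records=records)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
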