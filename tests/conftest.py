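import numpy as np
import pytest

from bidkit.io_formats import ChainRecord, ChainRole, ComplexRecord
from bidkit.synthetic import SyntheticConfig, generate_cluster, ideal_peptide


def make_chain(chain_id, role, sequence, atom_coords, atom_residue,
               names=None, elements=None):
    atom_coords = np.asarray(atom_coords, dtype=float)
    atom_residue = np.asarray(atom_residue, dtype=int)
    n_res = len(sequence)
    if names is None:
        names = []
        seen = {}
        for r in atom_residue:
            k = seen.get(r, 0)
            names.append("CA" if k == 0 else f"C{k}")
            seen[r] = k + 1
    names = np.asarray(names, dtype="U6")
    if elements is None:
        elements = np.full(len(atom_coords), "C", dtype="U4")
    ca = np.full((n_res, 3), np.nan)
    for i in range(n_res):
        sel = (atom_residue == i) & (names == "CA")
        if sel.any():
            ca[i] = atom_coords[sel][0]
    return ChainRecord(chain_id=chain_id, role=role, sequence=sequence,
                       atom_coords=atom_coords, atom_elements=np.asarray(elements, dtype="U4"),
                       atom_names=names, atom_residue=atom_residue, ca_coords=ca)


def make_two_chain_complex(antigen_coords, antibody_coords, antigen_seq=None,
                           resolution=2.0, r_factor=0.2, complex_id="fix"):
    """Antigen + antibody complex with one atom per residue (CA)."""
    antigen_coords = np.asarray(antigen_coords, dtype=float)
    antibody_coords = np.asarray(antibody_coords, dtype=float)
    n_ag, n_ab = len(antigen_coords), len(antibody_coords)
    ag = make_chain("A", ChainRole.ANTIGEN, antigen_seq or "A" * n_ag,
                    antigen_coords, np.arange(n_ag))
    ab = make_chain("H", ChainRole.ANTIBODY_SINGLE, "G" * n_ab,
                    antibody_coords, np.arange(n_ab))
    return ComplexRecord(complex_id=complex_id, chains=[ag, ab],
                         resolution=resolution, r_factor=r_factor)


@pytest.fixture(scope="session")
def small_cluster():
    """One deterministic synthetic cluster (depth 6) shared across tests."""
    cfg = SyntheticConfig(seed=42, chain_length=80)
    records, truth = generate_cluster(cfg, cluster_id="fixture", depth=6)
    return records, truth


@pytest.fixture(scope="session")
def helix_chain():
    return ideal_peptide("A" * 15)


@pytest.fixture(scope="session")
def extended_chain():
    return ideal_peptide("A" * 15, phi=-120.0, psi=130.0)
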