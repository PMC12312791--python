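import numpy as np
import pytest

from druggability import SimConfig, generate_dataset


def atom_line(serial, name, altloc, resname, chain, resseq, x, y, z, occ, record="ATOM"):
    """One fixed-column PDB coordinate line."""
    return (
        f"{record:<6s}{serial:>5d} {name:^4s}{altloc:1s}{resname:>3s} {chain}"
        f"{resseq:>4d}    {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{0.0:>6.2f}"
        f"           {name.strip()[0]:>1s}"
    )


@pytest.fixture
def toy_pdb(tmp_path):
    """Chain A: 3 CA residues (one with altlocs); chain B: 2 residues;
    plus 2 waters and a zinc as HETATM."""
    lines = [
        atom_line(1, "N", " ", "ALA", "A", 1, 0.0, 0.0, 0.0, 1.0),
        atom_line(2, "CA", " ", "ALA", "A", 1, 1.0, 0.0, 0.0, 1.0),
        atom_line(3, "CA", "A", "GLY", "A", 2, 4.0, 0.0, 0.0, 0.4),
        atom_line(4, "CA", "B", "GLY", "A", 2, 4.5, 0.0, 0.0, 0.6),
        atom_line(5, "CA", " ", "SER", "A", 3, 8.0, 0.0, 0.0, 1.0),
        atom_line(6, "CA", " ", "LEU", "B", 1, 0.0, 5.0, 0.0, 1.0),
        atom_line(7, "CA", " ", "VAL", "B", 2, 3.8, 5.0, 0.0, 1.0),
        atom_line(8, "O", " ", "HOH", "A", 101, 9.0, 9.0, 9.0, 1.0, record="HETATM"),
        atom_line(9, "O", " ", "HOH", "A", 102, 9.0, 9.0, 12.0, 1.0, record="HETATM"),
        atom_line(10, "ZN", " ", "ZN", "A", 103, 5.0, 5.0, 5.0, 1.0, record="HETATM"),
        "END",
    ]
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def small_sim():
    """A small separable dataset shared across fast tests."""
    return generate_dataset(
        SimConfig(
            n_pos=60,
            n_neg=60,
            embed_dim=16,
            n_informative=4,
            effect_size=3.0,
            n_go_terms=30,
            n_enriched_go=5,
            seq_length_range=(30, 80),
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions (600 proteins, 10/64 informative dims)."""
    return generate_dataset(SimConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
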