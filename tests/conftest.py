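import numpy as np
import pytest

import inpa


def atom_line(
    serial, name, resname, chain, resseq, x, y, z,
    altloc=" ", occ=1.0, element="C", record="ATOM", icode=" ",
):
    """Format one fixed-column PDB coordinate record."""
    return (
        f"{record:<6}{serial:>5} {name:^4}{altloc}{resname:<3} "
        f"{chain}{resseq:>4}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2}"
    )


@pytest.fixture
def pdb_3res(tmp_path):
    """Minimal 3-residue chain with non-CA and HETATM records to ignore."""
    lines = [
        atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, element="N"),
        atom_line(2, "CA", "ALA", "A", 1, 1.000, 2.000, 3.000),
        atom_line(3, "CA", "GLY", "A", 2, 4.500, 5.250, 6.125),
        atom_line(4, "CA", "SER", "A", 3, 7.125, 8.000, 9.750),
        atom_line(5, "O", "HOH", "A", 90, 1.0, 1.0, 1.0, record="HETATM", element="O"),
        "END",
    ]
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def pdb_altloc(tmp_path):
    """Residue 2 carries altloc A (occ 0.60) and B (occ 0.40)."""
    lines = [
        atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
        atom_line(2, "CA", "GLY", "A", 2, 1.000, 0.000, 0.000, altloc="A", occ=0.60),
        atom_line(3, "CA", "GLY", "A", 2, 9.000, 9.000, 9.000, altloc="B", occ=0.40),
        atom_line(4, "CA", "SER", "A", 3, 2.000, 0.000, 0.000),
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def pdb_2chains(tmp_path):
    lines = [
        atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
        atom_line(2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0),
        "TER",
        atom_line(3, "CA", "LEU", "B", 1, 0.0, 5.0, 0.0),
        atom_line(4, "CA", "VAL", "B", 2, 3.8, 5.0, 0.0),
        "END",
    ]
    path = tmp_path / "two_chains.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def helix50():
    return inpa.make_helix(50)


@pytest.fixture
def helix50_network(helix50):
    """Default-material network of a 50-residue helix at R_C = 6 Å."""
    graph = inpa.build_graph(helix50, 6.0)
    elements = inpa.assign_elements(graph, inpa.MaterialParams())
    contact = inpa.point_contacts(graph.n_nodes)
    return graph, elements, contact


def random_point_chain(n, box, seed, min_sep=0.5):
    """Random Cα positions in a cubic box (rejecting near-coincidences)."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, box, size=(n, 3))
    from scipy.spatial.distance import pdist

    while pdist(pts).min() < min_sep:  # pragma: no cover - rare
        pts = rng.uniform(0, box, size=(n, 3))
    return inpa.CalphaChain(
        resnames=["ALA"] * n,
        chain_ids=["A"] * n,
        seq_ids=np.arange(1, n + 1),
        coords=pts,
    )
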