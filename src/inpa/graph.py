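"""Interaction-radius contact graphs.

Two residues are linked whenever the distance between their Cα atoms is
strictly less than the interaction radius R_C, so the structure becomes a
set of intercrossing spheres.  Each link carries its length l_ij and the
cross-sectional area between the two spheres,

    A_ij = π (R_C² − l_ij² / 4),

which is what turns the topology into an electrical network downstream.
All geometry here is in Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import CalphaChain

__all__ = ["ProteinGraph", "build_graph", "is_connected", "rc_saturation_scan"]


@dataclass
class ProteinGraph:
    """Contact network of a Cα chain at a given interaction radius.

    Attributes
    ----------
    coords : ndarray (n, 3), Å
    resnames : list of str
    edges : ndarray (m, 2) of int
        Unordered node pairs, i < j, each at most once.
    lengths : ndarray (m,), Å
    areas : ndarray (m,), Å²
    r_c : float, Å
    """

    coords: np.ndarray
    resnames: list[str]
    edges: np.ndarray
    lengths: np.ndarray
    areas: np.ndarray
    r_c: float

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_links(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    def to_edge_csv(self, path: str | Path) -> None:
        """Export the edge list as CSV ``i,j,l_ij,A_ij`` (Å, Å²)."""
        import pandas as pd

        pd.DataFrame(
            {
                "i": self.edges[:, 0],
                "j": self.edges[:, 1],
                "l_ij": self.lengths,
                "A_ij": self.areas,
            }
        ).to_csv(path, index=False)


def build_graph(chain: CalphaChain, r_c: float) -> ProteinGraph:
    """Link every residue pair closer than ``r_c`` (strict inequality).

    Coincident nodes are rejected: the elemental impedance degenerates at
    zero link length and real Cα traces never coincide.
    """
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    coords = chain.coords
    if len(coords) < 2:
        raise ValueError("need at least 2 nodes")
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=r_c, output_type="ndarray")
    if len(pairs):
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
        lengths = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        keep = lengths < r_c  # query_pairs may include the boundary
        pairs, lengths = pairs[keep], lengths[keep]
    else:
        pairs = np.empty((0, 2), dtype=int)
        lengths = np.empty(0)
    if np.any(lengths == 0.0):
        raise ValueError("coincident Cα positions (zero-length link)")
    areas = np.pi * (r_c**2 - lengths**2 / 4.0)
    return ProteinGraph(
        coords=coords.copy(),
        resnames=list(chain.resnames),
        edges=pairs,
        lengths=lengths,
        areas=areas,
        r_c=float(r_c),
    )


def is_connected(graph: ProteinGraph, source: int, sink: int) -> bool:
    """True iff a path of links joins ``source`` and ``sink``."""
    n = graph.n_nodes
    if not (0 <= source < n and 0 <= sink < n):
        raise IndexError("node index out of range")
    if source == sink:
        return True
    if graph.n_links == 0:
        return False
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    adj = sp.coo_matrix(
        (np.ones(graph.n_links), (graph.edges[:, 0], graph.edges[:, 1])),
        shape=(n, n),
    )
    _, labels = connected_components(adj, directed=False)
    return bool(labels[source] == labels[sink])


def rc_saturation_scan(
    chain: CalphaChain,
    rc_values: Sequence[float],
    material=None,
):
    """Scan the interaction radius: link count and a static-impedance proxy.

    For each R_C the contact graph is rebuilt and, where the first and last
    node are connected, the two-terminal Z(0) with point contacts is solved
    (uniform material unless ``material`` is given); disconnected radii
    report ``inf``.  Once R_C exceeds the structure's diameter the graph is
    complete and both columns stop changing.

    Returns a DataFrame with columns ``rc, link_count, z0_ohm``.
    """
    import pandas as pd

    rc_values = list(rc_values)
    if not rc_values:
        raise ValueError("rc_values must be non-empty")
    if any(r <= 0 for r in rc_values):
        raise ValueError("rc_values must be positive")
    if any(b <= a for a, b in zip(rc_values, rc_values[1:])):
        raise ValueError("rc_values must be strictly increasing")

    from .impedance import MaterialParams, assign_elements
    from .solver import DisconnectedNetworkError, point_contacts, solve_impedance

    params = material if material is not None else MaterialParams()
    rows = []
    for rc in rc_values:
        g = build_graph(chain, rc)
        if g.n_links == 0 or not is_connected(g, 0, g.n_nodes - 1):
            z0 = np.inf
        else:
            elements = assign_elements(g, params)
            contact = point_contacts(g.n_nodes)
            try:
                z0 = float(solve_impedance(elements, contact, 0.0).real)
            except DisconnectedNetworkError:
                z0 = np.inf
        rows.append({"rc": rc, "link_count": g.n_links, "z0_ohm": z0})
    return pd.DataFrame(rows)
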