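"""Elemental RC impedances for contact-network links.

Each link between residues i and j is a resistor in parallel with a
capacitor, lumped into the complex impedance

    Z_ij(ω) = (l_ij / A_ij) · 1 / (1/ρ + i ε_ij ε₀ ω),

with l_ij the link length, A_ij the inter-sphere cross-section, ρ a single
resistivity shared by all amino acids (default 10¹⁰ Ω·m, an indicative
value — the microscopic transfer mechanism is deliberately unspecified),
and ε_ij a relative dielectric constant combined from the two residues'
per-residue values.  Geometry arrives in Å/Å² and is converted to SI here,
exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.constants import epsilon_0

__all__ = [
    "MaterialParams",
    "LinkElement",
    "link_impedance",
    "assign_elements",
    "load_eps_table",
    "default_eps_table",
]

_ANG = 1e-10  # m per Å


def load_eps_table(path: str | Path) -> dict[str, float]:
    """Read a per-residue dielectric table: lines ``RESNAME eps``, ``#`` comments."""
    table: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed dielectric table line: {raw!r}")
        name, value = parts[0].upper(), float(parts[1])
        if value < 1:
            raise ValueError(f"relative dielectric constant < 1 for {name}")
        table[name] = value
    return table


def default_eps_table() -> dict[str, float]:
    """The dielectric table shipped with the package (flat ε = 4)."""
    from importlib.resources import files

    return load_eps_table(files("inpa") / "data" / "eps_default.txt")


@dataclass
class MaterialParams:
    """Electrical material parameters of the network.

    Parameters
    ----------
    rho : float
        Resistivity in Ω·m, shared by all links.  Default 1e10.
    eps_table : mapping residue code -> relative dielectric constant.
        Defaults to the shipped flat table (ε = 4 for the 20 standard
        amino acids).
    eps_default : float or None
        Fallback ε for residues missing from the table; ``None`` makes an
        unknown residue an error.
    combine : {'arithmetic', 'geometric'}
        How the two residues' ε values are combined into the link's ε_ij.
    """

    rho: float = 1e10
    eps_table: Mapping[str, float] = field(default_factory=default_eps_table)
    eps_default: float | None = 4.0
    combine: str = "arithmetic"
    table_name: str = "builtin-flat-4"

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.combine not in ("arithmetic", "geometric"):
            raise ValueError(f"unknown combine rule {self.combine!r}")
        if any(v < 1 for v in self.eps_table.values()):
            raise ValueError("all eps values must be >= 1")

    def eps_of(self, resname: str) -> float:
        value = self.eps_table.get(resname.upper())
        if value is None:
            if self.eps_default is None:
                raise KeyError(f"residue {resname!r} not in dielectric table")
            value = self.eps_default
        return float(value)


@dataclass
class LinkElement:
    """One link's electrical state (SI units).

    ``l`` in metres, ``A`` in m²; admittance
    Y(ω) = (A/l)(1/ρ + i ε ε₀ ω) has a positive real part for any ω ≥ 0.
    """

    i: int
    j: int
    l: float
    A: float
    rho: float
    eps_rel: float

    def __post_init__(self) -> None:
        if self.l <= 0 or self.A <= 0:
            raise ValueError("link length and area must be positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


def link_impedance(elem: LinkElement, omega: float) -> complex:
    """Complex impedance of a single link at circular frequency ω (rad/s).

    At ω = 0 this is purely real and equals ρ·l/A.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    y = (elem.A / elem.l) * (1.0 / elem.rho + 1j * elem.eps_rel * epsilon_0 * omega)
    return 1.0 / y


def assign_elements(graph, params: MaterialParams) -> list[LinkElement]:
    """Attach an RC element to every link of a contact graph.

    The link's ε_ij is the pair combination (arithmetic or geometric mean)
    of the two residues' table values; geometry is converted from Å to SI.
    """
    elements: list[LinkElement] = []
    for (i, j), l_ang, a_ang2 in zip(graph.edges, graph.lengths, graph.areas):
        e_i = params.eps_of(graph.resnames[int(i)])
        e_j = params.eps_of(graph.resnames[int(j)])
        if params.combine == "arithmetic":
            eps = 0.5 * (e_i + e_j)
        else:
            eps = float(np.sqrt(e_i * e_j))
        elements.append(
            LinkElement(
                i=int(i),
                j=int(j),
                l=float(l_ang) * _ANG,
                A=float(a_ang2) * _ANG**2,
                rho=params.rho,
                eps_rel=eps,
            )
        )
    return elements
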