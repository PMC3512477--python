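"""Cα-trace structures: PDB input, synthetic helices and conformer pairs.

Throughout the package a protein is represented only by the ordered trace of
its Cα atoms — one point per amino acid — since the network model treats each
residue as a single interacting centre located at its alpha carbon.
Coordinates are kept in Ångström at this boundary; conversion to SI happens
once, when electrical elements are assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CalphaChain",
    "ConformerPair",
    "read_pdb",
    "write_pdb",
    "make_helix",
    "make_conformer_pair",
]


@dataclass
class CalphaChain:
    """Ordered Cα trace of a protein.

    Parameters
    ----------
    resnames : list of str
        Three-letter residue codes, one per node.
    chain_ids : list of str
        Chain identifier of each residue.
    seq_ids : ndarray of int
        Residue sequence numbers; strictly increasing within a chain
        (insertion codes break ties).
    coords : ndarray, shape (n, 3)
        Cα positions in Å.
    icodes : list of str, optional
        PDB insertion codes ('' when absent).
    """

    resnames: list[str]
    chain_ids: list[str]
    seq_ids: np.ndarray
    coords: np.ndarray
    icodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.seq_ids = np.asarray(self.seq_ids, dtype=int)
        n = len(self.resnames)
        if not self.icodes:
            self.icodes = [""] * n
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if len(self.chain_ids) != n or len(self.seq_ids) != n or len(self.icodes) != n:
            raise ValueError("field lengths disagree")
        if n < 2:
            raise ValueError("a chain needs at least 2 residues to form a network")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        # (seq, icode) strictly increasing within each chain
        for k in range(1, n):
            if self.chain_ids[k] != self.chain_ids[k - 1]:
                continue
            prev = (int(self.seq_ids[k - 1]), self.icodes[k - 1])
            cur = (int(self.seq_ids[k]), self.icodes[k])
            if cur <= prev:
                raise ValueError(
                    f"residue order not strictly increasing within chain "
                    f"{self.chain_ids[k]!r}: {prev} then {cur}"
                )

    def __len__(self) -> int:
        return len(self.resnames)

    @property
    def residues(self) -> list[tuple[str, str, int, np.ndarray]]:
        """Residues as (resname, chain_id, seq_index, position) tuples."""
        return [
            (self.resnames[k], self.chain_ids[k], int(self.seq_ids[k]), self.coords[k])
            for k in range(len(self))
        ]

    def consecutive_distances(self) -> np.ndarray:
        """Distances between consecutive Cα atoms, in Å."""
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    def diameter(self) -> float:
        """Largest pairwise Cα distance (Å)."""
        from scipy.spatial.distance import pdist

        return float(pdist(self.coords).max())

    def translated(self, shift: Sequence[float]) -> "CalphaChain":
        return CalphaChain(
            list(self.resnames),
            list(self.chain_ids),
            self.seq_ids.copy(),
            self.coords + np.asarray(shift, dtype=float),
            list(self.icodes),
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the Cα table with header ``chain,seq,resname,x,y,z`` (Å)."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "chain": self.chain_ids,
                "seq": self.seq_ids,
                "resname": self.resnames,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
            }
        )
        df.to_csv(path, index=False)


@dataclass
class ConformerPair:
    """Native/active pair of Cα chains of the same protein.

    The two conformers may differ in residue count, as deposited structure
    pairs of the same receptor often do.
    """

    native: CalphaChain
    active: CalphaChain
    label: str = ""


def read_pdb(
    path: str | Path,
    chain_filter: Iterable[str] | None = None,
    model_index: int = 0,
) -> CalphaChain:
    """Read a Cα trace from a PDB file.

    One node is returned per residue that carries a CA atom in an ATOM
    record.  For alternate locations the highest-occupancy conformer is
    kept (ties: first listed).  HETATM records are ignored.  By default all
    chains of the selected model are concatenated in file order; within a
    chain residues are ordered by (resSeq, iCode).

    Parameters
    ----------
    path : file path
    chain_filter : set of chain ids, optional
        Restrict to these chains.  ``None`` keeps all chains.
    model_index : int
        Which MODEL of a multi-model file to read (0-based).
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise ValueError(f"{path}: no models found")
    if model_index >= len(structure) or model_index < 0:
        raise ValueError(
            f"model_index {model_index} out of range: file has {len(structure)} model(s)"
        )
    model = structure[model_index]
    wanted = set(chain_filter) if chain_filter is not None else None

    resnames: list[str] = []
    chain_ids: list[str] = []
    seq_ids: list[int] = []
    icodes: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for chain in model:
        if wanted is not None and chain.name not in wanted:
            continue
        entries = []
        for residue in chain:
            if residue.het_flag == "H":
                continue
            ca_best = None
            for atom in residue:
                if atom.name != "CA":
                    continue
                if ca_best is None or atom.occ > ca_best.occ:
                    ca_best = atom
            if ca_best is None:
                continue
            icode = residue.seqid.icode.strip()
            entries.append(
                (residue.seqid.num, icode, residue.name, ca_best.pos)
            )
        entries.sort(key=lambda e: (e[0], e[1]))
        for num, icode, name, pos in entries:
            resnames.append(name)
            chain_ids.append(chain.name)
            seq_ids.append(num)
            icodes.append(icode)
            coords.append((pos.x, pos.y, pos.z))

    if not resnames:
        raise ValueError(f"{path}: no CA atoms found after filtering")
    if len(resnames) < 2:
        raise ValueError(f"{path}: fewer than 2 Cα atoms")
    return CalphaChain(resnames, chain_ids, np.array(seq_ids), np.array(coords), icodes)


def write_pdb(chain: CalphaChain, path: str | Path) -> None:
    """Write the Cα trace as minimal PDB ATOM records (0.001 Å precision)."""
    lines = []
    for k in range(len(chain)):
        x, y, z = chain.coords[k]
        icode = chain.icodes[k] or " "
        lines.append(
            f"ATOM  {k + 1:>5}  CA  {chain.resnames[k]:<3} "
            f"{chain.chain_ids[k][:1]}{int(chain.seq_ids[k]):>4}{icode}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f" C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def make_helix(
    n_residues: int,
    rise: float = 1.5,
    radius: float = 2.3,
    twist: float = 100.0,
) -> CalphaChain:
    """Deterministic ideal helix of Cα positions.

    The defaults are the ideal α-helix parameters (rise 1.5 Å, radius
    2.3 Å, 100° per residue), which put consecutive Cα atoms ~3.8 Å apart —
    the spacing of real protein backbones.  The helix axis is z.

    Parameters
    ----------
    n_residues : int, >= 2
    rise, radius : Å, > 0
    twist : degrees per residue, > 0
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    if rise <= 0 or radius <= 0 or twist <= 0:
        raise ValueError("rise, radius and twist must be positive")
    k = np.arange(n_residues)
    theta = np.deg2rad(twist) * k
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * k]
    )
    return CalphaChain(
        resnames=["ALA"] * n_residues,
        chain_ids=["A"] * n_residues,
        seq_ids=k + 1,
        coords=coords,
    )


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    # deterministic sign: positive component on the largest-|.| coordinate
    lead = np.argmax(np.abs(axis))
    return axis if axis[lead] >= 0 else -axis


def make_conformer_pair(
    base: CalphaChain,
    displacement: float,
    mode: str = "random",
    seed: int = 0,
    label: str = "synthetic",
) -> ConformerPair:
    """Derive a synthetic native/active pair from a base chain.

    ``mode='hinge'`` rigidly rotates the C-terminal half about an axis
    perpendicular to the chain's principal axis through the hinge residue;
    the rotation angle is chosen so the RMS displacement of the moved half
    equals ``displacement`` (Å).  ``mode='random'`` adds i.i.d. Gaussian
    noise to every coordinate with per-atom RMS displacement
    ``displacement``.  Deterministic given ``seed``; ``displacement=0``
    returns identical copies.
    """
    if displacement < 0:
        raise ValueError("displacement must be >= 0")
    if mode not in ("hinge", "random"):
        raise ValueError(f"unknown mode {mode!r}")

    coords = base.coords.copy()
    if displacement > 0:
        if mode == "random":
            rng = np.random.default_rng(seed)
            sigma = displacement / np.sqrt(3.0)
            coords = coords + rng.normal(0.0, sigma, size=coords.shape)
        else:
            h = len(base) // 2
            principal = _principal_axis(base.coords)
            # any fixed unit vector perpendicular to the principal axis
            trial = np.array([1.0, 0.0, 0.0])
            if abs(principal @ trial) > 0.9:
                trial = np.array([0.0, 1.0, 0.0])
            axis = np.cross(principal, trial)
            axis /= np.linalg.norm(axis)
            pivot = coords[h]
            moved = coords[h:] - pivot
            # distance of each moved atom from the rotation axis
            r_perp = np.linalg.norm(moved - np.outer(moved @ axis, axis), axis=1)
            rms_r = float(np.sqrt(np.mean(r_perp**2)))
            if rms_r > 0:
                s = min(1.0, displacement / (2.0 * rms_r))
                angle = 2.0 * np.arcsin(s)
                from scipy.spatial.transform import Rotation

                rot = Rotation.from_rotvec(angle * axis)
                coords[h:] = rot.apply(moved) + pivot
    active = CalphaChain(
        list(base.resnames),
        list(base.chain_ids),
        base.seq_ids.copy(),
        coords,
        list(base.icodes),
    )
    return ConformerPair(native=base, active=active, label=label)
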