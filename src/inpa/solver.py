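"""Linear Kirchhoff solution of the impedance network.

The two-terminal impedance is obtained by nodal analysis on the complex
admittance Laplacian: each contact set is merged into an ideal equipotential
supernode, the output supernode is grounded, a unit current is injected at
the input supernode, and the input potential is the impedance.  Components
not touching the contacts are dropped from the linear system (they carry no
current); if the two contacts fall in different components the network is
disconnected and the impedance is infinite.

Dense LU with one step of iterative refinement is used for the typical
10²–10³-node networks; a sparse LU branch takes over for larger systems.
Every solve is checked against a Kirchhoff current-conservation residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.constants import epsilon_0
from scipy.sparse.csgraph import connected_components

from .impedance import LinkElement
from .structure import CalphaChain, _principal_axis

__all__ = [
    "ContactSpec",
    "SpectrumResult",
    "IVResult",
    "DisconnectedNetworkError",
    "SolverError",
    "point_contacts",
    "make_planar_contacts",
    "solve_impedance",
    "spectrum",
    "nyquist",
    "linear_iv",
]

_RESIDUAL_TOL = 1e-9
_DENSE_LIMIT = 800


class DisconnectedNetworkError(RuntimeError):
    """No path of links joins the input and output contacts: Z is infinite."""


class SolverError(RuntimeError):
    """The nodal system could not be solved to the required residual."""


@dataclass(frozen=True)
class ContactSpec:
    """Placement of the two ideal (equipotential) electrical contacts."""

    kind: str  # 'point' or 'planar'
    input_nodes: frozenset
    output_nodes: frozenset
    axis: tuple | None = None
    depth_in: float | None = None
    depth_out: float | None = None

    def __post_init__(self) -> None:
        if not self.input_nodes or not self.output_nodes:
            raise ValueError("contact node sets must be non-empty")
        if self.input_nodes & self.output_nodes:
            raise ValueError("input and output contact sets overlap")

    def swapped(self) -> "ContactSpec":
        return ContactSpec(
            self.kind, self.output_nodes, self.input_nodes,
            self.axis, self.depth_out, self.depth_in,
        )


def point_contacts(n_nodes: int, source: int | None = None, sink: int | None = None) -> ContactSpec:
    """Point contacts, by default on the first and last node of the chain."""
    source = 0 if source is None else source
    sink = n_nodes - 1 if sink is None else sink
    return ContactSpec("point", frozenset({source}), frozenset({sink}))


def make_planar_contacts(
    chain: CalphaChain,
    depth_in: float,
    depth_out: float,
    axis: Sequence[float] | None = None,
) -> ContactSpec:
    """Extended (flat) contacts, e.g. an indenting tip and a substrate.

    All nodes within ``depth_in`` (Å) of the maximal projection onto
    ``axis`` form the input set; all within ``depth_out`` of the minimal
    projection form the output set.  ``axis`` defaults to the structure's
    principal axis.  Depth 0 keeps only the extreme node(s), reducing to a
    point contact.
    """
    if depth_in < 0 or depth_out < 0:
        raise ValueError("contact depths must be >= 0")
    if axis is None:
        axis_v = _principal_axis(chain.coords)
    else:
        axis_v = np.asarray(axis, dtype=float)
        norm = np.linalg.norm(axis_v)
        if norm == 0:
            raise ValueError("axis must be non-zero")
        axis_v = axis_v / norm
    proj = chain.coords @ axis_v
    extent = proj.max() - proj.min()
    if depth_in + depth_out >= extent:
        raise ValueError(
            f"depth_in + depth_out ({depth_in + depth_out} Å) must be smaller "
            f"than the extent along the axis ({extent:.2f} Å)"
        )
    input_nodes = frozenset(np.flatnonzero(proj >= proj.max() - depth_in).tolist())
    output_nodes = frozenset(np.flatnonzero(proj <= proj.min() + depth_out).tolist())
    return ContactSpec(
        "planar", input_nodes, output_nodes,
        axis=tuple(axis_v), depth_in=depth_in, depth_out=depth_out,
    )


# ---------------------------------------------------------------------------
# internal reduced-system machinery

def _element_arrays(elements: Sequence[LinkElement]):
    i = np.fromiter((e.i for e in elements), dtype=int, count=len(elements))
    j = np.fromiter((e.j for e in elements), dtype=int, count=len(elements))
    gfac = np.fromiter((e.A / e.l for e in elements), dtype=float, count=len(elements))
    rho = np.fromiter((e.rho for e in elements), dtype=float, count=len(elements))
    eps = np.fromiter((e.eps_rel for e in elements), dtype=float, count=len(elements))
    return i, j, gfac, rho, eps


class ReducedNetwork:
    """Contact-contracted nodal system for a fixed topology.

    Precomputes the supernode contraction, the component restriction and
    the scatter pattern of the Laplacian so that repeated solves (frequency
    sweeps, Monte-Carlo iterations) only refill values and factorize.
    """

    def __init__(self, i: np.ndarray, j: np.ndarray, n_nodes: int, contact: ContactSpec):
        i = np.asarray(i, dtype=int)
        j = np.asarray(j, dtype=int)
        in_idx = np.fromiter(contact.input_nodes, dtype=int)
        out_idx = np.fromiter(contact.output_nodes, dtype=int)
        for idx in (in_idx, out_idx):
            if idx.min(initial=0) < 0 or idx.max(initial=-1) >= n_nodes:
                raise IndexError("contact node index out of range")
        self.n_nodes = n_nodes

        # contracted node ids: virtual input supernode = n, output = n+1
        gmap = np.arange(n_nodes + 2)
        gmap[in_idx] = n_nodes
        gmap[out_idx] = n_nodes + 1
        gi, gj = gmap[i], gmap[j]
        active = gi != gj  # edges inside a supernode carry no drop

        size = n_nodes + 2
        adj = sp.coo_matrix(
            (np.ones(int(active.sum())), (gi[active], gj[active])), shape=(size, size)
        )
        _, labels = connected_components(adj, directed=False)
        if labels[n_nodes] != labels[n_nodes + 1]:
            raise DisconnectedNetworkError(
                "input and output contacts lie in different components; "
                "the impedance tends to infinity"
            )
        in_comp = labels == labels[n_nodes]

        red = np.full(size, -1, dtype=int)  # -1: ground or excluded (potential 0)
        red[n_nodes] = 0
        interior = in_comp.copy()
        interior[n_nodes] = False
        interior[n_nodes + 1] = False
        # contracted ids of original contact nodes never appear in gi/gj
        interior[in_idx] = False
        interior[out_idx] = False
        idx_int = np.flatnonzero(interior)
        red[idx_int] = 1 + np.arange(len(idx_int))
        self.m = 1 + len(idx_int)
        self._node_red = red[gmap[:n_nodes]]

        ei, ej = red[gi], red[gj]
        in_system = active & (in_comp[gi] | in_comp[gj])
        # links that actually belong to the solved two-terminal system
        # (not internal to a contact supernode, not in a floating component)
        self.edge_in_system = in_system.copy()
        # scatter pattern: flat indices into the m×m matrix + source edge + sign
        flat, edge_k, sign = [], [], []
        for k in np.flatnonzero(in_system):
            a, b = int(ei[k]), int(ej[k])
            if a >= 0:
                flat.append(a * self.m + a); edge_k.append(k); sign.append(1.0)
            if b >= 0:
                flat.append(b * self.m + b); edge_k.append(k); sign.append(1.0)
            if a >= 0 and b >= 0:
                flat.append(a * self.m + b); edge_k.append(k); sign.append(-1.0)
                flat.append(b * self.m + a); edge_k.append(k); sign.append(-1.0)
        self._flat = np.asarray(flat, dtype=int)
        self._edge_k = np.asarray(edge_k, dtype=int)
        self._sign = np.asarray(sign, dtype=float)

    def solve(self, y_edges: np.ndarray, current: float = 1.0):
        """Solve for the reduced potentials at unit (or given) injected current.

        Returns ``(Z, potentials_full, residual)`` where ``potentials_full``
        has one entry per original node (ground/excluded nodes at 0) and
        ``residual`` is the worst Kirchhoff current imbalance relative to
        the injected current.
        """
        m = self.m
        vals = self._sign * y_edges[self._edge_k]
        b = np.zeros(m, dtype=vals.dtype)
        b[0] = current
        if m <= _DENSE_LIMIT:
            mat = np.zeros(m * m, dtype=vals.dtype)
            np.add.at(mat, self._flat, vals)
            mat = mat.reshape(m, m)
            # symmetric Jacobi equilibration: large resistivity contrast
            # between link states otherwise degrades the LU residual
            d = np.sqrt(np.abs(mat.diagonal()))
            if np.any(d == 0) or not np.all(np.isfinite(d)):
                raise SolverError("singular nodal system (zero diagonal)")
            scaled = mat / np.outer(d, d)
            try:
                lu = scipy.linalg.lu_factor(scaled, check_finite=False)

                def correct(res):
                    return scipy.linalg.lu_solve(lu, res / d, check_finite=False) / d

                x = correct(b)
                for _ in range(3):
                    r = b - mat @ x
                    if np.max(np.abs(r)) < 1e-12 * abs(current):
                        break
                    x = x + correct(r)
            except (scipy.linalg.LinAlgError, ValueError) as exc:
                raise SolverError(f"dense LU failed: {exc}") from exc
            r = b - mat @ x
        else:
            rows, cols = divmod(self._flat, m)
            mat = sp.coo_matrix((vals, (rows, cols)), shape=(m, m)).tocsc()
            try:
                lu = sp.linalg.splu(mat)
                x = lu.solve(b)
                for _ in range(3):
                    r = b - mat @ x
                    if np.max(np.abs(r)) < 1e-12 * abs(current):
                        break
                    x = x + lu.solve(r)
            except RuntimeError as exc:
                raise SolverError(f"sparse LU failed: {exc}") from exc
            r = b - mat @ x
        residual = float(np.max(np.abs(r))) / abs(current)
        # a backward-stable solve cannot beat eps·||Y||·||x|| in the residual;
        # with large link-state contrast that floor can exceed the nominal
        # tolerance, so enforce whichever is larger
        norm_y = float(np.max(np.abs(vals))) * 4.0
        norm_x = float(np.max(np.abs(x)))
        floor = 100.0 * m * np.finfo(float).eps * norm_y * norm_x / abs(current)
        if not np.isfinite(residual) or residual > max(_RESIDUAL_TOL, floor):
            raise SolverError(
                f"Kirchhoff residual {residual:.3e} exceeds "
                f"{max(_RESIDUAL_TOL, floor):.3e} (singular or ill-conditioned network)"
            )
        phi = np.zeros(self.n_nodes, dtype=x.dtype)
        inside = self._node_red >= 0
        phi[inside] = x[self._node_red[inside]]
        return x[0], phi, residual


def _admittances(gfac, rho, eps, omega: float) -> np.ndarray:
    if omega == 0.0:
        return gfac / rho
    return gfac * (1.0 / rho + 1j * eps * epsilon_0 * omega)


# ---------------------------------------------------------------------------
# public operations

def solve_impedance(
    elements: Sequence[LinkElement],
    contact: ContactSpec,
    omega: float,
    full: bool = False,
):
    """Two-terminal complex impedance of the network at ω (rad/s).

    With ``full=True`` returns ``(Z, node_potentials, residual)`` for the
    unit-current solve (potentials in volts per ampere injected).
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if len(elements) == 0:
        raise DisconnectedNetworkError("network has no links")
    i, j, gfac, rho, eps = _element_arrays(elements)
    n_nodes = int(max(i.max(), j.max(),
                      max(contact.input_nodes), max(contact.output_nodes))) + 1
    net = ReducedNetwork(i, j, n_nodes, contact)
    z, phi, residual = net.solve(_admittances(gfac, rho, eps, omega))
    z = complex(z)
    if full:
        return z, phi, residual
    return z


def frequency_grid(f_min: float, f_max: float, points_per_decade: int = 10) -> np.ndarray:
    """Log-spaced frequency grid inclusive of both endpoints (Hz)."""
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    decades = np.log10(f_max / f_min)
    n = int(round(decades * points_per_decade)) + 1
    if n < 2:
        n = 2
    return np.logspace(np.log10(f_min), np.log10(f_max), n)


@dataclass
class SpectrumResult:
    """Global impedance spectrum Z(ω) over a frequency grid."""

    frequencies: np.ndarray  # Hz
    Z: np.ndarray  # complex Ω
    contact: ContactSpec
    r_c: float | None = None

    def z0(self) -> float:
        """Static (lowest-frequency) real impedance, Ω."""
        return float(self.Z[0].real)

    def to_csv(self, path: str | Path, metadata: Sequence[str] = ()) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "freq_hz": self.frequencies,
                "z_real_ohm": self.Z.real,
                "z_imag_ohm": self.Z.imag,
            }
        )
        _write_csv_with_header(df, path, metadata)


def _write_csv_with_header(df, path, metadata: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for line in metadata:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def spectrum(
    elements: Sequence[LinkElement],
    contact: ContactSpec,
    f_min: float = 0.1,
    f_max: float = 1e5,
    points_per_decade: int = 10,
    r_c: float | None = None,
) -> SpectrumResult:
    """Impedance spectrum over a log grid (default 0.1 Hz – 100 kHz)."""
    freqs = frequency_grid(f_min, f_max, points_per_decade)
    if len(elements) == 0:
        raise DisconnectedNetworkError("network has no links")
    i, j, gfac, rho, eps = _element_arrays(elements)
    n_nodes = int(max(i.max(), j.max(),
                      max(contact.input_nodes), max(contact.output_nodes))) + 1
    net = ReducedNetwork(i, j, n_nodes, contact)
    z = np.empty(len(freqs), dtype=complex)
    for k, f in enumerate(freqs):
        z[k], _, _ = net.solve(_admittances(gfac, rho, eps, 2.0 * np.pi * f))
    return SpectrumResult(frequencies=freqs, Z=z, contact=contact, r_c=r_c)


def nyquist(spec: SpectrumResult, normalize_to: float | None = None):
    """Nyquist table: (Re Z / Z_ref, −Im Z / Z_ref) per frequency.

    ``Z_ref`` defaults to Re Z at the lowest frequency of this spectrum, so
    a self-normalized curve starts at abscissa 1 at the low-frequency end.
    To compare conformers, pass the native state's static value instead.
    """
    import pandas as pd

    z_ref = spec.z0() if normalize_to is None else float(normalize_to)
    if z_ref <= 0:
        raise ValueError("normalization impedance must be positive")
    return pd.DataFrame(
        {
            "z_real_norm": spec.Z.real / z_ref,
            "z_imag_neg_norm": -spec.Z.imag / z_ref,
        }
    )


@dataclass
class IVResult:
    """Current-voltage sweep with per-point Monte-Carlo statistics.

    ``regime_fraction`` is the mean fraction of links activated (switched to
    the low-resistivity state) while in the injection (over-barrier)
    regime; ``direct_fraction`` the same for the direct (sub-barrier)
    regime.  Both are ``None`` for purely ohmic sweeps.
    """

    voltages: np.ndarray
    current_mean: np.ndarray
    current_sd: np.ndarray
    n_realizations: int
    regime_fraction: np.ndarray | None = None
    direct_fraction: np.ndarray | None = None

    def to_csv(self, path: str | Path, metadata: Sequence[str] = ()) -> None:
        import pandas as pd

        inj = (
            self.regime_fraction
            if self.regime_fraction is not None
            else np.zeros_like(self.voltages)
        )
        df = pd.DataFrame(
            {
                "voltage_v": self.voltages,
                "current_mean_a": self.current_mean,
                "current_sd_a": self.current_sd,
                "injection_fraction": inj,
            }
        )
        _write_csv_with_header(df, path, metadata)


def linear_iv(z0: float, voltages: Sequence[float]) -> IVResult:
    """Ohmic I-V: I = V / Z(0), zero variance."""
    if z0 <= 0:
        raise ValueError("Z(0) must be positive")
    v = np.asarray(voltages, dtype=float)
    return IVResult(
        voltages=v,
        current_mean=v / z0,
        current_sd=np.zeros_like(v),
        n_realizations=1,
    )
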