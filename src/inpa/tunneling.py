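"""Stochastic sequential-tunneling I-V characteristics.

Nonlinear transport is modelled as a chain of barrier penetrations: at each
Monte-Carlo iteration the resistive network is solved for the node
potentials, and every link flips to a low-resistivity state with the
voltage-dependent probability

    P_ij = exp( −(2 l_ij / ħ) √(2 m (Φ − e V_ij)) )        (e V_ij < Φ)

where V_ij is the magnitude of the potential drop across the link, m the
electron effective mass (bare by default) and Φ the barrier height.  When
the drop tilts the barrier over (e V_ij ≥ Φ) the WKB transmission through
the resulting triangular barrier is used instead (the Fowler–Nordheim, or
injection, regime):

    P_ij = exp( −4 l_ij √(2 m) Φ^{3/2} / (3 ħ e V_ij) ).

Barriers may be Gaussian-distributed across links (quenched per
realization, truncated at Φ > 0).  The solve → drop → redraw loop is
iterated to a fluctuating steady state; the terminal current is averaged
after burn-in and across realizations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.constants import e as _E, hbar as _HBAR, m_e as _ME

from .impedance import LinkElement
from .solver import ContactSpec, IVResult, ReducedNetwork, _element_arrays

__all__ = [
    "TunnelingParams",
    "tunnel_probability",
    "direct_transmission",
    "fowler_nordheim_transmission",
    "mc_iv_sweep",
    "iv_with_leakage",
    "crossover_voltage",
]


@dataclass
class TunnelingParams:
    """Parameters of the sequential-tunneling Monte Carlo.

    Parameters
    ----------
    phi_mean : float, eV
        Mean barrier height.  Default 69 meV with ``phi_sigma`` 44 meV —
        the Gaussian-distributed barrier set that best reproduces measured
        monolayer I-V curves; a single barrier of 53–59 meV is the
        common alternative (set ``phi_sigma=0``).
    phi_sigma : float, eV
        Standard deviation of the per-link barrier; 0 means one shared
        barrier (the Gaussian machinery is bypassed entirely).
    m_eff : float, kg
        Electron effective mass; bare electron mass by default, the same
        for every link length.
    rho_low_ratio : float
        Low-resistivity state as a fraction of the resting resistivity.
        The model only needs the high/low contrast; 1e-6 by default.
    leakage_r : float or None, Ω
        Optional fixed resistor in parallel with the whole two-terminal
        network (contact-region conduction); its ohmic current is added.
    branch : {'hard', 'blended'}
        Matching of the two transmission formulas at eV = Φ: hard switch
        (default; the two WKB branches do not meet continuously) or a
        variant rescaled to be continuous at the branch point.
    burn_in_frac : float
        Fraction of iterations discarded before averaging.
    """

    phi_mean: float = 69e-3
    phi_sigma: float = 44e-3
    m_eff: float = _ME
    rho_low_ratio: float = 1e-6
    leakage_r: float | None = None
    branch: str = "hard"
    burn_in_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.phi_mean <= 0:
            raise ValueError("phi_mean must be positive")
        if self.phi_sigma < 0:
            raise ValueError("phi_sigma must be >= 0")
        if not (0 < self.rho_low_ratio <= 1):
            raise ValueError("rho_low_ratio must be in (0, 1]")
        if self.branch not in ("hard", "blended"):
            raise ValueError(f"unknown branch rule {self.branch!r}")
        if not (0 <= self.burn_in_frac < 1):
            raise ValueError("burn_in_frac must be in [0, 1)")


def direct_transmission(l, phi, v_drop, m_eff: float = _ME):
    """Sub-barrier transmission exp(−(2l/ħ)√(2m(Φ − eV))); valid for eV ≤ Φ.

    ``l`` in metres, ``phi`` in eV, ``v_drop`` the drop magnitude in volts.
    Equals 1 when eV = Φ (the barrier height goes to zero).
    """
    l = np.asarray(l, dtype=float)
    phi_j = np.asarray(phi, dtype=float) * _E
    ev_j = np.abs(np.asarray(v_drop, dtype=float)) * _E
    height = np.clip(phi_j - ev_j, 0.0, None)
    return np.exp(-(2.0 * l / _HBAR) * np.sqrt(2.0 * m_eff * height))


def fowler_nordheim_transmission(l, phi, v_drop, m_eff: float = _ME):
    """Triangular-barrier WKB transmission for the over-tilted case eV ≥ Φ.

    exp(−4 l √(2m) Φ^{3/2} / (3 ħ e V)); ``phi`` in eV, ``v_drop`` in volts.
    """
    l = np.asarray(l, dtype=float)
    phi_j = np.asarray(phi, dtype=float) * _E
    ev_j = np.abs(np.asarray(v_drop, dtype=float)) * _E
    with np.errstate(divide="ignore"):
        expo = -(4.0 * l * np.sqrt(2.0 * m_eff) * phi_j**1.5) / (3.0 * _HBAR * ev_j)
    return np.exp(expo)


def tunnel_probability(l, phi, v_drop, m_eff: float = _ME, branch: str = "hard"):
    """Per-link activation probability, dispatching on the regime.

    Direct (sub-barrier) formula for e·|V| < Φ, triangular-barrier
    (Fowler–Nordheim) formula for e·|V| ≥ Φ.  ``branch='blended'`` rescales
    the injection branch to join the direct one continuously at eV = Φ
    (clipped at 1); the default hard switch keeps both WKB expressions as
    they stand, with a documented discontinuity at the branch point.
    Accepts scalars or broadcastable arrays; P ∈ (0, 1].
    """
    l = np.asarray(l, dtype=float)
    phi = np.asarray(phi, dtype=float)
    v = np.abs(np.asarray(v_drop, dtype=float))
    if np.any(l <= 0):
        raise ValueError("link length must be positive")
    if np.any(phi <= 0):
        raise ValueError("barrier height must be positive")
    l, phi, v = np.broadcast_arrays(l, phi, v)
    injection = v * 1.0 >= phi  # eV >= Φ  (both sides in eV)
    p = np.where(
        injection,
        fowler_nordheim_transmission(l, phi, np.where(injection, v, 1.0), m_eff),
        direct_transmission(l, phi, v, m_eff),
    )
    if branch == "blended":
        # rescale the injection branch to be continuous at eV = Φ, where the
        # direct branch reaches 1
        at_branch = fowler_nordheim_transmission(l, phi, phi, m_eff)
        p = np.where(injection, np.minimum(1.0, p / at_branch), p)
    elif branch != "hard":
        raise ValueError(f"unknown branch rule {branch!r}")
    p = np.clip(p, 0.0, 1.0)
    return p if p.ndim else float(p)


def _draw_barriers(rng: np.random.Generator, n: int, mean: float, sigma: float) -> np.ndarray:
    """Quenched per-link barriers: N(mean, sigma²) truncated at Φ > 0 by rejection."""
    if sigma == 0.0:
        return np.full(n, mean)
    phi = rng.normal(mean, sigma, size=n)
    bad = phi <= 0.0
    while np.any(bad):
        phi[bad] = rng.normal(mean, sigma, size=int(bad.sum()))
        bad = phi <= 0.0
    return phi


def mc_iv_sweep(
    elements: Sequence[LinkElement],
    contact: ContactSpec,
    params: TunnelingParams,
    voltages: Sequence[float],
    n_realizations: int = 20,
    max_iter: int = 200,
    seed: int = 0,
) -> IVResult:
    """Monte-Carlo I-V sweep with sequential tunneling.

    Per realization and voltage: draw the quenched barriers, then iterate
    (solve resistive network → per-link drops → synchronous stochastic
    redraw of link states); the terminal current I = V / Z(0, state) is
    averaged after burn-in.  Each voltage point starts from the resting
    (all high-resistivity) state.  Deterministic given ``seed``.
    """
    voltages = np.asarray(voltages, dtype=float)
    if np.any(voltages < 0):
        raise ValueError("voltages must be >= 0")
    if np.any(np.diff(voltages) < 0):
        raise ValueError("voltages must be sorted ascending")
    if n_realizations < 1 or max_iter < 1:
        raise ValueError("n_realizations and max_iter must be >= 1")

    if len(elements) == 0:
        from .solver import DisconnectedNetworkError

        raise DisconnectedNetworkError("network has no links")
    i, j, gfac, rho_high, _ = _element_arrays(elements)
    lengths = np.fromiter((e.l for e in elements), dtype=float, count=len(elements))
    rho_low = rho_high * params.rho_low_ratio
    n_nodes = int(max(i.max(), j.max(),
                      max(contact.input_nodes), max(contact.output_nodes))) + 1
    net = ReducedNetwork(i, j, n_nodes, contact)
    n_links = len(elements)
    burn = int(np.floor(params.burn_in_frac * max_iter))
    rng = np.random.default_rng(seed)

    cur_mean = np.empty(len(voltages))
    cur_sd = np.empty(len(voltages))
    inj_frac = np.empty(len(voltages))
    dir_frac = np.empty(len(voltages))

    for iv, v in enumerate(voltages):
        i_real = np.empty(n_realizations)
        inj_real = np.empty(n_realizations)
        dir_real = np.empty(n_realizations)
        for r in range(n_realizations):
            phi_ev = _draw_barriers(rng, n_links, params.phi_mean, params.phi_sigma)
            low = np.zeros(n_links, dtype=bool)  # fresh start per voltage
            i_acc = 0.0
            inj_acc = 0.0
            dir_acc = 0.0
            n_rec = 0
            for it in range(max_iter):
                rho_state = np.where(low, rho_low, rho_high)
                z0, phi_node, _ = net.solve(gfac / rho_state)
                z0 = float(z0.real) if np.iscomplexobj(z0) else float(z0)
                current = v / z0
                drops = np.abs(phi_node[i] - phi_node[j]) * current
                p = tunnel_probability(
                    lengths, phi_ev, drops, m_eff=params.m_eff, branch=params.branch
                )
                low = rng.random(n_links) < p
                if it >= burn:
                    # regime bookkeeping over transport links only: links
                    # shorted inside a contact supernode carry no drop and
                    # do not participate in the two-terminal current path
                    sys_mask = net.edge_in_system
                    injection = drops >= phi_ev  # volts vs eV: same numbers
                    i_acc += current
                    inj_acc += float(np.mean((low & injection)[sys_mask]))
                    dir_acc += float(np.mean((low & ~injection)[sys_mask]))
                    n_rec += 1
            i_real[r] = i_acc / n_rec
            inj_real[r] = inj_acc / n_rec
            dir_real[r] = dir_acc / n_rec
        cur_mean[iv] = i_real.mean()
        cur_sd[iv] = i_real.std(ddof=1) if n_realizations > 1 else 0.0
        inj_frac[iv] = inj_real.mean()
        dir_frac[iv] = dir_real.mean()

    if params.leakage_r is not None:
        if params.leakage_r <= 0:
            raise ValueError("leakage_r must be positive")
        cur_mean = cur_mean + voltages / params.leakage_r

    return IVResult(
        voltages=voltages,
        current_mean=cur_mean,
        current_sd=cur_sd,
        n_realizations=n_realizations,
        regime_fraction=inj_frac,
        direct_fraction=dir_frac,
    )


def iv_with_leakage(iv: IVResult, leakage_r: float) -> IVResult:
    """Add the current of a resistor in parallel with the whole network."""
    if leakage_r <= 0:
        raise ValueError("leakage_r must be positive")
    return IVResult(
        voltages=iv.voltages,
        current_mean=iv.current_mean + iv.voltages / leakage_r,
        current_sd=iv.current_sd.copy(),
        n_realizations=iv.n_realizations,
        regime_fraction=None if iv.regime_fraction is None else iv.regime_fraction.copy(),
        direct_fraction=None if iv.direct_fraction is None else iv.direct_fraction.copy(),
    )


def crossover_voltage(iv: IVResult) -> float | None:
    """Smallest sweep voltage where injection-regime activation dominates.

    Returns the first voltage at which the mean fraction of activated links
    in the injection regime exceeds the direct-regime fraction, or ``None``
    if that never happens within the sweep.
    """
    if iv.regime_fraction is None or iv.direct_fraction is None:
        raise ValueError("IVResult carries no regime bookkeeping")
    above = iv.regime_fraction > iv.direct_fraction
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return None
    return float(iv.voltages[idx[0]])
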