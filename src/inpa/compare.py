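"""Native vs activated conformer comparison and macroscopic scaling.

The relevant output of the network model is the *relative* electrical
change of a receptor across its conformational change, not the absolute
single-molecule values.  This module runs the same pipeline on both
conformers (each with its own interaction radius, which is recorded in
every report) and forms per-frequency impedance ratios and per-voltage
current ratios.  A single multiplicative factor — fitted once by anchoring
the native-state single-protein current to a macroscopic measurement —
scales both conformers' curves; all ratios are invariant under it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .graph import build_graph
from .impedance import MaterialParams, assign_elements
from .solver import IVResult, SpectrumResult, linear_iv, point_contacts, solve_impedance, spectrum
from .structure import ConformerPair
from .tunneling import TunnelingParams, mc_iv_sweep

__all__ = ["ScalingSpec", "ContrastReport", "conformer_contrast", "fit_scaling", "apply_scaling"]


@dataclass
class ScalingSpec:
    """Single-protein → macroscopic current scaling (a pure gauge)."""

    anchor_voltage: float
    anchor_current_macroscopic: float
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("scaling factor must be positive")


def fit_scaling(
    single_iv: IVResult, anchor_voltage: float, macroscopic_current: float
) -> ScalingSpec:
    """Fit the one multiplicative factor anchoring a single-protein sweep.

    The native-state single-protein current at ``anchor_voltage`` is mapped
    onto the macroscopic measurement; the same factor must then be applied
    unchanged to the activated state.
    """
    matches = np.flatnonzero(np.isclose(single_iv.voltages, anchor_voltage))
    if len(matches) == 0:
        raise ValueError(f"anchor voltage {anchor_voltage} V not in sweep")
    i_single = float(single_iv.current_mean[matches[0]])
    if i_single <= 0:
        raise ValueError("single-protein current at the anchor voltage is not positive")
    if macroscopic_current <= 0:
        raise ValueError("macroscopic current must be positive")
    return ScalingSpec(
        anchor_voltage=float(anchor_voltage),
        anchor_current_macroscopic=float(macroscopic_current),
        factor=macroscopic_current / i_single,
    )


def apply_scaling(iv: IVResult, scaling: ScalingSpec) -> IVResult:
    """Multiply an I-V sweep by the fitted factor (currents and spreads)."""
    return IVResult(
        voltages=iv.voltages.copy(),
        current_mean=iv.current_mean * scaling.factor,
        current_sd=iv.current_sd * scaling.factor,
        n_realizations=iv.n_realizations,
        regime_fraction=None if iv.regime_fraction is None else iv.regime_fraction.copy(),
        direct_fraction=None if iv.direct_fraction is None else iv.direct_fraction.copy(),
    )


@dataclass
class ContrastReport:
    """Electrical contrast between the native and activated conformers."""

    impedance: "object"  # DataFrame: freq_hz, z0-normalized columns, ratios
    current: "object | None"  # DataFrame: voltage_v, currents, ratio
    native_spectrum: SpectrumResult
    active_spectrum: SpectrumResult
    r_c_native: float
    r_c_active: float
    label: str = ""

    def to_csv(self, path: str | Path, metadata: Sequence[str] = ()) -> None:
        header = [
            f"pair={self.label}",
            f"r_c_native_A={self.r_c_native}",
            f"r_c_active_A={self.r_c_active}",
            *metadata,
        ]
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            self.impedance.to_csv(fh, index=False)
            if self.current is not None:
                fh.write("#\n")
                self.current.to_csv(fh, index=False)


def conformer_contrast(
    pair: ConformerPair,
    r_c_native: float,
    r_c_active: float,
    material: MaterialParams | None = None,
    f_min: float = 0.1,
    f_max: float = 1e5,
    points_per_decade: int = 10,
    voltages: Sequence[float] | None = None,
    tunneling: TunnelingParams | None = None,
    n_realizations: int = 20,
    max_iter: int = 200,
    seed: int = 0,
) -> ContrastReport:
    """Run both conformers through the pipeline and form active/native ratios.

    Each conformer may use its own interaction radius (a modelling choice
    that is recorded, not hidden).  Impedance ratios are per-frequency
    |Z_active|/|Z_native|; if ``voltages`` is given, current ratios come
    from the ohmic law or, when ``tunneling`` is set, from the
    sequential-tunneling Monte Carlo (independent seeds per conformer
    derived from ``seed``).  An identical pair at identical settings gives
    ratio 1 everywhere.
    """
    import pandas as pd

    material = material if material is not None else MaterialParams()

    spectra = {}
    elements = {}
    for name, chain, rc in (
        ("native", pair.native, r_c_native),
        ("active", pair.active, r_c_active),
    ):
        g = build_graph(chain, rc)
        elems = assign_elements(g, material)
        contact = point_contacts(g.n_nodes)
        spectra[name] = spectrum(
            elems, contact, f_min=f_min, f_max=f_max,
            points_per_decade=points_per_decade, r_c=rc,
        )
        elements[name] = (elems, contact)

    z_n, z_a = spectra["native"].Z, spectra["active"].Z
    impedance = pd.DataFrame(
        {
            "freq_hz": spectra["native"].frequencies,
            "z_abs_native_ohm": np.abs(z_n),
            "z_abs_active_ohm": np.abs(z_a),
            "z_abs_ratio": np.abs(z_a) / np.abs(z_n),
        }
    )

    current = None
    if voltages is not None:
        ivs = {}
        for k, name in enumerate(("native", "active")):
            elems, contact = elements[name]
            if tunneling is None:
                z0 = float(solve_impedance(elems, contact, 0.0).real)
                ivs[name] = linear_iv(z0, voltages)
            else:
                ivs[name] = mc_iv_sweep(
                    elems, contact, tunneling, voltages,
                    n_realizations=n_realizations, max_iter=max_iter,
                    seed=seed + k,
                )
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(
                ivs["native"].current_mean > 0,
                ivs["active"].current_mean / ivs["native"].current_mean,
                np.nan,
            )
        current = pd.DataFrame(
            {
                "voltage_v": ivs["native"].voltages,
                "current_native_a": ivs["native"].current_mean,
                "current_active_a": ivs["active"].current_mean,
                "current_ratio": ratio,
            }
        )

    return ContrastReport(
        impedance=impedance,
        current=current,
        native_spectrum=spectra["native"],
        active_spectrum=spectra["active"],
        r_c_native=r_c_native,
        r_c_active=r_c_active,
        label=pair.label,
    )
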