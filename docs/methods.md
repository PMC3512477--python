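# Methods

## The model

A protein's tertiary structure is reduced to its Cα trace: one node per
amino acid, placed at the alpha-carbon position. Two nodes i, j are linked
whenever their distance l_ij is strictly smaller than an interaction radius
R_C, so the structure becomes a set of intercrossing spheres of radius R_C.
Each link carries the elemental impedance of a resistor in parallel with a
capacitor,

    Z_ij(ω) = (l_ij / A_ij) · 1 / (1/ρ + i ε_ij ε₀ ω),
    A_ij = π (R_C² − l_ij² / 4),

where A_ij is the cross-sectional area between the two spheres, ρ a single
resistivity shared by all residues (default 10¹⁰ Ω·m, an indicative value:
the microscopic transfer mechanism is deliberately left unspecified), ε₀
the vacuum permittivity and ε_ij a relative dielectric constant combined
from per-residue values. Contacts are ideal equipotential node sets; the
network is solved in a linear Kirchhoff scheme for the two-terminal
impedance Z(ω) over a log-spaced frequency grid (default 0.1 Hz–100 kHz,
10 points per decade), from which Nyquist curves (−Im Z vs Re Z) are drawn.
The static solve also yields the ohmic law V = Z(0)·I.

Nonlinear transport adds a sequential-tunneling Monte Carlo: every link can
switch to a low-resistivity state with probability

    P_ij = exp( −(2 l_ij/ħ) √(2 m (Φ_ij − e V_ij)) )      for e V_ij < Φ_ij,
    P_ij = exp( −4 l_ij √(2m) Φ_ij^{3/2} / (3 ħ e V_ij) )  for e V_ij ≥ Φ_ij,

the second expression being the WKB transmission through the triangular
(over-tilted, Fowler–Nordheim / "injection") barrier. V_ij is the magnitude
of the self-consistent potential drop across the link in the current
network state; m is the electron effective mass, bare by default and
independent of link length. Per voltage point the loop *solve network →
compute drops → synchronously redraw all link states* is iterated to a
fluctuating steady state; the terminal current is averaged after burn-in
and across independent realizations.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| R_C | 6 Å | interaction radius; must exceed the ~3.8 Å backbone spacing for connectivity; the graph completes near the structure diameter |
| ρ | 10¹⁰ Ω·m | resting link resistivity, shared by all residues |
| ε table | flat 4.0 | per-residue relative dielectric constants; editable two-column text file; pair combination arithmetic (or geometric) mean |
| Φ mean | 69 meV | barrier height; with σ = 44 meV Gaussian-distributed per link (quenched per realization, truncated at Φ > 0); σ = 0 gives the single-barrier variant (53–59 meV typical) |
| m_eff | mₑ | tunneling effective mass, length-independent |
| rho_low_ratio | 10⁻⁶ | activated-state resistivity as a fraction of ρ; only the high/low contrast matters qualitatively, and this knob is part of the test surface |
| leakage_R | off | optional resistor in parallel with the whole two-terminal network, standing in for conduction through contact regions |
| burn-in | 20 % of 200 iterations | discarded before averaging |

## Numerical choices

- **Units.** Geometry enters in Å/Å² and is converted to SI exactly once,
  when elements are assigned; everything downstream is SI.
- **Nodal reduction.** Contact sets are contracted to supernodes; components
  not touching the contacts are dropped (they carry no current); input/output
  in different components is reported as a disconnected network (infinite
  impedance) — an error in single solves, an `inf` row in radius scans.
- **Linear algebra.** Dense LU with symmetric Jacobi equilibration and up to
  three iterative-refinement steps for systems ≤ 800 unknowns; sparse LU
  beyond. Every solve checks the Kirchhoff current residual against
  max(10⁻⁹ of the injected current, the machine-precision backward-stability
  floor ε·‖Y‖·‖x‖ for the matrix at hand). The floor matters only when the
  10⁶ link-state contrast of the Monte Carlo is present; uniform-resistivity
  networks sit far below 10⁻⁹.
- **Threshold semantics.** Links require l_ij < R_C strictly; coincident
  nodes are rejected as malformed input (the elemental impedance degenerates
  at l = 0). The KD-tree neighbour search is an internal optimization whose
  contract is equality with the all-pairs scan (tested).
- **Branch point of the transmission.** The two WKB expressions do not meet
  continuously at eV = Φ. The default is a hard switch at eV ≥ Φ; a
  "blended" variant rescales the injection branch to join the direct branch
  (which reaches 1 there) continuously, clipped at 1. The discontinuity is a
  model property, not a bug.
- **Monte-Carlo scheme.** Synchronous redraw of all link states per
  iteration; barriers are quenched disorder (drawn once per realization);
  each voltage point restarts from the resting state (no sweep hysteresis);
  probabilities use |V_ij|. With σ = 0 no Gaussian draws are consumed, so
  the single-barrier model is reproduced exactly at fixed seed.
- **Regime bookkeeping.** Activated-link fractions (direct vs injection) are
  counted over links that actually belong to the solved two-terminal system;
  links shorted inside a contact supernode carry no drop and are excluded.
  The crossover voltage is the first sweep point where injection-activated
  links outnumber direct-activated ones.
- **Saturation in R_C.** Beyond the structure diameter the graph is complete
  and the topology stops changing; Z(0) still scales as the link-area factor
  (A ∝ R_C² for R_C ≫ l_ij), which follows directly from the area formula.
  Saturation statements therefore refer to the topology and to relative
  (conformer-contrast) quantities, which are R_C-envelope-free.

## The synthetic-structure generator

`make_helix` produces an ideal α-helical Cα trace (rise 1.5 Å, radius
2.3 Å, 100°/residue → 3.83 Å consecutive spacing), and
`make_conformer_pair` derives an "activated" conformer either by a rigid
hinge rotation of the C-terminal half (rotation angle set so the moved
half's RMS displacement equals the requested value; 2 Å default — the scale
of a receptor's activation rearrangement) or by i.i.d. Gaussian coordinate
noise. This emulates what the pipeline needs from a deposited structure
pair: backbone-spaced ordered chains, compact geometry, and a controlled
native/active difference. It does **not** emulate side-chain packing,
secondary-structure diversity, chain breaks, or the asymmetric loop
rearrangements of real receptors, so passing tests demonstrate the
correctness of the machinery and the qualitative trends (superlinearity,
crossover shifts, contrast ratios), not quantitative agreement with any
particular protein. Real structures enter through `read_pdb` (gemmi-backed,
Cα/ATOM records only, highest-occupancy altloc, all chains of the first
model by default with `chain_filter` to narrow — deposited receptor pairs
are often trimeric and the choice monomer vs oligomer is left to the user).

## Problem sizes

Default test and acceptance runs use 25–60-residue synthetic chains,
Monte-Carlo sweeps of 30–100 realizations × 100 iterations, and one
200-node random geometric graph for conservation checks. These sizes give
Monte-Carlo standard errors well below the effects being asserted while
keeping any run at the scale of seconds to a couple of minutes on one CPU.

## Known limitations

- The per-residue dielectric table ships flat (ε = 4) — residue-specific
  polarizability-derived values are a user input, not a package claim.
- The low-state resistivity is a free contrast parameter; absolute currents
  in the activated regime depend on it, ratios much less so.
- No temperature dependence, no frequency-dependent dielectric response,
  no non-ideal contact elements (Warburg/CPE), no hysteresis across sweep
  points.
- Comparing conformers at different R_C values (as EIS fits sometimes
  require) is supported but is a modelling choice; every report records the
  radii used.
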