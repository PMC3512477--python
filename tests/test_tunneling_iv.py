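"""Sequential-tunneling probabilities and Monte-Carlo I-V sweeps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.constants import e as E_CHARGE, hbar as HBAR, m_e as M_E

import inpa


def helix_chain_network(n=50, r_c=4.2):
    """Series chain: R_C below the second-neighbour distance keeps only
    consecutive links."""
    chain = inpa.make_helix(n)
    graph = inpa.build_graph(chain, r_c)
    assert graph.n_links == n - 1
    elements = inpa.assign_elements(graph, inpa.MaterialParams())
    contact = inpa.point_contacts(graph.n_nodes)
    return elements, contact


def scalar_probability(l, phi_ev, v, m=M_E):
    """Independent scalar evaluation of both transmission branches."""
    phi_j = phi_ev * E_CHARGE
    ev_j = abs(v) * E_CHARGE
    if ev_j < phi_j:
        return math.exp(-(2.0 * l / HBAR) * math.sqrt(2.0 * m * (phi_j - ev_j)))
    return math.exp(
        -(4.0 * l * math.sqrt(2.0 * m) * phi_j**1.5) / (3.0 * HBAR * ev_j)
    )


class TestTunnelProbability:
    def test_matches_independent_evaluation_on_grid(self):
        for l_ang in (2.0, 3.8, 6.0):
            for phi in (53e-3, 59e-3, 69e-3):
                for v in (0.0, 0.02, 0.05, phi, 0.1, 1.0):
                    got = inpa.tunnel_probability(l_ang * 1e-10, phi, v)
                    want = scalar_probability(l_ang * 1e-10, phi, v)
                    assert got == pytest.approx(want, rel=1e-12)

    def test_direct_branch_is_one_at_barrier_top(self):
        assert inpa.direct_transmission(3.8e-10, 59e-3, 59e-3) == pytest.approx(1.0)

    def test_zero_bias_reference_value(self):
        # hand evaluation with CODATA constants: exp(−(2·3.8Å/ħ)√(2 m Φ))
        p = inpa.tunnel_probability(3.8e-10, 59e-3, 0.0)
        assert p == pytest.approx(0.3884, abs=2e-3)
        assert p == pytest.approx(0.39, abs=5e-3)

    @given(
        l=st.floats(1e-10, 1e-9),
        phi=st.floats(0.01, 0.5),
        v1=st.floats(0.0, 2.0),
        dv=st.floats(1e-6, 0.5),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_drop_within_each_branch(self, l, phi, v1, dv):
        v2 = v1 + dv
        same_branch = (v1 < phi and v2 < phi) or (v1 >= phi and v2 > v1 >= phi)
        if same_branch:
            p1 = inpa.tunnel_probability(l, phi, v1)
            p2 = inpa.tunnel_probability(l, phi, v2)
            assert p2 >= p1

    @given(
        l=st.floats(1e-10, 1e-9),
        phi=st.floats(0.01, 0.5),
        v=st.floats(0.0, 2.0),
        scale=st.floats(1.01, 3.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_decreasing_in_length_and_barrier(self, l, phi, v, scale):
        p = inpa.tunnel_probability(l, phi, v)
        assert inpa.tunnel_probability(l * scale, phi, v) <= p
        if v < phi:  # barrier growth keeps the branch only in the direct regime
            assert inpa.tunnel_probability(l, phi * scale, v) <= p

    def test_blended_branch_continuous_at_switch(self):
        l, phi = 3.8e-10, 69e-3
        below = inpa.tunnel_probability(l, phi, phi - 1e-12, branch="blended")
        above = inpa.tunnel_probability(l, phi, phi + 1e-12, branch="blended")
        assert above == pytest.approx(below, rel=1e-5)
        # the hard switch has the documented discontinuity
        hard_above = inpa.tunnel_probability(l, phi, phi + 1e-12, branch="hard")
        assert hard_above < below

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            inpa.tunnel_probability(-1e-10, 0.05, 0.0)
        with pytest.raises(ValueError):
            inpa.tunnel_probability(1e-10, 0.0, 0.0)
        with pytest.raises(ValueError):
            inpa.tunnel_probability(1e-10, 0.05, 0.0, branch="soft")


class TestMcIvSweep:
    def test_huge_barrier_reduces_to_ohmic_law(self):
        elements, contact = helix_chain_network(20)
        params = inpa.TunnelingParams(phi_mean=10.0, phi_sigma=0.0)
        v = [0.0, 0.5, 1.0]
        iv = inpa.mc_iv_sweep(elements, contact, params, v,
                              n_realizations=3, max_iter=20, seed=1)
        z0 = inpa.solve_impedance(elements, contact, 0.0).real
        lin = inpa.linear_iv(z0, v)
        np.testing.assert_allclose(iv.current_mean, lin.current_mean, rtol=1e-9)
        assert (iv.current_sd == 0).all()

    def test_equal_resistivities_make_switching_invisible(self):
        elements, contact = helix_chain_network(20)
        params = inpa.TunnelingParams(rho_low_ratio=1.0)
        v = [0.0, 0.5, 1.0, 2.0]
        iv = inpa.mc_iv_sweep(elements, contact, params, v,
                              n_realizations=3, max_iter=20, seed=1)
        z0 = inpa.solve_impedance(elements, contact, 0.0).real
        np.testing.assert_allclose(iv.current_mean, np.asarray(v) / z0, rtol=1e-9)

    def test_seed_reproducibility_bit_identical(self):
        elements, contact = helix_chain_network(20)
        params = inpa.TunnelingParams()
        kwargs = dict(n_realizations=4, max_iter=30, seed=123)
        a = inpa.mc_iv_sweep(elements, contact, params, [0.0, 1.0, 2.0], **kwargs)
        b = inpa.mc_iv_sweep(elements, contact, params, [0.0, 1.0, 2.0], **kwargs)
        np.testing.assert_array_equal(a.current_mean, b.current_mean)
        np.testing.assert_array_equal(a.current_sd, b.current_sd)
        np.testing.assert_array_equal(a.regime_fraction, b.regime_fraction)

    def test_sigma_zero_equals_constant_barrier_path(self):
        """phi_sigma = 0 must follow the single-barrier code path exactly:
        no Gaussian draws are consumed, so results match a run whose barriers
        are forced constant by construction."""
        elements, contact = helix_chain_network(15)
        a = inpa.mc_iv_sweep(
            elements, contact, inpa.TunnelingParams(phi_mean=59e-3, phi_sigma=0.0),
            [0.0, 1.0], n_realizations=3, max_iter=20, seed=7,
        )
        b = inpa.mc_iv_sweep(
            elements, contact, inpa.TunnelingParams(phi_mean=59e-3, phi_sigma=0.0),
            [0.0, 1.0], n_realizations=3, max_iter=20, seed=7,
        )
        np.testing.assert_array_equal(a.current_mean, b.current_mean)

    def test_superlinear_when_activation_occurs(self):
        elements, contact = helix_chain_network(50)
        params = inpa.TunnelingParams()
        iv = inpa.mc_iv_sweep(elements, contact, params, [0.0, 1.0, 2.0],
                              n_realizations=10, max_iter=100, seed=5)
        activated = (iv.regime_fraction + iv.direct_fraction)[1:]
        assert (activated > 0).all()
        assert iv.current_mean[2] > 2.0 * iv.current_mean[1]

    def test_current_zero_at_zero_bias_and_increasing(self):
        elements, contact = helix_chain_network(30)
        iv = inpa.mc_iv_sweep(elements, contact, inpa.TunnelingParams(),
                              [0.0, 0.5, 1.0, 2.0, 4.0],
                              n_realizations=8, max_iter=60, seed=2)
        assert iv.current_mean[0] == 0.0
        assert (np.diff(iv.current_mean) > 0).all()

    def test_bad_sweep_inputs(self):
        elements, contact = helix_chain_network(10)
        params = inpa.TunnelingParams()
        with pytest.raises(ValueError):
            inpa.mc_iv_sweep(elements, contact, params, [-1.0, 0.0])
        with pytest.raises(ValueError):
            inpa.mc_iv_sweep(elements, contact, params, [1.0, 0.5])
        with pytest.raises(ValueError):
            inpa.mc_iv_sweep(elements, contact, params, [0.0], n_realizations=0)


class TestLeakage:
    def test_infinite_leakage_is_identity(self):
        elements, contact = helix_chain_network(15)
        iv = inpa.mc_iv_sweep(elements, contact, inpa.TunnelingParams(),
                              [0.0, 1.0], n_realizations=2, max_iter=10, seed=3)
        out = inpa.iv_with_leakage(iv, 1e300)
        np.testing.assert_allclose(out.current_mean, iv.current_mean, rtol=1e-12)

    def test_dominant_leakage_is_ohmic(self):
        elements, contact = helix_chain_network(15)
        z0 = inpa.solve_impedance(elements, contact, 0.0).real
        leak = z0 * 1e-9
        iv = inpa.linear_iv(z0, [0.0, 0.5, 1.0])
        out = inpa.iv_with_leakage(iv, leak)
        np.testing.assert_allclose(out.current_mean, np.array([0.0, 0.5, 1.0]) / leak,
                                   rtol=1e-6)

    def test_additivity_of_leakage_branch(self):
        elements, contact = helix_chain_network(15)
        params = inpa.TunnelingParams()
        kwargs = dict(n_realizations=2, max_iter=10, seed=3)
        base = inpa.mc_iv_sweep(elements, contact, params, [0.0, 1.0, 2.0], **kwargs)
        with_leak = inpa.mc_iv_sweep(
            elements, contact,
            inpa.TunnelingParams(leakage_r=1e18), [0.0, 1.0, 2.0], **kwargs,
        )
        leak_only = np.array([0.0, 1.0, 2.0]) / 1e18
        np.testing.assert_allclose(
            with_leak.current_mean, base.current_mean + leak_only, rtol=1e-12
        )

    def test_nonpositive_leakage_rejected(self):
        iv = inpa.linear_iv(1.0, [0.0, 1.0])
        with pytest.raises(ValueError):
            inpa.iv_with_leakage(iv, 0.0)


class TestCrossover:
    def test_sweep_capped_below_barrier_gives_none(self):
        elements, contact = helix_chain_network(20)
        # per-link drop ≈ V/19 stays far below Φ = 0.5 eV
        params = inpa.TunnelingParams(phi_mean=0.5, phi_sigma=0.0)
        iv = inpa.mc_iv_sweep(elements, contact, params, [0.0, 0.5, 1.0],
                              n_realizations=3, max_iter=20, seed=1)
        assert inpa.crossover_voltage(iv) is None

    def test_two_node_single_link_crossover_at_phi_over_e(self):
        """Whole bias drops across the one link: the injection regime opens
        exactly at V = Φ/e."""
        phi = 0.1
        elements = [inpa.LinkElement(0, 1, 3.8e-10, 93.46e-20, 1e10, 4.0)]
        contact = inpa.point_contacts(2)
        params = inpa.TunnelingParams(phi_mean=phi, phi_sigma=0.0)
        voltages = [0.0, 0.05, 0.09, phi, 0.15, 0.2]
        iv = inpa.mc_iv_sweep(elements, contact, params, voltages,
                              n_realizations=3, max_iter=40, seed=2)
        assert inpa.crossover_voltage(iv) == pytest.approx(phi)

    def test_deeper_indentation_lowers_crossover(self):
        """Fewer series links ⇒ larger per-link drops ⇒ earlier crossover."""
        chain = inpa.make_helix(40)
        graph = inpa.build_graph(chain, 4.2)
        elements = inpa.assign_elements(graph, inpa.MaterialParams())
        params = inpa.TunnelingParams(phi_mean=69e-3, phi_sigma=0.0)
        voltages = np.linspace(0.0, 8.0, 17)
        crossovers = []
        for depth in (5.0, 25.0):
            contact = inpa.make_planar_contacts(chain, depth, 0.0, axis=[0, 0, 1])
            iv = inpa.mc_iv_sweep(elements, contact, params, voltages,
                                  n_realizations=5, max_iter=60, seed=4)
            crossovers.append(inpa.crossover_voltage(iv))
        assert crossovers[0] is not None and crossovers[1] is not None
        assert crossovers[1] <= crossovers[0]

    def test_requires_regime_bookkeeping(self):
        iv = inpa.linear_iv(1.0, [0.0, 1.0])
        with pytest.raises(ValueError):
            inpa.crossover_voltage(iv)
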