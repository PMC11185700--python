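"""Exchange models, equilibrium solutions and Bloch-McConnell propagation."""

import math

import numpy as np
import pytest
import scipy.integrate
import scipy.linalg
from hypothesis import given, settings, strategies as st

import foldswitch_nmr as fn
from foldswitch_nmr.exchange import (
    bloch_mcconnell_generator,
    equilibrium_magnetization,
    equilibrium_populations,
    propagate,
    rate_matrix,
)


def two_state(k12, k21, units="s"):
    return fn.ExchangeModel(
        ("A", "B"), {("A", "B"): k12, ("B", "A"): k21}, units=units
    )


class TestExchangeModel:
    def test_rejects_one_way_exchange(self):
        with pytest.raises(ValueError, match="reverse"):
            fn.ExchangeModel(("A", "B"), {("A", "B"): 1.0})

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError, match=">= 0"):
            fn.ExchangeModel(("A", "B"), {("A", "B"): -1.0, ("B", "A"): 1.0})

    def test_hour_units_converted_on_entry(self):
        m = two_state(0.09, 0.36, units="hr")
        assert m.rate("A", "B") == pytest.approx(0.09 / 3600)

    def test_kex_is_sum_of_directions(self):
        assert two_state(12.11, 160.89).kex("A", "B") == pytest.approx(173.0)


class TestEquilibriumPopulations:
    def test_printed_tjump_rates_give_80_20(self):
        # 0.09 / 0.36 hr^-1 Ground<->FS interconversion
        p = equilibrium_populations(two_state(0.09, 0.36, units="hr"))
        assert np.allclose(p, [0.80, 0.20], atol=1e-12)

    def test_symmetric_rates_give_half_half(self):
        p = equilibrium_populations(two_state(5.0, 5.0))
        assert np.allclose(p, [0.5, 0.5], atol=1e-12)

    def test_three_state_chain_matches_linear_solve_oracle(self):
        # E<->G<->PD chain; k_PDG chosen so p_PD = 0.03 at p_G ~ 0.89
        k_gpd = 2.0
        model = fn.ExchangeModel(
            ("E", "G", "PD"),
            {
                ("G", "E"): 12.1, ("E", "G"): 160.9,
                ("G", "PD"): k_gpd, ("PD", "G"): k_gpd * 0.89 / 0.03,
            },
        )
        p = equilibrium_populations(model)
        # independent oracle: replace one master-equation row with the
        # normalization constraint and solve the dense linear system
        K = rate_matrix(model)
        A = K.copy()
        A[-1, :] = 1.0
        b = np.zeros(3)
        b[-1] = 1.0
        expected = np.linalg.solve(A, b)
        assert np.allclose(p, expected, atol=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_disconnected_graph_names_unreachable_states(self):
        model = fn.ExchangeModel(
            ("A", "B", "C", "D"),
            {("A", "B"): 1.0, ("B", "A"): 2.0, ("C", "D"): 1.0, ("D", "C"): 1.0},
        )
        with pytest.raises(ValueError, match=r"\['C', 'D'\]"):
            equilibrium_populations(model)

    def test_all_zero_rates_rejected(self):
        model = fn.ExchangeModel(("A", "B"), {("A", "B"): 0.0, ("B", "A"): 0.0})
        with pytest.raises(ValueError, match="zero"):
            equilibrium_populations(model)

    @given(
        k12=st.floats(0.01, 1e3), k21=st.floats(0.01, 1e3),
    )
    @settings(deadline=None, max_examples=50)
    def test_two_state_detailed_balance(self, k12, k21):
        m = two_state(k12, k21)
        p = equilibrium_populations(m)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert p[0] * k12 == pytest.approx(p[1] * k21, rel=1e-9)


class TestRateMatrix:
    def test_two_state_closed_form(self):
        K = rate_matrix(two_state(3.0, 7.0))
        assert np.allclose(K, [[-3.0, 7.0], [3.0, -7.0]])

    def test_columns_sum_to_zero(self):
        model = fn.ExchangeModel(
            ("E", "G", "PD"),
            {("G", "E"): 12.0, ("E", "G"): 138.0, ("G", "PD"): 2.0, ("PD", "G"): 0.6},
        )
        K = rate_matrix(model)
        assert np.allclose(K.sum(axis=0), 0.0, atol=1e-14)

    def test_long_time_propagation_reaches_equilibrium(self):
        model = two_state(2.0, 6.0)
        K = rate_matrix(model)
        p0 = np.array([1.0, 0.0])
        p_inf = scipy.linalg.expm(K * (50.0 / model.kex("A", "B"))) @ p0
        assert np.allclose(p_inf, equilibrium_populations(model), atol=1e-10)

    def test_rate_scaling_scales_relaxation_rate(self):
        # multiplying all rates by c multiplies the relaxation eigenvalue by c
        for c in (2.0, 10.0):
            K1 = rate_matrix(two_state(1.0, 3.0))
            Kc = rate_matrix(two_state(1.0, 3.0).scaled(c))
            ev1 = sorted(np.linalg.eigvals(K1).real)[0]
            evc = sorted(np.linalg.eigvals(Kc).real)[0]
            assert evc == pytest.approx(c * ev1, rel=1e-12)


SPIN_1 = fn.SpinParams("r1", {"A": 120.0}, r1=1.5, r2=10.0, larmor_mhz=81.08)


class TestBlochMcConnellGenerator:
    def test_no_rf_single_state_recovers_with_r1(self):
        model = fn.ExchangeModel(("A",), {})
        G = bloch_mcconnell_generator(model, SPIN_1, b1_hz=0.0, carrier_ppm=120.0)
        v0 = np.array([0.0, 0.0, 0.0, 1.0])  # saturated z, constant element 1
        for t in (0.1, 0.5, 2.0):
            v = propagate(G, t, v0)
            assert v[2] == pytest.approx(1.0 - math.exp(-1.5 * t), rel=1e-9)

    def test_on_resonance_nutation_matches_bloch_ode_oracle(self):
        model = fn.ExchangeModel(("A",), {})
        b1 = 20.0
        G = bloch_mcconnell_generator(model, SPIN_1, b1_hz=b1, carrier_ppm=120.0)
        v0 = np.array([0.0, 0.0, 1.0, 1.0])

        # independent oracle: adaptive integration of the 3x3 Bloch ODE
        w1 = 2 * math.pi * b1
        def bloch(_, m):
            mx, my, mz = m
            return [
                -10.0 * mx,
                -10.0 * my - w1 * mz,
                w1 * my - 1.5 * (mz - 1.0),
            ]

        t_end = 0.05  # one nutation period at 20 Hz
        sol = scipy.integrate.solve_ivp(
            bloch, (0, t_end), [0.0, 0.0, 1.0], rtol=1e-10, atol=1e-12
        )
        v = propagate(G, t_end, v0)
        assert np.allclose(v[:3], sol.y[:, -1], atol=1e-7)

    def test_zero_exchange_generator_is_block_diagonal(self):
        model = fn.ExchangeModel(("A", "B"), {("A", "B"): 0.0, ("B", "A"): 0.0})
        spin = fn.SpinParams(
            "x", {"A": 120.0, "B": 123.0}, r1=1.5, r2=10.0, larmor_mhz=81.08
        )
        with pytest.raises(ValueError):
            # no equilibrium with all-zero rates: recovery target undefined
            bloch_mcconnell_generator(model, spin, 10.0, 120.0)

    def test_two_state_blocks_match_single_state_generators(self):
        model = fn.ExchangeModel(("A", "B"), {("A", "B"): 5.0, ("B", "A"): 5.0})
        spin = fn.SpinParams(
            "x", {"A": 120.0, "B": 123.0}, r1=1.5, r2=10.0, larmor_mhz=81.08
        )
        G = bloch_mcconnell_generator(model, spin, 10.0, 121.0)
        # stripping the exchange contribution leaves two independent
        # single-state Bloch blocks
        from foldswitch_nmr.exchange import rate_matrix as rm

        K = rm(model)
        Gx = G.copy()
        for comp in range(3):
            Gx[comp : 6 : 3, comp : 6 : 3] -= K
        for i, label in enumerate(("A", "B")):
            single = fn.ExchangeModel((label,), {})
            sspin = fn.SpinParams(
                "x", {label: spin.shifts_ppm[label]}, r1=1.5, r2=10.0,
                larmor_mhz=81.08,
            )
            Gs = bloch_mcconnell_generator(single, sspin, 10.0, 121.0)
            block = Gx[3 * i : 3 * i + 3, 3 * i : 3 * i + 3]
            assert np.allclose(block, Gs[:3, :3], atol=1e-12)

    def test_missing_state_parameters_are_listed(self):
        model = fn.ExchangeModel(("A", "B"), {("A", "B"): 1.0, ("B", "A"): 1.0})
        spin = fn.SpinParams("x", {"A": 120.0}, r1=1.5, r2=10.0, larmor_mhz=81.08)
        with pytest.raises(ValueError, match=r"\['B'\]"):
            bloch_mcconnell_generator(model, spin, 10.0, 120.0)


class TestPropagate:
    def test_zero_duration_is_identity(self):
        model = fn.ExchangeModel(("A",), {})
        G = bloch_mcconnell_generator(model, SPIN_1, 10.0, 119.0)
        v0 = np.array([0.3, -0.2, 0.9, 1.0])
        assert np.allclose(propagate(G, 0.0, v0), v0)

    def test_semigroup_property(self):
        model = fn.ExchangeModel(("A",), {})
        G = bloch_mcconnell_generator(model, SPIN_1, 15.0, 119.5)
        v0 = np.array([0.0, 0.0, 1.0, 1.0])
        a, b = 0.137, 0.291
        direct = propagate(G, a + b, v0)
        stepped = propagate(G, b, propagate(G, a, v0))
        assert np.allclose(direct, stepped, atol=1e-10)

    def test_free_transverse_decay(self):
        model = fn.ExchangeModel(("A",), {})
        G = bloch_mcconnell_generator(model, SPIN_1, 0.0, 120.0)  # on resonance
        v0 = np.array([1.0, 0.0, 0.0, 1.0])
        v = propagate(G, 0.1, v0)
        assert abs(complex(v[0], v[1])) == pytest.approx(math.exp(-1.0), rel=1e-9)

    def test_non_finite_generator_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            propagate(np.array([[np.nan]]), 1.0, np.array([1.0]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matrix_exponential_matches_ode_oracle(self, seed):
        """expm propagation vs adaptive ODE integration, rel. tol 1e-8."""
        rng = np.random.default_rng(seed)
        n = 2 + seed % 2
        states = tuple(f"S{i}" for i in range(n))
        rates = {}
        for i in range(n - 1):
            rates[(states[i], states[i + 1])] = float(rng.uniform(1, 200))
            rates[(states[i + 1], states[i])] = float(rng.uniform(1, 200))
        model = fn.ExchangeModel(states, rates)
        spin = fn.SpinParams(
            "x",
            {s: float(rng.uniform(110, 130)) for s in states},
            r1={s: float(rng.uniform(0.5, 3)) for s in states},
            r2={s: float(rng.uniform(5, 30)) for s in states},
            larmor_mhz=81.08,
        )
        G = bloch_mcconnell_generator(model, spin, 20.0, float(rng.uniform(110, 130)))
        v0 = equilibrium_magnetization(model).values
        t = 0.4
        got = propagate(G, t, v0)
        sol = scipy.integrate.solve_ivp(
            lambda _, v: G @ v, (0, t), v0, rtol=1e-11, atol=1e-13
        )
        ref = sol.y[:, -1]
        assert np.allclose(got, ref, rtol=1e-8, atol=1e-10)


class TestPopulationConservation:
    def test_z_magnetization_converges_to_equilibrium_without_rf(self):
        model = two_state(3.0, 9.0)
        spin = fn.SpinParams(
            "x", {"A": 120.0, "B": 123.0}, r1=1.5, r2=10.0, larmor_mhz=81.08
        )
        G = bloch_mcconnell_generator(model, spin, 0.0, 150.0)
        v0 = np.zeros(7)
        v0[2] = 1.0  # all z on state A
        v0[-1] = 1.0
        t = 50.0 / model.kex("A", "B") + 5.0 / 1.5  # exchange + R1 settling
        v = propagate(G, t, v0)
        p_eq = equilibrium_populations(model)
        assert np.allclose([v[2], v[5]], p_eq, atol=1e-6)

    def test_chain_detailed_balance(self):
        model = fn.ExchangeModel(
            ("E", "G", "PD"),
            {("G", "E"): 12.0, ("E", "G"): 138.0, ("G", "PD"): 2.0, ("PD", "G"): 0.61},
        )
        p = equilibrium_populations(model)
        for a, b in (("G", "E"), ("G", "PD")):
            ia, ib = model.index(a), model.index(b)
            assert p[ia] * model.rate(a, b) == pytest.approx(
                p[ib] * model.rate(b, a), rel=1e-10
            )
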