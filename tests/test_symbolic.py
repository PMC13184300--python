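"""Symbolic derivative and feature-condition derivations."""

import numpy as np
import pytest
import sympy as sp

import gujerdsa as g
from gujerdsa.symbolic import lambdified_conditions

from conftest import random_asm1_states

x, x1, x2 = sp.symbols("x x1 x2")


class TestRateJacobian:
    def test_logistic(self, logistic):
        J = g.rate_jacobian(logistic)
        r_g, K = sp.symbols("r_g K")
        assert sp.simplify(J[0, 0] - r_g * (1 - 2 * x / K)) == 0

    def test_rotation(self, rotation):
        assert g.rate_jacobian(rotation) == sp.Matrix([[0, 1], [-1, 0]])

    def test_asm1_autotrophic_growth_row(self, mbc14):
        J = g.rate_jacobian(mbc14)
        j = mbc14.process_names.index("aerobic_growth_autotrophs")
        nonzero = {
            name
            for k, name in enumerate(mbc14.states.names)
            if J[j, k] != 0
        }
        assert nonzero == {"S_NHx", "S_O2", "X_a"}


class TestSecondDerivative:
    def test_logistic_closed_form(self, logistic):
        r_g, K = sp.symbols("r_g K")
        expected = r_g**2 * x * (1 - x / K) * (1 - 2 * x / K)
        got = g.second_derivative(logistic, "x")
        assert sp.simplify(got - expected) == 0

    def test_rotation_signal_x1(self, rotation):
        assert sp.simplify(g.second_derivative(rotation, "x1") + x1) == 0

    def test_asm1_free_states_exclude_particulate_organic_N(self, mbc14):
        expr = g.second_derivative(mbc14, "S_O2")
        free = {s.name for s in expr.free_symbols}
        assert "X_cbN" not in free
        assert {"S_b", "X_cb", "X_h", "X_a", "S_O2", "S_NOx", "S_NHx", "S_bN"} <= free

    def test_matches_hand_transcribed_expansion(self, mbc14, rng):
        """The matrix-route second derivative equals a hand-written
        term-by-term chain-rule expansion of the oxygen balance."""
        p = mbc14.parameters
        f_hand = _hand_oxygen_second_derivative(p)
        _, _, f2, names = lambdified_conditions(mbc14, "S_O2")
        for state in random_asm1_states(mbc14, rng, 100):
            z = float(rng.uniform(0, 2000))
            args = [state.get(n, z if n == "z_O2" else 0.0) for n in names]
            got = f2(*args)
            want = f_hand(state, z)
            assert got == pytest.approx(want, rel=1e-8, abs=1e-8)


def _hand_oxygen_second_derivative(p):
    """Independent transcription of the expanded oxygen second derivative.

    Written directly from the two oxygen-consuming growth functions and the
    per-state mass balances, with all partial derivatives coded by hand
    (Monod derivative K/(s+K)^2), not via the stoichiometric matrix.
    """
    m_a = (p["Y_A"] + p["i_COD_NO3"]) / p["Y_A"]
    m_h = (p["Y_H"] - 1) / p["Y_H"]

    def fn(s, z):
        NH, O2, Sb = s["S_NHx"], s["S_O2"], s["S_b"]
        Xa, Xh, NO = s["X_a"], s["X_h"], s["S_NOx"]
        monod = lambda c, K: c / (c + K)
        dmonod = lambda c, K: K / (c + K) ** 2
        g_a = p["mu_A"] * Xa * monod(NH, p["K_NH"]) * monod(O2, p["K_OA"])
        g_h = (
            p["mu_H"] * Xh * monod(NH, p["K_NH_H"]) * monod(O2, p["K_OH"])
            * monod(Sb, p["K_S"])
        )
        # partial derivatives of the two growth functions
        dga_dNH = p["mu_A"] * Xa * dmonod(NH, p["K_NH"]) * monod(O2, p["K_OA"])
        dga_dO2 = p["mu_A"] * Xa * monod(NH, p["K_NH"]) * dmonod(O2, p["K_OA"])
        dga_dXa = g_a / Xa if Xa else 0.0
        dgh_dNH = (
            p["mu_H"] * Xh * dmonod(NH, p["K_NH_H"]) * monod(O2, p["K_OH"])
            * monod(Sb, p["K_S"])
        )
        dgh_dO2 = (
            p["mu_H"] * Xh * monod(NH, p["K_NH_H"]) * dmonod(O2, p["K_OH"])
            * monod(Sb, p["K_S"])
        )
        dgh_dSb = (
            p["mu_H"] * Xh * monod(NH, p["K_NH_H"]) * monod(O2, p["K_OH"])
            * dmonod(Sb, p["K_S"])
        )
        dgh_dXh = g_h / Xh if Xh else 0.0
        # remaining process rates entering the state balances
        g_hNO = (
            p["mu_H"] * p["eta_g"] * Xh * monod(Sb, p["K_S"])
            * (p["K_OH"] / (p["K_OH"] + O2)) * monod(NO, p["K_NO"])
            * monod(NH, p["K_NH_H"])
        )
        r_amm = p["k_a"] * s["S_bN"] * Xh
        r_hyd = (
            p["k_h"] * (s["X_cb"] * Xh / (p["K_X"] * Xh + s["X_cb"]))
            * (
                monod(O2, p["K_OH"])
                + p["eta_h"] * (p["K_OH"] / (p["K_OH"] + O2)) * monod(NO, p["K_NO"])
            )
            if (p["K_X"] * Xh + s["X_cb"]) > 0
            else 0.0
        )
        # autonomous state balances (no actuation)
        d_NH = (
            -p["i_XB"] * (g_h + g_hNO)
            - (p["i_XB"] + 1 / p["Y_A"]) * g_a
            + r_amm
        )
        d_O2_auto = m_a * g_a + m_h * g_h
        d_Sb = -(g_h + g_hNO) / p["Y_H"] + r_hyd
        d_Xa = g_a - p["b_A"] * Xa
        d_Xh = g_h + g_hNO - p["b_H"] * Xh
        return (
            d_NH * (dga_dNH * m_a + dgh_dNH * m_h)
            + d_O2_auto * (dga_dO2 * m_a + dgh_dO2 * m_h)
            + d_Sb * dgh_dSb * m_h
            + d_Xa * dga_dXa * m_a
            + d_Xh * dgh_dXh * m_h
            + z * (dga_dO2 * m_a + dgh_dO2 * m_h)
        )

    return fn


class TestRampConditions:
    def test_logistic_locus_is_half_capacity(self, logistic):
        conds = g.ramp_conditions(logistic, "x")
        K = sp.Symbol("K")
        roots = sp.solve(conds.equality, x)
        # keep roots inside the open interval (0, K) where the
        # inequality r_g x (1 - x/K) > 0 holds
        interior = [r for r in roots if r not in (0, K)]
        assert interior == [K / 2]

    def test_rotation_locus(self, rotation):
        conds = g.ramp_conditions(rotation, "x1")
        assert sp.simplify(conds.equality + x1) == 0
        assert sp.simplify(conds.inequality - x2) == 0

    def test_condition_states_monod(self, monod):
        conds = g.ramp_conditions(monod, "X")
        assert set(g.condition_states(conds)) == {"S", "X"}

    def test_condition_states_logistic(self, logistic):
        assert g.condition_states(g.ramp_conditions(logistic, "x")) == ("x",)

    def test_asm1_condition_states(self, mbc14):
        conds = g.ramp_conditions(mbc14, "S_O2")
        assert set(g.condition_states(conds)) == {
            "S_b", "X_cb", "X_h", "X_a", "S_O2", "S_NOx", "S_NHx", "S_bN",
        }
        assert set(conds.free_actuation) == {"z_O2", "zdot_O2"}

    def test_conditions_export_parse_back(self, mbc14):
        from gujerdsa._expr import parse_expression

        conds = g.ramp_conditions(mbc14, "S_O2")
        text = conds.as_strings()
        scope = {
            n: sp.Symbol(n)
            for n in (
                *mbc14.states.names,
                *mbc14.parameters,
                "z_O2",
                "zdot_O2",
            )
        }
        back = parse_expression(text["second_derivative"], scope)
        subs = {sp.Symbol(k): v for k, v in mbc14.parameters.items()}
        point = {sp.Symbol(n): 3.0 + i for i, n in enumerate(mbc14.states.names)}
        point[sp.Symbol("z_O2")] = 7.0
        point[sp.Symbol("zdot_O2")] = 0.0
        a = float(back.subs(subs).subs(point))
        b = float(conds.equality.subs(subs).subs(point))
        assert a == pytest.approx(b, rel=1e-10)


class TestStructuralInfeasibility:
    def test_oxygen_ramp_needs_aeration(self, mbc14):
        assert g.structurally_infeasible(mbc14, "S_O2", actuation_zero=True)

    def test_inconclusive_with_free_actuation(self, mbc14):
        assert not g.structurally_infeasible(mbc14, "S_O2", actuation_zero=False)

    def test_logistic_growth_is_feasible(self, logistic):
        assert not g.structurally_infeasible(logistic, "x")


class TestInvariants:
    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_time_rescaling_leaves_locus_unchanged(self, c, rng):
        """Scaling all rates by c scales the first derivative by c and the
        second by c², so the ramp locus set is unchanged."""
        base = g.monod_batch_model()
        scaled = g.monod_batch_model(mu_max=c * base.parameters["mu_max"])
        cb = g.ramp_conditions(base, "X")
        cs = g.ramp_conditions(scaled, "X")
        pb = base.parameter_subs()
        ps = scaled.parameter_subs()
        for _ in range(25):
            point = {
                sp.Symbol("S"): float(rng.uniform(0.1, 100)),
                sp.Symbol("X"): float(rng.uniform(0.1, 100)),
            }
            d1b = float(cb.inequality.subs(pb).subs(point))
            d1s = float(cs.inequality.subs(ps).subs(point))
            d2b = float(cb.equality.subs(pb).subs(point))
            d2s = float(cs.equality.subs(ps).subs(point))
            assert d1s == pytest.approx(c * d1b, rel=1e-9)
            assert d2s == pytest.approx(c**2 * d2b, rel=1e-9)

    def test_derivatives_match_finite_differences_along_trajectory(self, monod):
        """Symbolic first/second derivatives agree with central differences
        of an integrated trajectory."""
        h = 1e-4
        grid = np.arange(0.0, 0.5 + h / 2, h)
        # double differencing amplifies trajectory error by 1/h^2, so the
        # oracle trajectory must be much tighter than the comparison tolerance
        traj = g.integrate(model=monod, initial_state={"S": 50.0, "X": 5.0},
                           schedule=None, time_grid=grid, rtol=1e-12, atol=1e-12)
        _, f1, f2, names = lambdified_conditions(monod, "X")
        cols = {n: traj.column(n) for n in monod.states.names}
        args = [cols.get(n, 0.0) for n in names]
        d1 = np.asarray(f1(*args), float)
        d2 = np.asarray(f2(*args), float)
        y = traj.column("X")
        fd1 = np.gradient(y, grid)
        fd2 = (y[2:] - 2 * y[1:-1] + y[:-2]) / h**2
        err1 = np.max(np.abs(fd1 - d1)[2:-2]) / np.max(np.abs(d1))
        err2 = np.max(np.abs(fd2 - d2[1:-1])) / np.max(np.abs(d2))
        assert err1 <= 1e-4
        assert err2 <= 1e-4
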