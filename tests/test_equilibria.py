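"""Speciation, charge balance and pH solver against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkashift import (
    CompoundParams,
    EquilibriumError,
    Polarity,
    SolutionComposition,
    aggregate_link,
    aggregate_link_inverse,
    charge_balance_residual,
    solve_ph,
    species_at_ph,
)
from pkashift.titration import simulate_titration, standard_setup

from conftest import ph_grid_oracle


class TestAggregateLink:
    def test_no_aggregation_limit(self):
        assert aggregate_link(math.inf) == 0.0
        assert aggregate_link_inverse(0.0) == math.inf

    @pytest.mark.parametrize("s", [1e-6, 75e-6, 0.32])
    def test_round_trip_bijective(self, s):
        assert aggregate_link_inverse(aggregate_link(s)) == pytest.approx(
            s, rel=1e-12)

    def test_inverse_proportionality(self):
        # A = 1/S: halving the solubility doubles the aggregation constant,
        # and S = 75 uM maps to A = 13333.33... L/mol
        assert aggregate_link(75e-6) == pytest.approx(1 / 75e-6, rel=1e-15)
        assert aggregate_link(75e-6) == 2 * aggregate_link(150e-6)

    def test_nonpositive_solubility_rejected(self):
        with pytest.raises(ValueError):
            aggregate_link(0.0)
        with pytest.raises(ValueError):
            aggregate_link(-1e-6)


class TestCompoundParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            CompoundParams(0.0, 1e-4)
        with pytest.raises(ValueError):
            CompoundParams(15.0, 1e-4)  # above pkw
        with pytest.raises(ValueError):
            CompoundParams(7.0, -1e-4)
        with pytest.raises(ValueError):
            CompoundParams(7.0, 1e-4, "acid", pkw=-1.0)

    def test_a_zero_iff_s_infinite(self):
        assert CompoundParams(7.0).a_aggregation == 0.0
        assert CompoundParams(7.0, 1e-4).a_aggregation > 0.0

    def test_from_aggregation_round_trip(self):
        p = CompoundParams.from_aggregation(7.0, 1e4)
        assert p.s_intrinsic == pytest.approx(1e-4, rel=1e-12)


class TestSpeciesAtPh:
    def test_empty_system(self, reference_acid):
        st_ = species_at_ph(reference_acid, 0.0, 5.0)
        assert st_.c_neutral_dissolved == st_.c_charged == st_.c_aggregate == 0
        assert st_.c_h == pytest.approx(10 ** -5.0, rel=1e-12)

    def test_henderson_hasselbalch_midpoint(self, ideal_acid):
        st_ = species_at_ph(ideal_acid, 1e-3, ideal_acid.pka_intrinsic)
        assert st_.c_neutral_dissolved == pytest.approx(5e-4, rel=1e-12)
        assert st_.c_charged == pytest.approx(5e-4, rel=1e-12)
        assert st_.c_aggregate == 0.0

    def test_against_brute_force_scan(self):
        # independent oracle: 1-D scan over the dissolved neutral
        # concentration on a 2e6-point log grid, root of the mass balance
        params = CompoundParams(7.00, 100e-6, "acid")
        c_total, ph = 1e-3, 7.00
        h = 10.0 ** -ph
        ka = 10.0 ** -params.pka_intrinsic
        a = 1.0 / params.s_intrinsic
        x = np.logspace(-12, 0, 2_000_000)
        f = x * (1 + ka / h + a * c_total) - c_total  # monotone in x
        i = np.searchsorted(f, 0.0)
        # linear interpolation of the bracketing pair
        x_root = x[i - 1] - f[i - 1] * (x[i] - x[i - 1]) / (f[i] - f[i - 1])
        st_ = species_at_ph(params, c_total, ph)
        assert st_.c_neutral_dissolved == pytest.approx(x_root, rel=1e-6)
        assert st_.c_charged == pytest.approx(x_root * ka / h, rel=1e-6)
        assert st_.c_aggregate == pytest.approx(
            c_total - x_root * (1 + ka / h), rel=1e-6)

    def test_negative_c_total_rejected(self, reference_acid):
        with pytest.raises(ValueError):
            species_at_ph(reference_acid, -1e-6, 7.0)

    def test_neutral_form_saturates_at_intrinsic_solubility(self, reference_acid):
        # the defining property of S: dissolved neutral -> S as C -> inf
        st_ = species_at_ph(reference_acid, 10.0, 2.0)
        assert st_.c_neutral_dissolved == pytest.approx(
            reference_acid.s_intrinsic, rel=1e-3)
        assert st_.c_neutral_dissolved < reference_acid.s_intrinsic

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        pka=st.floats(2.0, 12.0),
        log_s=st.floats(-7.0, 0.0),
        log_c=st.floats(-8.0, -1.0),
        ph=st.floats(1.0, 13.0),
        polarity=st.sampled_from(["acid", "base"]),
    )
    def test_equilibrium_invariants(self, pka, log_s, log_c, ph, polarity):
        """Mass balance, water product and mass action on every output."""
        params = CompoundParams(pka, 10 ** log_s, polarity)
        c_total = 10 ** log_c
        s = species_at_ph(params, c_total, ph)
        assert min(s.c_neutral_dissolved, s.c_charged, s.c_aggregate) >= 0
        total = s.c_neutral_dissolved + s.c_charged + s.c_aggregate
        assert total == pytest.approx(c_total, rel=1e-9)
        assert s.c_h * s.c_oh == pytest.approx(10 ** -params.pkw, rel=1e-9)
        if s.c_neutral_dissolved > 0:
            ka = 10 ** -pka
            if params.polarity is Polarity.ACID:
                assert s.c_charged * s.c_h == pytest.approx(
                    ka * s.c_neutral_dissolved, rel=1e-9)
            else:
                assert s.c_neutral_dissolved * s.c_h == pytest.approx(
                    ka * s.c_charged, rel=1e-9)

    def test_aggregate_vanishes_at_infinite_dilution(self, reference_acid):
        cs = np.logspace(-9, -3, 7)
        agg = [species_at_ph(reference_acid, c, 5.0).c_aggregate / c for c in cs]
        assert all(np.diff(agg) > 0)
        assert agg[0] < 1e-4


class TestChargeBalance:
    def test_pure_water_neutral(self, reference_acid):
        st_ = species_at_ph(reference_acid, 0.0, reference_acid.pkw / 2)
        res = charge_balance_residual(st_, SolutionComposition(), "acid")
        assert res == pytest.approx(0.0, abs=1e-18)

    def test_spectator_salt(self, reference_acid):
        st_ = species_at_ph(reference_acid, 0.0, reference_acid.pkw / 2)
        comp = SolutionComposition(c_na=0.05, c_cl=0.05)
        assert charge_balance_residual(st_, comp, "acid") == pytest.approx(
            0.0, abs=1e-15)

    def test_solver_output_closes_balance(self, sparingly_soluble_acid):
        comp = SolutionComposition(c_total=2.5e-4, c_na=3.75e-4,
                                   c_cl=2.0e-4, c_h_added=2.0e-4)
        st_ = solve_ph(sparingly_soluble_acid, comp)
        res = charge_balance_residual(st_, comp, "acid")
        assert abs(res) < 1e-12


class TestSolvePh:
    def test_pure_water(self, reference_acid):
        st_ = solve_ph(CompoundParams(7.0), SolutionComposition())
        assert st_.ph == pytest.approx(reference_acid.pkw / 2, abs=1e-8)

    def test_strong_acid_limit(self):
        comp = SolutionComposition(c_cl=1e-3, c_h_added=1e-3)
        st_ = solve_ph(CompoundParams(7.0), comp)
        assert st_.ph == pytest.approx(3.0, abs=1e-3)

    def test_against_grid_search_oracle(self, sparingly_soluble_acid):
        comp = SolutionComposition(c_total=2.5e-4, c_na=3.75e-4,
                                   c_cl=2.0e-4, c_h_added=2.0e-4)
        st_ = solve_ph(sparingly_soluble_acid, comp)
        ph_oracle = ph_grid_oracle(sparingly_soluble_acid, comp.c_na,
                                   comp.c_cl, comp.c_total)
        assert st_.ph == pytest.approx(ph_oracle, abs=1e-4)

    def test_c_total_zero_with_compound_params(self, sparingly_soluble_acid):
        # legal: returns the pure-electrolyte pH
        comp = SolutionComposition(c_total=0.0, c_na=1e-4)
        st_ = solve_ph(sparingly_soluble_acid, comp)
        expected = -math.log10(
            (math.sqrt(1e-8 + 4 * 10 ** -13.997) - 1e-4) / 2)
        assert st_.ph == pytest.approx(expected, abs=1e-6)

    def test_impossible_composition_raises(self, reference_acid):
        # more NaOH-equivalent charge than water can buffer inside (0, pkw)
        with pytest.raises(EquilibriumError):
            solve_ph(reference_acid, SolutionComposition(c_na=5.0))

    def test_acid_base_mirror_symmetry(self):
        """A base with pKa p and an acid with pKa (pkw − p) titrate as exact
        pH mirror images when the titrant direction is exchanged."""
        pkw = 13.997
        base = CompoundParams(9.0, 2e-4, "base", pkw)
        acid = CompoundParams(pkw - 9.0, 2e-4, "acid", pkw)
        curve_b = simulate_titration(
            base, standard_setup(1e-3, titrant_kind="strong_base"))
        curve_a = simulate_titration(
            acid, standard_setup(1e-3, titrant_kind="strong_acid"))
        np.testing.assert_allclose(curve_b.ph, pkw - curve_a.ph, atol=1e-9)


class TestImplicitTitrationEquation:
    def test_symbolic_rederivation(self, sparingly_soluble_acid):
        """Eliminate the species from the raw equilibrium system with sympy
        and confirm the solver's root satisfies the resulting implicit
        equation in [H+]."""
        sympy = pytest.importorskip("sympy")
        H, OH, ROH, RO, AGG = sympy.symbols("H OH ROH RO AGG", positive=True)
        Ka, Kw, A, C, Na, Cl = sympy.symbols("Ka Kw A C Na Cl", positive=True)
        eqs = [
            sympy.Eq(ROH + RO + AGG, C),          # mass balance
            sympy.Eq(Ka * ROH, RO * H),           # acid dissociation
            sympy.Eq(AGG, A * C * ROH),           # aggregation mass action
            sympy.Eq(H * OH, Kw),                 # water product
        ]
        sol = sympy.solve(eqs, [ROH, RO, AGG, OH], dict=True)[0]
        residual = (Na + H) - (sol[RO] + Cl + sol[OH])  # electroneutrality
        f = sympy.lambdify((H, Ka, Kw, A, C, Na, Cl), sympy.simplify(residual))

        params = sparingly_soluble_acid
        comp_vals = dict(C=2.5e-4, Na=3.75e-4, Cl=2.0e-4)
        st_ = solve_ph(params, SolutionComposition(
            c_total=comp_vals["C"], c_na=comp_vals["Na"], c_cl=comp_vals["Cl"],
            c_h_added=comp_vals["Cl"]))
        val = f(st_.c_h, 10 ** -params.pka_intrinsic, 10 ** -params.pkw,
                1 / params.s_intrinsic, **comp_vals)
        assert abs(val) < 1e-12
        # and the symbolic residual agrees with the package residual
        # at off-equilibrium pH values too
        for ph in [4.0, 6.5, 8.0, 11.0]:
            s = species_at_ph(params, comp_vals["C"], ph)
            pkg = charge_balance_residual(
                s, SolutionComposition(c_total=comp_vals["C"],
                                       c_na=comp_vals["Na"],
                                       c_cl=comp_vals["Cl"],
                                       c_h_added=comp_vals["Cl"]), "acid")
            sym = f(10 ** -ph, 10 ** -params.pka_intrinsic,
                    10 ** -params.pkw, 1 / params.s_intrinsic, **comp_vals)
            assert pkg == pytest.approx(sym, rel=1e-9, abs=1e-18)
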