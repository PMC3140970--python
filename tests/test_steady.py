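"""Steady-state solvers: closed forms, cross-checks, stability certificates."""

import numpy as np
import pytest

import filonet as fn

from conftest import max_species_rel_diff, random_params

#: closed-form bound fraction for single-site binding with
#: A_tot = B_tot = K_D = 1:  AB^2 - 3 AB + 1 = 0 -> AB = (3 - sqrt(5))/2
CPB_CLOSED_FORM = (3.0 - np.sqrt(5.0)) / 2.0


def isolated_capping_params():
    """Only R1 active: CP_total = B_total = 1 nM, K_D = 1 nM."""
    p = fn.endogenous_params()
    p.totals = {"Eps8": 0.0, "Abi": 0.0, "IRSp53": 0.0, "VASP": 0.0, "CP": 1.0}
    p.b_total = 1.0
    p.kinetics[1] = (0.1, 0.1)  # K_D = 1 nM
    p.kinetics[8] = (0.0, 0.0)
    # keep turnover on so the (empty) F-actin pool has a decaying mode
    # rather than an inert zero eigenvalue
    p.k_turn = 0.01
    p.context_label = "isolated-R1"
    return p


class TestClosedForms:
    @pytest.mark.parametrize("solver", [fn.relax_to_steady, fn.solve_steady])
    def test_single_site_binding_quadratic(self, model, solver):
        ss = solver(model, isolated_capping_params())
        assert ss.converged
        assert ss["CPB"] == pytest.approx(CPB_CLOSED_FORM, abs=1e-8)

    @pytest.mark.parametrize("solver", [fn.relax_to_steady, fn.solve_steady])
    def test_empty_cell_has_zero_steady_state(self, model, solver):
        p = fn.endogenous_params()
        p.totals = {k: 0.0 for k in p.totals}
        p.b_total = 0.0
        ss = solver(model, p)
        assert ss.converged
        assert all(
            v == 0.0 for k, v in ss.concentrations.items() if k != "Ga"
        )


class TestContracts:
    def test_wild_type_hela_converges_and_is_stable(self, model, hela):
        ss = fn.relax_to_steady(model, hela)
        assert ss.converged
        assert ss.residual_norm <= 1e-9
        assert ss.max_re_eigenvalue < 0

    def test_conserved_totals_match_parameters(self, model, hela):
        ss = fn.solve_steady(model, hela)
        x = model.state_vector(ss.concentrations)
        assert fn.conservation_error(model, hela, x) < 1e-9

    def test_all_concentrations_non_negative(self, model, neuron):
        ss = fn.solve_steady(model, neuron)
        assert all(v >= 0 for v in ss.concentrations.values())

    def test_negative_guess_rejected(self, model, hela):
        guess = fn.default_initial_state(model, hela)
        guess[0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            fn.solve_steady(model, hela, guess=guess)

    def test_negative_initial_state_rejected(self, model, hela):
        init = fn.default_initial_state(model, hela)
        init[0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            fn.relax_to_steady(model, hela, init=init)

    def test_non_convergence_is_flagged_not_silent(self, model, hela):
        ss = fn.relax_to_steady(model, hela, t_max=1e-3, tol=1e-30, refine=False)
        assert not ss.converged

    def test_steady_state_flux_balance_on_actin(self, model, hela):
        # polymerization balances turnover; the F-actin binding steps of
        # the bundlers individually equilibrate
        ss = fn.solve_steady(model, hela)
        flux = model.mass_action_fluxes(
            model.state_vector(ss.concentrations), hela
        )
        assert flux[7] == pytest.approx(flux[8], abs=1e-8)
        assert abs(flux[4]) < 1e-8 and abs(flux[6]) < 1e-8


class TestOracleEquivalence:
    def test_relaxation_and_rootfinding_agree_on_contexts(self, model):
        for name in fn.CONTEXTS:
            p = fn.cell_context(name)
            a = fn.relax_to_steady(model, p)
            b = fn.solve_steady(model, p)
            assert max_species_rel_diff(a, b) < 1e-6

    @pytest.mark.parametrize("seed", range(6))
    def test_relaxation_and_rootfinding_agree_on_random_parameters(
        self, model, seed
    ):
        rng = np.random.default_rng(1000 + seed)
        p = random_params(rng)
        a = fn.relax_to_steady(model, p)
        b = fn.solve_steady(model, p)
        assert a.converged and b.converged
        assert max_species_rel_diff(a, b) < 1e-6

    def test_unique_steady_state_from_random_initializations(self, model, hela):
        # 20 feasible starts relax to the same state: no multistability
        reference = fn.solve_steady(model, hela)
        rng = np.random.default_rng(7)
        for _ in range(20):
            red = {
                "CPB": rng.uniform(0, 50),
                "EA": rng.uniform(0, 50),
                "EI": rng.uniform(0, 50),
                "VI": rng.uniform(0, 50),
                "Fa": rng.uniform(0, 3000),
            }
            init = fn.default_initial_state(model, hela)
            for name, val in red.items():
                init[model.index[name]] = val
            init[model.index["CP"]] -= red["CPB"]
            init[model.index["B"]] -= red["CPB"]
            init[model.index["E"]] -= red["EA"] + red["EI"]
            init[model.index["A"]] -= red["EA"]
            init[model.index["I"]] -= red["EI"] + red["VI"]
            init[model.index["V"]] -= red["VI"]
            ss = fn.relax_to_steady(model, hela, init=init)
            assert ss.converged
            assert max_species_rel_diff(ss, reference) < 1e-6


class TestStability:
    def test_isolated_binding_eigenvalue(self, model):
        # linearization of one reversible pair: lambda = -(k_on(A+B)+k_off)
        p = isolated_capping_params()
        ss = fn.solve_steady(model, p)
        verdict = fn.assert_stable(ss, model, p)
        assert verdict.stable
        k_on, k_off = p.kinetics[1]
        expected = -(k_on * (ss["CP"] + ss["B"]) + k_off)
        assert np.any(np.isclose(verdict.eigenvalues.real, expected, rtol=1e-6))

    def test_turnover_eigenvalue_in_empty_network(self, model):
        p = fn.endogenous_params()
        p.totals = {k: 0.0 for k in p.totals}
        p.b_total = 0.0
        ss = fn.solve_steady(model, p)
        verdict = fn.assert_stable(ss, model, p)
        # the F-actin mode relaxes at exactly -k_turn when nothing binds it
        assert np.any(np.isclose(verdict.eigenvalues.real, -p.k_turn, rtol=1e-8))

    def test_all_contexts_stable(self, model):
        for name in fn.CONTEXTS:
            p = fn.cell_context(name)
            ss = fn.solve_steady(model, p)
            assert fn.assert_stable(ss, model, p).stable

    def test_unconverged_state_cannot_be_certified(self, model, hela):
        ss = fn.relax_to_steady(model, hela, t_max=1e-3, tol=1e-30, refine=False)
        with pytest.raises(ValueError, match="converged"):
            fn.assert_stable(ss, model, hela)


class TestSerialization:
    def test_steady_state_to_dict_has_diagnostics(self, model, hela):
        d = fn.solve_steady(model, hela).to_dict()
        assert {"context", "method", "converged", "residual_norm", "stable"} <= set(d)
        assert d["conc_Ga"] == hela.ga
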