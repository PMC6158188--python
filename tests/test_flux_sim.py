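"""FBA/pFBA solvers, phase constraints and prediction validation.

Solver-facing assertions stick to solver-independent quantities: objective
values, the pFBA L1 norm, steady-state residuals and uniquely determined
fluxes.
"""

import numpy as np
import pytest

from fluxomix.flux_sim import (
    ConstraintConfigurationError,
    ExchangeMap,
    PhaseConstraints,
    apply_phase_constraints,
    compute_relative_flux,
    flux_variability,
    simulate_phases,
    solve_fba,
    solve_pfba,
    validate_predictions,
)
from fluxomix.gem_model import build_stoichiometric_matrix
from fluxomix.synthetic_data import (
    FermentationScenario,
    make_random_toy_model,
    make_toy_model,
    simulate_fermentation,
)

from oracles import brute_force_fba, brute_force_pfba_l1


def assert_steady_state(model, sol, atol=1e-6):
    """Feasibility contract: ||S v||_inf <= 1e-6 and bounds to 1e-9."""
    smat = build_stoichiometric_matrix(model)
    v = np.array([sol.fluxes[rid] for rid in smat.col_index])
    assert np.max(np.abs(smat.values @ v)) <= atol
    for r in model.reactions:
        assert r.lower_bound - 1e-9 <= sol.fluxes[r.id] <= r.upper_bound + 1e-9


class TestFba:
    def test_chain_pushes_uptake_capacity(self, chain_model):
        sol = solve_fba(chain_model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0)
        assert all(v == pytest.approx(10.0) for v in sol.fluxes.values())
        assert_steady_state(chain_model, sol)

    def test_closed_system_has_zero_flux(self, chain_model):
        closed = chain_model.copy()
        closed.get_reaction("UPT").upper_bound = 0.0
        sol = solve_fba(closed)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.0)
        assert all(abs(v) <= 1e-9 for v in sol.fluxes.values())

    def test_core_biomass_matches_independent_cobra_formulation(self, core_model):
        """Dual-route check: the same reaction list formulated directly in
        cobrapy (GLPK) must give the same optimum as the in-package LP."""
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("core_check")
        mets = {m.id: cobra.Metabolite(m.id.replace("[", "_").replace("]", ""),
                                       compartment=m.compartment)
                for m in core_model.metabolites}
        for r in core_model.reactions:
            rx = cobra.Reaction(r.id)
            rx.lower_bound, rx.upper_bound = r.lower_bound, r.upper_bound
            cm.add_reactions([rx])
            rx.add_metabolites({mets[mid]: c for mid, c in r.stoichiometry.items()})
        cm.objective = "BIOMASS"
        z_cobra = cm.optimize().objective_value
        sol = solve_fba(core_model)
        assert sol.objective_value == pytest.approx(z_cobra, rel=1e-6)

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_objective_matches_vertex_enumeration(self, seed):
        model = make_random_toy_model(seed)
        z_enum, _ = brute_force_fba(model)
        sol = solve_fba(model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(z_enum, abs=1e-8)
        assert_steady_state(model, sol)

    def test_infeasible_reported_without_fluxes(self, chain_model):
        broken = chain_model.copy()
        broken.get_reaction("UPT").lower_bound = 5.0
        broken.get_reaction("UPT").upper_bound = 5.0
        broken.get_reaction("CONV").upper_bound = 1.0
        broken.get_reaction("CONV").lower_bound = 0.0
        sol = solve_fba(broken)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    def test_empty_objective_rejected(self, chain_model):
        bare = chain_model.copy()
        bare.objective = {}
        with pytest.raises(ValueError, match="objective"):
            solve_fba(bare)

    def test_loosening_a_bound_never_decreases_max_objective(self, core_model):
        base = solve_fba(core_model).objective_value
        for rid in ("EX_glc", "EX_o2", "EMP"):
            loose = core_model.copy()
            rxn = loose.get_reaction(rid)
            rxn.lower_bound -= 5.0
            rxn.upper_bound += 5.0
            assert solve_fba(loose).objective_value >= base - 1e-9

    def test_scaling_rates_scales_optimal_fluxes(self, core_model):
        lam = 2.5
        scaled = core_model.copy()
        for r in scaled.reactions:
            r.lower_bound *= lam
            r.upper_bound *= lam
        z1 = solve_fba(core_model).objective_value
        z2 = solve_fba(scaled).objective_value
        assert z2 == pytest.approx(lam * z1, rel=1e-8)


class TestPfba:
    def test_unique_optimum_equals_fba(self, chain_model):
        fba = solve_fba(chain_model)
        pfba = solve_pfba(chain_model)
        assert pfba.objective_value == pytest.approx(fba.objective_value, rel=1e-8)
        for rid, v in fba.fluxes.items():
            assert pfba.fluxes[rid] == pytest.approx(v, abs=1e-7)

    def test_diamond_routes_through_short_path(self, diamond_model):
        l1_enum, z_enum = brute_force_pfba_l1(diamond_model)
        sol = solve_pfba(diamond_model)
        assert sol.objective_value == pytest.approx(z_enum, rel=1e-8)
        assert sol.total_absolute_flux == pytest.approx(l1_enum, abs=1e-6)
        # all flux on the 2-reaction branch
        assert sol.fluxes["P1A"] == pytest.approx(10.0, abs=1e-6)
        assert sol.fluxes["P2A"] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(1, 8))
    def test_l1_dominates_any_optimal_vertex(self, seed):
        model = make_random_toy_model(seed)
        sol = solve_pfba(model)
        assert sol.optimal
        l1_enum, z_enum = brute_force_pfba_l1(model)
        assert sol.objective_value == pytest.approx(z_enum, abs=1e-7)
        assert sol.total_absolute_flux <= l1_enum + 1e-6

    def test_l1_never_exceeds_plain_fba_l1(self, core_model):
        fba = solve_fba(core_model)
        pfba = solve_pfba(core_model)
        assert pfba.total_absolute_flux <= sum(
            abs(v) for v in fba.fluxes.values()
        ) + 1e-6
        assert pfba.objective_value == pytest.approx(
            fba.objective_value, rel=1e-8
        )
        assert_steady_state(core_model, pfba)


class TestPhaseConstraints:
    def test_zero_tolerance_pins_rates_exactly(self, core_model):
        pc = PhaseConstraints(
            time_h=16.0, q_S=1.0, q_O2=2.0, q_P=0.01, m_ATP=1.0, tolerance=0.0
        )
        out = apply_phase_constraints(core_model, pc)
        glc = out.get_reaction("EX_glc")
        assert (glc.lower_bound, glc.upper_bound) == (-1.0, -1.0)
        atpm = out.get_reaction("ATPM")
        assert (atpm.lower_bound, atpm.upper_bound) == (1.0, 1.0)

    def test_relative_band_orientation_under_uptake_negative_convention(
        self, core_model
    ):
        pc = PhaseConstraints(
            time_h=16.0, q_S=2.0, q_O2=4.0, q_P=0.5,
            q_byproducts={"EX_succ": 0.2}, m_ATP=1.0, tolerance=0.1,
        )
        out = apply_phase_constraints(core_model, pc)
        o2 = out.get_reaction("EX_o2")
        assert o2.lower_bound == pytest.approx(-4.4)
        assert o2.upper_bound == pytest.approx(-3.6)
        succ = out.get_reaction("EX_succ")
        assert succ.lower_bound == pytest.approx(0.18)
        assert succ.upper_bound == pytest.approx(0.22)

    def test_exactly_five_bound_groups_modified(self, core_model):
        pc = PhaseConstraints(
            time_h=16.0, q_S=1.0, q_O2=2.0, q_P=0.01,
            q_byproducts={"EX_succ": 0.1}, m_ATP=1.0,
        )
        out = apply_phase_constraints(core_model, pc)
        changed = [
            r.id for r in out.reactions
            if (r.lower_bound, r.upper_bound)
            != (
                core_model.get_reaction(r.id).lower_bound,
                core_model.get_reaction(r.id).upper_bound,
            )
        ]
        assert set(changed) == {"EX_glc", "EX_o2", "EX_glaA", "EX_succ", "ATPM"}

    def test_anoxia_makes_obligate_aerobe_infeasible(self, core_model):
        pc = PhaseConstraints(
            time_h=30.0, q_S=1.0, q_O2=0.0, m_ATP=1.0, tolerance=0.0
        )
        out = apply_phase_constraints(core_model, pc)
        assert solve_fba(out).status == "infeasible"

    def test_unknown_exchange_named_in_error(self, core_model):
        pc = PhaseConstraints(
            time_h=1.0, q_S=1.0, q_O2=1.0, q_byproducts={"EX_ghost": 0.1}
        )
        with pytest.raises(ConstraintConfigurationError, match="EX_ghost"):
            apply_phase_constraints(core_model, pc)

    def test_invalid_tolerance_rejected(self):
        with pytest.raises(ValueError, match="tolerance"):
            PhaseConstraints(time_h=0.0, q_S=1.0, q_O2=1.0, tolerance=1.5)


class TestRelativeFlux:
    def test_uniform_chain_maps_to_hundred(self, chain_model):
        sol = solve_fba(chain_model)
        rel = compute_relative_flux(sol, "UPT")
        assert all(v == pytest.approx(100.0) for v in rel.values())

    def test_branch_split_arithmetic(self):
        from fluxomix.flux_sim import FBASolution

        sol = FBASolution(
            status="optimal", objective_value=10.0,
            fluxes={"uptake": 10.0, "branch_a": 4.0, "branch_b": 6.0},
        )
        rel = compute_relative_flux(sol, "uptake")
        assert rel == pytest.approx(
            {"uptake": 100.0, "branch_a": 40.0, "branch_b": 60.0}
        )

    def test_near_zero_reference_advises_absolute(self, chain_model):
        closed = chain_model.copy()
        closed.get_reaction("UPT").upper_bound = 0.0
        sol = solve_fba(closed)
        with pytest.raises(ValueError, match="absolute"):
            compute_relative_flux(sol, "UPT")


class TestSimulatePhases:
    def test_empty_phase_list_yields_empty_result(self, core_model):
        assert simulate_phases(core_model, []) == []

    def test_infeasible_phase_does_not_abort_batch(self, core_model):
        good = PhaseConstraints(time_h=16.0, q_S=1.0, q_O2=1.2, m_ATP=1.0)
        bad = PhaseConstraints(time_h=40.0, q_S=1.0, q_O2=0.0, m_ATP=1.0,
                               tolerance=0.0)
        results = simulate_phases(core_model, [good, bad])
        assert [r.solution.status for r in results] == ["optimal", "infeasible"]
        assert results[1].mu_predicted is None

    def test_mu_equals_biomass_flux_and_qco2_the_exchange_flux(
        self, core_model, noise_free_fermentation
    ):
        results = simulate_phases(core_model, noise_free_fermentation["phases"])
        for r in results:
            assert r.mu_predicted == pytest.approx(r.solution.fluxes["BIOMASS"])
            assert r.qCO2_predicted == pytest.approx(r.solution.fluxes["EX_co2"])
            assert r.relative_fluxes["EX_glc"] == pytest.approx(-100.0)


class TestValidatePredictions:
    def test_noise_free_closed_loop_recovers_truth_exactly(
        self, core_model, noise_free_fermentation
    ):
        results = simulate_phases(core_model, noise_free_fermentation["phases"])
        report = validate_predictions(results, noise_free_fermentation["measured"])
        assert report["summary"]["mean_rel_error_mu"] == pytest.approx(0.0, abs=1e-6)
        assert report["summary"]["mean_rel_error_qCO2"] == pytest.approx(0.0, abs=1e-6)

    def test_ten_percent_perturbation_reports_point_one(
        self, core_model, noise_free_fermentation
    ):
        results = simulate_phases(core_model, noise_free_fermentation["phases"])
        measured = {
            t: {"mu": m["mu"] * 1.1, "qCO2": m["qCO2"] * 1.1}
            for t, m in noise_free_fermentation["measured"].items()
        }
        report = validate_predictions(results, measured)
        for entry in report["per_phase"].values():
            assert entry["mu_rel_error"] == pytest.approx(0.1 / 1.1, rel=1e-3)

    def test_phase_key_mismatch_listed(self, core_model, noise_free_fermentation):
        results = simulate_phases(core_model, noise_free_fermentation["phases"][:2])
        with pytest.raises(KeyError, match="mismatch"):
            validate_predictions(results, noise_free_fermentation["measured"])


class TestFluxVariability:
    def test_diamond_branches_are_degenerate_but_total_is_not(self, diamond_model):
        fva = flux_variability(diamond_model)
        lo, hi = fva["P1A"]
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(10.0, abs=1e-6)
        lo, hi = fva["SEC"]
        assert lo == pytest.approx(10.0, abs=1e-6)
        assert hi == pytest.approx(10.0, abs=1e-6)
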