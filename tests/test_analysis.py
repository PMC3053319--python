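"""Growth sweep, phase detector, two-strategy geometry, amino acids,
enzyme concentrations and expression correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import crowdfba as cf
from crowdfba.analysis import round_to_sig


class TestGrowthSweep:
    def test_growth_concave_nondecreasing(self, toy_sweep):
        g = np.array([p.growth_rate for p in toy_sweep.points])
        assert np.all(np.diff(g) >= -1e-9)
        assert np.all(np.diff(g, 2) <= 1e-6)  # LP value function is concave

    def test_yield_nonincreasing_under_crowding(self, toy_sweep):
        y = np.array([p.growth_yield for p in toy_sweep.points])
        assert np.all(np.diff(y) <= 1e-6)

    def test_zero_uptake_yield_is_stoichiometric_limit(self, toy, toy_sweep):
        y_resp, _ = toy.spec.respiration_strategy()
        assert toy_sweep.points[0].growth_yield == pytest.approx(y_resp, abs=1e-9)

    def test_stoichiometric_sweep_constant_yield_no_lactate(self, toy):
        sweep = cf.growth_sweep(toy.model, toy.medium, None, n_points=8, max_uptake=1.0)
        y_resp, _ = toy.spec.respiration_strategy()
        for p in sweep.points:
            assert p.growth_yield == pytest.approx(y_resp, abs=1e-6)
            assert p.lactate_range.max_flux <= 1e-6
            assert not p.cap_binding

    def test_saturating_uptake_matches_closed_form(self, toy, toy_sweep):
        _, cost_ferm = toy.spec.fermentation_strategy()
        assert toy_sweep.uptake_at_max == pytest.approx(toy.spec.cap / cost_ferm, rel=1e-6)

    def test_cap_binding_flag_tracks_the_phase_structure(self, toy_sweep):
        flags = [p.cap_binding for p in toy_sweep.points]
        assert not flags[0] and flags[-1]
        assert flags == sorted(flags)  # once binding, stays binding

    def test_three_point_sweep_on_linear_chain(self, toy):
        sweep = cf.growth_sweep(toy.model, toy.medium, None, n_points=3, max_uptake=0.02)
        g = [p.growth_rate for p in sweep.points]
        # well below the cap, growth is proportional to uptake
        assert len(g) == 3
        assert g[2] == pytest.approx(2 * g[1], rel=1e-6)

    def test_without_crowding_needs_max_uptake(self, toy):
        with pytest.raises(cf.ModelValidationError, match="max_uptake"):
            cf.growth_sweep(toy.model, toy.medium, None)


class TestDetectPhases:
    def test_constructed_boundaries_recovered(self):
        sweep = cf.make_synthetic_sweep((0.40, 0.90), n_points=101)
        phases = cf.detect_phases(sweep)
        assert phases.boundary_I_II == pytest.approx(0.40, abs=0.011)
        assert phases.boundary_II_III == pytest.approx(0.90, abs=0.011)
        assert not phases.no_phase_III

    def test_uniform_cost_control_has_no_phase_iii(self, uniform_toy):
        sweep = cf.growth_sweep(uniform_toy.model, uniform_toy.medium, uniform_toy.crowding, n_points=25)
        phases = cf.detect_phases(sweep)
        assert phases.no_phase_III
        assert phases.boundary_II_III == 1.0

    def test_grid_refinement_moves_boundaries_less_than_one_cell(self):
        for n in (51, 101):
            coarse = cf.detect_phases(cf.make_synthetic_sweep((0.43, 0.92), n_points=n))
            fine = cf.detect_phases(cf.make_synthetic_sweep((0.43, 0.92), n_points=2 * n - 1))
            cell = 1.0 / (n - 1)
            assert abs(coarse.boundary_I_II - fine.boundary_I_II) <= cell + 1e-9
            assert abs(coarse.boundary_II_III - fine.boundary_II_III) <= cell + 1e-9

    def test_toy_boundaries_match_two_strategy_geometry(self, toy, toy_sweep):
        """On the two-route fixture the phase-I boundary sits at the ratio of
        the strategies' yield-to-cost ratios (cap-binding onset)."""
        ya, ca = toy.spec.respiration_strategy()
        yb, cb = toy.spec.fermentation_strategy()
        expected = (ya / ca) / (yb / cb)
        phases = cf.detect_phases(toy_sweep)
        cell = 1.0 / (len(toy_sweep.points) - 1)
        assert phases.boundary_I_II == pytest.approx(expected, abs=2 * cell)
        assert phases.boundary_II_III == pytest.approx(expected, abs=2 * cell)


def _brute_force(spec: cf.TwoStrategySpec, n=20001):
    ua = np.linspace(0.0, min(spec.U, spec.C / spec.C_A), n)
    ub = np.minimum(spec.U - ua, (spec.C - spec.C_A * ua) / spec.C_B)
    ub = np.maximum(ub, 0.0)
    growth = spec.Y_A * ua + spec.Y_B * ub
    return float(growth.max())


class TestTwoStrategy:
    def test_pure_a_when_cap_slack(self):
        spec = cf.TwoStrategySpec(Y_A=1.0, C_A=0.5, Y_B=0.4, C_B=0.1, U=1.0, C=10.0)
        ua, ub, growth = cf.two_strategy_optimum(spec)
        assert (ua, ub) == (1.0, 0.0)
        assert growth == pytest.approx(1.0)

    def test_pure_b_with_printed_ratios_when_uptake_unlimited(self):
        # B's yield-to-cost ratio 0.7 beats A's 0.31, so with ample glucose
        # the optimum is pure fermentation
        spec = cf.TwoStrategySpec(Y_A=0.094, C_A=0.302, Y_B=0.035, C_B=0.050, U=1e6, C=0.078)
        ua, ub, growth = cf.two_strategy_optimum(spec)
        assert ua == pytest.approx(0.0, abs=1e-9)
        assert growth == pytest.approx(0.035 * 0.078 / 0.050, rel=1e-9)

    def test_mixed_solution_matches_brute_force(self):
        spec = cf.TwoStrategySpec(Y_A=0.094, C_A=0.302, Y_B=0.035, C_B=0.050, U=1.0, C=0.1)
        _, _, growth = cf.two_strategy_optimum(spec)
        assert growth == pytest.approx(_brute_force(spec), abs=1e-3)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        ya=st.floats(0.01, 2.0), ca=st.floats(0.01, 2.0),
        yb=st.floats(0.01, 2.0), cb=st.floats(0.01, 2.0),
        u=st.floats(0.1, 3.0), c=st.floats(0.01, 1.0),
    )
    def test_vertex_enumeration_matches_brute_force(self, ya, ca, yb, cb, u, c):
        spec = cf.TwoStrategySpec(ya, ca, yb, cb, u, c)
        _, _, growth = cf.two_strategy_optimum(spec)
        assert growth == pytest.approx(_brute_force(spec), abs=2e-3)

    def test_yield_to_cost_ratio_printed_values(self):
        assert round_to_sig(cf.yield_to_cost_ratio(0.094, 0.302), 2) == 0.31
        assert round_to_sig(cf.yield_to_cost_ratio(0.035, 0.050), 2) == 0.70

    def test_yield_to_cost_identity_and_error(self):
        assert cf.yield_to_cost_ratio(0.42, 0.42) == 1.0
        with pytest.raises(cf.ModelValidationError):
            cf.yield_to_cost_ratio(1.0, 0.0)


class TestAminoAcidSweep:
    def test_glutamine_beats_glutamate_under_crowding(self, toy_aa):
        gains = cf.amino_acid_sweep(
            toy_aa.model, toy_aa.medium, toy_aa.crowding, ["EX_gln", "EX_glu"]
        )
        crowd = gains[gains["mode"] == "crowding"].set_index("amino_acid")["gain_abs"]
        assert crowd["EX_gln"] > crowd["EX_glu"] > 0

    def test_amino_acid_without_consumer_gains_nothing(self, toy_aa):
        gains = cf.amino_acid_sweep(toy_aa.model, toy_aa.medium, toy_aa.crowding, ["EX_ala"])
        assert (gains["gain_abs"].abs() < 1e-9).all()

    def test_missing_exchange_reported_not_fatal(self, toy_aa, caplog):
        with caplog.at_level("WARNING", logger="crowdfba"):
            gains = cf.amino_acid_sweep(
                toy_aa.model, toy_aa.medium, toy_aa.crowding, ["EX_gln", "EX_missing"]
            )
        miss = gains[gains["amino_acid"] == "EX_missing"]
        assert miss["gain_abs"].isna().all()
        assert len(gains[gains["amino_acid"] == "EX_gln"]) == 2

    def test_huge_cap_recovers_stoichiometric_gains(self, toy_aa):
        gains = cf.amino_acid_sweep(
            toy_aa.model, toy_aa.medium, toy_aa.crowding.with_cap(1e6), ["EX_gln", "EX_glu"]
        )
        piv = gains.pivot(index="amino_acid", columns="mode", values="gain_abs")
        assert np.allclose(piv["stoichiometric"], piv["crowding"], atol=1e-6)


class TestEnzymeConcentrations:
    def test_zero_flux_zero_concentrations(self, toy):
        sol = cf.fba(toy.model, toy.medium.with_uptake("EX_glc", 0.0), crowding=toy.crowding)
        concs = cf.enzyme_concentrations(sol, toy.enzyme_params, toy.model.gene_to_reactions)
        assert all(c.concentration == pytest.approx(0.0, abs=1e-9) for c in concs)

    def test_gene_sums_over_its_reactions(self):
        params = [
            cf.EnzymeParams("R1", kcat=3600.0, molecular_weight=3.6e6),  # coeff 1.0
            cf.EnzymeParams("R2", kcat=3600.0, molecular_weight=7.2e6),  # coeff 2.0
        ]
        sol = cf.FluxSolution({"R1": 1.0, "R2": 1.0}, 0.0, "optimal")
        (g,) = cf.enzyme_concentrations(sol, params, {"g": ["R1", "R2"]})
        assert g.concentration == pytest.approx(3.0)

    def test_total_bounded_by_cap_modulo_shared_reactions(self, toy):
        sol = cf.fba(toy.model, toy.medium.with_uptake("EX_glc", 10.0), crowding=toy.crowding)
        concs = cf.enzyme_concentrations(sol, toy.enzyme_params, toy.model.gene_to_reactions)
        total = sum(c.concentration for c in concs)
        # GLYC carries two genes, so its concentration is counted twice; the
        # remaining gene-wise total cannot exceed the spent budget
        by_id = {p.reaction_id: p for p in toy.enzyme_params}
        glyc_conc = sol.net()["GLYC"] * by_id["GLYC"].cost_coefficient
        assert total - glyc_conc <= toy.spec.cap + 1e-6


class TestCorrelateExpression:
    def test_monotone_transform_gives_perfect_rho(self):
        conc = {f"g{i}": float(i) for i in range(20)}
        expr = pd.DataFrame(
            {"c1": np.exp(np.arange(20.0) / 5), "c2": np.arange(20.0) ** 2},
            index=list(conc),
        )
        res = cf.correlate_expression(conc, expr)
        assert res.per_column.tolist() == pytest.approx([1.0, 1.0])

    def test_independent_expression_mean_rho_near_zero(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(200)]
        conc = dict(zip(genes, rng.gamma(2.0, size=200)))
        expr = pd.DataFrame(rng.normal(size=(200, 50)), index=genes,
                            columns=[f"c{j}" for j in range(50)])
        res = cf.correlate_expression(conc, expr)
        se = (1 / np.sqrt(199)) / np.sqrt(50)
        assert abs(res.mean_rho) < 3 * se

    def test_calibrated_noise_recovers_target_rho(self):
        rng = np.random.default_rng(1)
        conc = {f"g{i}": v for i, v in enumerate(rng.gamma(2.0, size=300))}
        expr = cf.make_synthetic_expression(conc, rho_target=0.3, n_columns=30, seed=2)
        res = cf.correlate_expression(conc, expr)
        assert 0.2 <= res.mean_rho <= 0.4

    def test_paired_comparison_separates_informative_model(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(300)]
        conc_good = dict(zip(genes, rng.gamma(2.0, size=300)))
        vals = np.fromiter(conc_good.values(), float)
        conc_bad = dict(zip(genes, rng.permutation(vals)))  # scrambled predictions
        expr = cf.make_synthetic_expression(conc_good, rho_target=0.4, n_columns=40, seed=4)
        res = cf.correlate_expression(conc_good, expr, other_concentrations=conc_bad)
        assert res.mean_rho > res.mean_rho_other
        assert res.wilcoxon_p < 1e-4

    def test_too_few_shared_genes_skips_column(self, caplog):
        conc = {"g1": 1.0, "g2": 2.0}
        expr = pd.DataFrame({"c1": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(cf.ModelValidationError):
            cf.correlate_expression(conc, expr)  # fewer than 3 shared genes anywhere
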