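"""ACHR sampling: chord geometry, uniformity, determinism, summaries."""

import numpy as np
import pytest
from scipy import stats

import crowdfba as cf
from crowdfba.sampler import chord_limits


def _segment_model(lo=2.0, hi=5.0):
    """Flux space is the 1-D segment v_in = v_out in [lo, hi]."""
    mets = [cf.Metabolite("m")]
    rxns = [
        cf.Reaction("IN", {"m": 1}, lo, hi, is_exchange=True),
        cf.Reaction("OUT", {"m": -1}, 0.0, 10.0, is_exchange=True),
    ]
    return cf.MetabolicModel(mets, rxns, biomass_reaction_id="OUT")


class TestChordLimits:
    def test_box_only(self):
        x = np.array([0.5, 0.5])
        d = np.array([1.0, 0.0])
        t_min, t_max = chord_limits(x, d, np.zeros(2), np.ones(2))
        assert (t_min, t_max) == (-0.5, 0.5)

    def test_matches_bisection_oracle_on_random_polytope(self):
        """Analytic chord endpoints vs. feasibility bisection on a random 3-D
        polytope (box + random half-spaces)."""
        rng = np.random.default_rng(7)
        lb, ub = np.zeros(3), np.ones(3)
        A = rng.normal(size=(5, 3))
        x0 = np.full(3, 0.5)
        b = A @ x0 + rng.uniform(0.05, 0.5, size=5)  # keep x0 strictly inside

        def feasible(p):
            return np.all(p >= lb - 1e-12) and np.all(p <= ub + 1e-12) and np.all(A @ p <= b + 1e-12)

        for _ in range(25):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            t_min, t_max = chord_limits(x0, d, lb, ub, A, b)
            for t_analytic, sign in ((t_max, 1.0), (t_min, -1.0)):
                lo_t, hi_t = 0.0, 10.0
                for _ in range(60):  # bisect the feasibility boundary
                    mid = 0.5 * (lo_t + hi_t)
                    if feasible(x0 + sign * mid * d):
                        lo_t = mid
                    else:
                        hi_t = mid
                assert sign * t_analytic == pytest.approx(lo_t, abs=1e-6)


class TestACHR:
    def test_segment_mean(self):
        model = _segment_model(2.0, 5.0)
        ss = cf.achr_sample(model, n_samples=400, seed=11, thinning=2)
        vals = ss.to_frame()["OUT"].to_numpy()
        se = np.sqrt(9.0 / 12.0 / len(vals))
        assert abs(vals.mean() - 3.5) < 3 * se + 0.05  # slack for autocorrelation

    def test_all_rows_satisfy_constraints(self, toy):
        ss = cf.achr_sample(
            toy.model, toy.medium, toy.crowding, growth_fraction=0.9,
            n_samples=40, seed=3, thinning=5,
        )
        viol = ss.max_violation(toy.crowding)
        assert max(viol.values()) <= 1e-6

    def test_seed_determinism(self, toy):
        kwargs = dict(growth_fraction=0.5, n_samples=20, seed=42, thinning=5)
        a = cf.achr_sample(toy.model, toy.medium, toy.crowding, **kwargs)
        b = cf.achr_sample(toy.model, toy.medium, toy.crowding, **kwargs)
        assert np.array_equal(a.samples, b.samples)

    def test_box_marginal_uniform(self):
        """On a region whose only constraints are box bounds, the sampled
        marginal should be indistinguishable from uniform (KS, alpha=0.01)."""
        model = _segment_model(0.0, 1.0)
        ss = cf.achr_sample(model, n_samples=5000, seed=5, thinning=2)
        vals = ss.to_frame()["OUT"].to_numpy()
        assert stats.kstest(vals, "uniform").pvalue > 0.01

    def test_phase_iii_growth_fixing_forces_lactate(self, toy, toy_sweep):
        phases = cf.detect_phases(toy_sweep)
        frac = 0.5 * (phases.boundary_II_III + 1.0)
        medium = toy.medium.with_uptake("EX_glc", toy_sweep.uptake_at_max)
        ss = cf.achr_sample(
            toy.model, medium, toy.crowding, growth_fraction=frac,
            n_samples=30, seed=9, thinning=5,
        )
        med = cf.median_flux(ss)
        assert med.net()["EX_lac"] > 1e-3
        assert min(ss.to_frame()["EX_lac"]) > 0  # every sample secretes


class TestMedianFlux:
    def test_single_sample_is_identity(self, toy):
        ss = cf.achr_sample(toy.model, toy.medium, toy.crowding, n_samples=1, seed=0, thinning=3)
        med = cf.median_flux(ss)
        assert med.fluxes == dict(zip(ss.reaction_ids, map(float, ss.samples[0])))

    def test_pairwise_median(self):
        model = _segment_model(0.0, 10.0)
        ss = cf.achr_sample(model, n_samples=2, seed=1, thinning=2)
        ss.samples = np.array([[0.0, 0.0], [10.0, 10.0]])
        med = cf.median_flux(ss)
        assert med.fluxes["OUT"] == 5.0

    def test_mass_balance_residual_bounded_by_spread(self, toy):
        ss = cf.achr_sample(
            toy.model, toy.medium, toy.crowding, growth_fraction=0.8,
            n_samples=50, seed=2, thinning=5,
        )
        med = cf.median_flux(ss)
        S = np.abs(ss.model.stoichiometric_matrix().toarray())
        spread = np.ptp(ss.samples, axis=0).max()
        # triangle inequality: the median differs from any feasible row by at
        # most the per-coordinate spread, and S annihilates feasible rows
        assert med.binding_report["mass_balance_residual_inf"] <= S.sum(axis=1).max() * spread + 1e-9


class TestPathwayActivity:
    def test_single_reaction_pathway_equals_median_flux(self, toy):
        ss = cf.achr_sample(toy.model, toy.medium, toy.crowding, n_samples=20, seed=4, thinning=5)
        med = cf.median_flux(ss)
        (act,) = cf.pathway_activity(ss, {"glycolysis": ["GLYC"]})
        assert act.mean_flux == pytest.approx(abs(med.net()["GLYC"]))

    def test_empty_pathway_skipped(self, toy, caplog):
        ss = cf.achr_sample(toy.model, toy.medium, toy.crowding, n_samples=5, seed=4, thinning=5)
        with caplog.at_level("WARNING", logger="crowdfba"):
            out = cf.pathway_activity(ss, {"ghost": ["NOPE"]})
        assert out == []
        assert any("ghost" in rec.message for rec in caplog.records)

    def test_phase_pattern_glycolysis_and_oxphos(self, toy, toy_sweep):
        """Across the three operating points the fixture reproduces the
        expected pattern: glycolytic activity highest in phase III, oxygen-
        consuming (oxphos) activity higher in phase II than in phase I."""
        phases = cf.detect_phases(toy_sweep)
        ops = cf.phase_operating_points(toy_sweep, phases)
        act = {}
        for phase, growth in ops.items():
            # pin the glucose bound to the uptake that realises this phase's
            # operating growth rate, then sample near that point's optimum
            uptake = min(
                (p.glucose_uptake for p in toy_sweep.points if p.growth_rate >= growth - 1e-9),
                default=toy_sweep.uptake_at_max,
            )
            medium = toy.medium.with_uptake("EX_glc", uptake)
            ss = cf.achr_sample(
                toy.model, medium, toy.crowding, growth_fraction=0.99,
                n_samples=40, seed=21, thinning=5,
            )
            act[phase] = {a.pathway: a.mean_flux for a in cf.pathway_activity(ss, toy.pathway_map)}
        assert act["III"]["glycolysis"] > act["I"]["glycolysis"]
        assert act["II"]["oxphos"] > act["I"]["oxphos"]
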