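"""kcat/MW assignment, cap arithmetic, and crowding-cost accounting."""

import numpy as np
import pandas as pd
import pytest

import crowdfba as cf
from crowdfba.enzymes import FLUX_SCALE, MEDIAN_FILL, assign_enzyme_params


class TestComputeCap:
    def test_protein_times_metabolic_fraction(self):
        assert round(cf.compute_cap(0.779, 0.1), 3) == 0.078

    def test_identity(self):
        assert cf.compute_cap(1.0, 1.0) == 1.0

    def test_arithmetic(self):
        assert cf.compute_cap(0.5, 0.2) == pytest.approx(0.1)

    @pytest.mark.parametrize("args", [(0.0, 0.5), (0.5, 0.0), (-1, 0.5), (0.5, 1.5)])
    def test_out_of_range_rejected(self, args):
        with pytest.raises(cf.ModelValidationError):
            cf.compute_cap(*args)


def _model_for_assignment():
    mets = [cf.Metabolite(m) for m in ("A", "B", "C", "D")]
    rxns = [
        cf.Reaction("EX_A", {"A": -1}, -10, 10, is_exchange=True),
        cf.Reaction("R1", {"A": -1, "B": 1}, 0, 10, ec_number="1.1.1.1"),
        cf.Reaction("R2", {"B": -1, "C": 1}, -10, 10, ec_number="2.2.2.2"),
        cf.Reaction("R3", {"C": -1, "D": 1}, 0, 10),  # no kcat data -> median fill
        cf.Reaction("BIO", {"D": -1}, 0, 10, is_biomass=True),
    ]
    return cf.MetabolicModel(mets, rxns, biomass_reaction_id="BIO")


class TestAssignEnzymeParams:
    def test_precedence_and_max_within_category(self):
        model = _model_for_assignment()
        kt = pd.DataFrame(
            {
                "ec": ["1.1.1.1", "1.1.1.1", "1.1.1.1", "2.2.2.2"],
                "kcat_per_s": [5.0, 9.0, 100.0, 2.0],
                "kcat_source": ["human_wildtype", "human_wildtype", "sabio", "nonhuman_wildtype"],
            }
        )
        mw = pd.DataFrame({"ec": ["1.1.1.1", "2.2.2.2"], "mw_mg_per_mmol": [50000.0, 80000.0]})
        params = {p.reaction_id: p for p in assign_enzyme_params(model, kt, mw)}
        # human wild-type wins over the larger sabio value; max within category
        assert params["R1"].kcat == pytest.approx(9.0 * 3600)
        assert params["R1"].kcat_source == "human_wildtype"
        assert params["R2"].kcat == pytest.approx(2.0 * 3600)

    def test_median_fill_odd(self):
        model = _model_for_assignment()
        kt = pd.DataFrame(
            {
                "reaction_id": ["R1", "R2", "EX_A"],
                "kcat_per_s": [1.0, 2.0, 100.0],
                "kcat_source": ["human_wildtype"] * 3,
            }
        )
        params = {p.reaction_id: p for p in assign_enzyme_params(model, kt, None)}
        assert params["R3"].kcat == pytest.approx(2.0 * 3600)  # median of {1, 2, 100}
        assert params["R3"].kcat_source == MEDIAN_FILL

    def test_median_fill_even_count_averages_central_pair(self):
        model = _model_for_assignment()
        kt = pd.DataFrame(
            {
                "reaction_id": ["R1", "R2"],
                "kcat_per_s": [1.0, 3.0],
                "kcat_source": ["human_wildtype"] * 2,
            }
        )
        params = {p.reaction_id: p for p in assign_enzyme_params(model, kt, None)}
        assert params["R3"].kcat == pytest.approx(2.0 * 3600)

    def test_median_invariant_to_row_order_and_duplicates(self):
        model = _model_for_assignment()
        base = pd.DataFrame(
            {
                "reaction_id": ["R1", "R2"],
                "kcat_per_s": [1.0, 3.0],
                "kcat_source": ["human_wildtype"] * 2,
            }
        )
        dup = pd.concat([base.iloc[::-1], base.iloc[[0]], base.iloc[[0]]], ignore_index=True)
        p1 = {p.reaction_id: p.kcat for p in assign_enzyme_params(model, base, None)}
        p2 = {p.reaction_id: p.kcat for p in assign_enzyme_params(model, dup, None)}
        assert p1 == p2

    def test_exchange_and_biomass_exempt(self):
        model = _model_for_assignment()
        kt = pd.DataFrame({"reaction_id": ["R1"], "kcat_per_s": [1.0], "kcat_source": ["sabio"]})
        params = {p.reaction_id: p for p in assign_enzyme_params(model, kt, None)}
        assert params["EX_A"].exempt and params["BIO"].exempt
        assert not params["R1"].exempt

    def test_split_directions_share_params(self):
        model = cf.split_reversible(_model_for_assignment())
        kt = pd.DataFrame({"reaction_id": ["R2"], "kcat_per_s": [4.0], "kcat_source": ["sabio"]})
        params = {p.reaction_id: p for p in assign_enzyme_params(model, kt, None)}
        # one entry keyed by the original id covers both directions
        assert "R2" in params and "R2__fwd" not in params
        cp = cf.CrowdingParams.from_enzyme_params(list(params.values()), cap=1.0)
        assert cp.coefficient_for("R2__fwd") == cp.coefficient_for("R2__rev")

    def test_empty_table_rejected(self):
        with pytest.raises(cf.ModelValidationError, match="empty"):
            assign_enzyme_params(_model_for_assignment(), pd.DataFrame(), None)


class TestCrowdingCost:
    def test_zero_fluxes_zero_cost(self, toy):
        cost = cf.crowding_cost({r: 0.0 for r in toy.model.reaction_ids}, toy.crowding)
        assert cost["total"] == 0.0

    def test_single_reaction_arithmetic(self):
        p = cf.EnzymeParams("R", kcat=50.0, molecular_weight=100.0)
        cp = cf.CrowdingParams.from_enzyme_params([p], cap=1.0)
        cost = cf.crowding_cost({"R": 2.0}, cp)
        assert cost["total"] == pytest.approx(2.0 * 100.0 / 50.0 * FLUX_SCALE)

    def test_linearity_doubling_fluxes_doubles_cost(self, toy):
        sol = cf.fba(toy.model, toy.medium, crowding=toy.crowding)
        c1 = cf.crowding_cost(sol.fluxes, toy.crowding)["total"]
        c2 = cf.crowding_cost({k: 2 * v for k, v in sol.fluxes.items()}, toy.crowding)["total"]
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_binding_constraint_cost_equals_cap(self, toy):
        # at high glucose availability the cap binds, so the optimum spends it fully
        medium = toy.medium.with_uptake("EX_glc", 10.0)
        sol = cf.fba(toy.model, medium, crowding=toy.crowding)
        assert sol.cap_binding
        cost = cf.crowding_cost(sol.fluxes, toy.crowding)["total"]
        assert cost == pytest.approx(toy.spec.cap, abs=1e-6)

    def test_unparameterised_flux_rejected(self):
        p = cf.EnzymeParams("R", kcat=50.0, molecular_weight=100.0)
        cp = cf.CrowdingParams.from_enzyme_params([p], cap=1.0)
        with pytest.raises(cf.ModelValidationError, match="no crowding parameters"):
            cf.crowding_cost({"R": 1.0, "MYSTERY": 1.0}, cp)

    def test_negative_flux_rejected(self):
        p = cf.EnzymeParams("R", kcat=50.0, molecular_weight=100.0)
        cp = cf.CrowdingParams.from_enzyme_params([p], cap=1.0)
        with pytest.raises(cf.ModelValidationError, match="split"):
            cf.crowding_cost({"R": -1.0}, cp)


def test_enzyme_table_round_trip(toy, tmp_path):
    path = tmp_path / "enzymes.tsv"
    cf.write_enzyme_table(toy.enzyme_params, path, toy.model)
    back = cf.read_enzyme_table(path)
    orig = {p.reaction_id: p for p in toy.enzyme_params}
    assert {p.reaction_id for p in back} == set(orig)
    for p in back:
        assert p.kcat == pytest.approx(orig[p.reaction_id].kcat)
        assert p.molecular_weight == pytest.approx(orig[p.reaction_id].molecular_weight)
        assert p.exempt == orig[p.reaction_id].exempt


def test_median_known_kcat(toy):
    # known (non-median-fill) kcats of the fixture: 1, 1, 0.5 per second
    assert cf.median_known_kcat(toy.enzyme_params) == pytest.approx(1.0 * 3600)
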