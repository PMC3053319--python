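"""Linear-programming core: FBA, crowding-constrained FBA, FVA, ATP yields.

Flux balance analysis maximises an objective flux (usually biomass) subject
to the steady-state constraint S·v = 0 and the flux bounds.  When crowding
parameters are supplied the model is split into unidirectional reactions
(v >= 0) and one linear inequality per cap group,
``sum_i a_i v_i <= C``, is added.

All headline quantities that depend on the particular optimal vertex
(lactate, oxygen) should be reported as FVA ranges, not single FBA vectors:
alternate optima are the rule in these models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import (
    MetabolicModel,
    Medium,
    ModelValidationError,
    apply_medium,
    net_fluxes,
    split_reversible,
)
from .enzymes import CrowdingParams

#: LP feasibility tolerance passed to the backend.
FEAS_TOL = 1e-9
#: Tolerance used when reporting constraint activity / comparing optima.
REPORT_TOL = 1e-6

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


@dataclass
class FluxSolution:
    """A flux vector with its objective value and constraint-activity report.

    ``fluxes`` is keyed by the ids of the model actually solved (split ids
    when crowding was active); :meth:`net` collapses back to the original
    reaction ids.  ``binding_report`` maps constraint names (``cap:<group>``,
    ``uptake:<exchange>``) to their slack; a slack below ``REPORT_TOL``
    means the constraint is binding at the optimum.
    """

    fluxes: dict[str, float]
    objective_value: float
    status: str
    binding_report: dict[str, float] = field(default_factory=dict)
    split_map: dict | None = None

    def net(self) -> dict[str, float]:
        return net_fluxes(self.fluxes, self.split_map)

    def uptake(self, exchange_id: str) -> float:
        """Uptake through an exchange as a positive magnitude."""
        return max(0.0, -self.net().get(exchange_id, 0.0))

    def secretion(self, exchange_id: str) -> float:
        return max(0.0, self.net().get(exchange_id, 0.0))

    def is_binding(self, name: str, tol: float = REPORT_TOL) -> bool:
        return self.binding_report.get(name, np.inf) < tol

    @property
    def cap_binding(self) -> bool:
        return any(
            slack < REPORT_TOL for name, slack in self.binding_report.items() if name.startswith("cap:")
        )


@dataclass
class FluxRange:
    """FVA result for one reaction: attainable [min, max] net flux."""

    reaction_id: str
    min_flux: float
    max_flux: float

    def __post_init__(self):
        if self.min_flux > self.max_flux + REPORT_TOL:
            raise ModelValidationError(
                f"{self.reaction_id}: min_flux {self.min_flux} > max_flux {self.max_flux}"
            )


class _LP:
    """Assembled LP data for one (possibly split) model."""

    def __init__(self, model: MetabolicModel, crowding: CrowdingParams | None):
        self.model = model
        self.S = model.stoichiometric_matrix()
        self.lb = np.array([r.lower_bound for r in model.reactions])
        self.ub = np.array([r.upper_bound for r in model.reactions])
        self.cap_rows: list[tuple[str, np.ndarray, float]] = []
        if crowding is not None:
            for name, members, cap in crowding.cap_groups:
                row = np.zeros(model.n_reactions)
                for j, r in enumerate(model.reactions):
                    if crowding.is_member(r.id, members):
                        a = crowding.coefficient_for(r.id)
                        if a:
                            row[j] = a
                self.cap_rows.append((name, row, cap))

    def column_vector(self, targets: dict[str, float]) -> np.ndarray:
        """Objective/constraint vector over columns from original-id weights.

        A weight on an original reversible reaction is applied as +w on its
        forward and -w on its reverse column (net flux).
        """
        c = np.zeros(self.model.n_reactions)
        smap = self.model.split_map
        for rid, w in targets.items():
            if self.model.has_reaction(rid):
                c[self.model.reaction_index(rid)] += w
            elif smap is not None and rid in smap:
                fwd, rev = smap[rid]
                c[self.model.reaction_index(fwd)] += w
                if rev is not None:
                    c[self.model.reaction_index(rev)] -= w
            else:
                raise ModelValidationError(f"unknown reaction id {rid!r}")
        return c

    def solve(
        self,
        objective: np.ndarray,
        maximize: bool = True,
        extra_ub: list[tuple[np.ndarray, float]] | None = None,
    ) -> tuple[str, float, np.ndarray | None]:
        A_ub_rows = [row for _, row, _ in self.cap_rows]
        b_ub = [cap for _, _, cap in self.cap_rows]
        if extra_ub:
            A_ub_rows += [row for row, _ in extra_ub]
            b_ub += [rhs for _, rhs in extra_ub]
        A_ub = sparse.csr_matrix(np.vstack(A_ub_rows)) if A_ub_rows else None
        res = linprog(
            -objective if maximize else objective,
            A_ub=A_ub,
            b_ub=np.array(b_ub) if A_ub_rows else None,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([self.lb, self.ub]),
            method="highs",
            options={"primal_feasibility_tolerance": FEAS_TOL, "dual_feasibility_tolerance": FEAS_TOL},
        )
        if res.status == 2:
            return INFEASIBLE, np.nan, None
        if res.status == 3:
            return UNBOUNDED, np.inf if maximize else -np.inf, None
        if res.status != 0:
            raise RuntimeError(f"LP backend failure: {res.message}")
        value = float(objective @ res.x)
        return OPTIMAL, value, res.x


def _prepare(
    model: MetabolicModel, medium: Medium | None, crowding: CrowdingParams | None
) -> MetabolicModel:
    work = apply_medium(model, medium) if medium is not None else model
    if crowding is not None and not work.is_split:
        work = split_reversible(work)
    return work


def _solution(lp: _LP, status, value, x, medium: Medium | None) -> FluxSolution:
    if x is None:
        return FluxSolution({}, value, status, {}, lp.model.split_map)
    fluxes = {r.id: float(v) for r, v in zip(lp.model.reactions, x)}
    report = {}
    for name, row, cap in lp.cap_rows:
        report[f"cap:{name}"] = float(cap - row @ x)
    if medium is not None:
        nets = net_fluxes(fluxes, lp.model.split_map)
        for ex, bound in medium.uptake_bounds.items():
            report[f"uptake:{ex}"] = float(bound - max(0.0, -nets.get(ex, 0.0)))
    return FluxSolution(fluxes, value, status, report, lp.model.split_map)


def fba(
    model: MetabolicModel,
    medium: Medium | None = None,
    objective_id: str | None = None,
    crowding: CrowdingParams | None = None,
    maximize: bool = True,
) -> FluxSolution:
    """Flux balance analysis, optionally under the solvent-capacity cap.

    Maximises *objective_id* (default: the model's biomass reaction) subject
    to S·v = 0, the bounds (with the medium applied), and — when *crowding*
    is given — the per-group enzyme-capacity inequalities on the split
    model.  Infeasibility/unboundedness are reported in ``status``, not
    raised.
    """
    objective_id = objective_id or model.biomass_reaction_id
    if objective_id is None:
        raise ModelValidationError("no objective: model has no biomass reaction id")
    work = _prepare(model, medium, crowding)
    lp = _LP(work, crowding)
    c = lp.column_vector({objective_id: 1.0})
    status, value, x = lp.solve(c, maximize=maximize)
    return _solution(lp, status, value, x, medium)


def fva(
    model: MetabolicModel,
    medium: Medium | None = None,
    crowding: CrowdingParams | None = None,
    reaction_ids: list[str] | None = None,
    growth_fraction: float = 1.0,
    objective_id: str | None = None,
) -> list[FluxRange]:
    """Flux variability analysis at a fixed fraction of the optimal objective.

    For each target reaction the minimal and maximal *net* flux is computed
    subject to all model constraints plus
    ``objective >= growth_fraction * optimum - 1e-9`` (the absolute slack
    guards against empty feasible sets from round-off).
    """
    if not 0 <= growth_fraction <= 1:
        raise ModelValidationError(f"growth_fraction must be in [0, 1], got {growth_fraction}")
    objective_id = objective_id or model.biomass_reaction_id
    work = _prepare(model, medium, crowding)
    lp = _LP(work, crowding)
    obj = lp.column_vector({objective_id: 1.0})
    status, optimum, _ = lp.solve(obj, maximize=True)
    if status != OPTIMAL:
        raise ModelValidationError(f"FVA reference optimum not available: status {status}")
    extra = []
    if growth_fraction > 0:
        extra.append((-obj, -(growth_fraction * optimum - FEAS_TOL)))
    targets = reaction_ids if reaction_ids is not None else _original_ids(work)
    out = []
    for rid in targets:
        c = lp.column_vector({rid: 1.0})
        st_min, vmin, _ = lp.solve(c, maximize=False, extra_ub=extra)
        st_max, vmax, _ = lp.solve(c, maximize=True, extra_ub=extra)
        if st_min != OPTIMAL or st_max != OPTIMAL:
            raise ModelValidationError(f"FVA subproblem for {rid!r}: {st_min}/{st_max}")
        if vmin > vmax:  # round-off on a fully determined flux
            vmin = vmax = 0.5 * (vmin + vmax)
        out.append(FluxRange(rid, vmin, vmax))
    return out


def _original_ids(model: MetabolicModel) -> list[str]:
    if model.split_map is None:
        return model.reaction_ids
    return list(model.split_map)


def max_atp_yield(
    model: MetabolicModel,
    aerobic: bool = True,
    glucose_exchange: str = "EX_glc",
    oxygen_exchange: str = "EX_o2",
    atp_demand: str = "ATPM",
    glucose_uptake: float = 1.0,
) -> float:
    """Maximal ATP-hydrolysis flux per unit glucose taken up.

    Fixes glucose uptake to *glucose_uptake* (default 1 mmol/(gDW·h)),
    forbids oxygen uptake when ``aerobic=False``, and maximises the ATP
    demand reaction — the classical 2 (fermentation) vs 32 (respiration)
    mol ATP / mol glucose question, answered on the network's actual
    stoichiometry.
    """
    for rid in (glucose_exchange, oxygen_exchange, atp_demand):
        if not model.has_reaction(rid):
            raise ModelValidationError(f"model lacks required reaction {rid!r}")
    if glucose_uptake <= 0:
        return 0.0
    work = model.copy()
    glc = work.reaction(glucose_exchange)
    glc.lower_bound = -glucose_uptake
    glc.upper_bound = -glucose_uptake
    if not aerobic:
        o2 = work.reaction(oxygen_exchange)
        o2.lower_bound = max(o2.lower_bound, 0.0)
        if o2.lower_bound > o2.upper_bound:
            o2.upper_bound = o2.lower_bound
    sol = fba(work, objective_id=atp_demand)
    if sol.status != OPTIMAL:
        raise ModelValidationError(f"ATP-yield LP not optimal: {sol.status}")
    return sol.objective_value / glucose_uptake
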