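"""Stoichiometric model representation.

A metabolic network is a set of metabolites and reactions; the reactions'
signed stoichiometric coefficients assemble into the m x n matrix S whose
null space (intersected with flux bounds) is the steady-state flux cone.
Exchange reactions are boundary pseudo-reactions written in the direction
``metabolite_external ->``, so uptake is a *negative* flux internally;
every user-facing API reports uptake as a positive magnitude.

Fluxes are in mmol/(gDW·h) throughout the package.
"""

from __future__ import annotations

import copy as _copy
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

logger = logging.getLogger("crowdfba")

#: Conventional finite "unbounded" flux sentinel, mmol/(gDW·h).  Finite LP
#: bounds keep simplex/interior-point backends numerically stable.
INF_FLUX = 1000.0

FWD_SUFFIX = "__fwd"
REV_SUFFIX = "__rev"


class ModelValidationError(ValueError):
    """The model (or an input referencing it) violates a structural invariant."""


class FormatError(ValueError):
    """An input file could not be parsed into a valid model."""


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``molecular_weight`` is in mg/mmol (numerically equal to g/mol) and is
    optional; it is only needed for mass-fraction biomass components.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    molecular_weight: float | None = None

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelValidationError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass
class Reaction:
    """A (possibly reversible) reaction with flux bounds in mmol/(gDW·h).

    ``stoichiometry`` maps metabolite id -> signed coefficient (negative =
    consumed).  Reversibility is a *derived* property of the bounds: a
    reaction is reversible iff ``lower_bound < 0``.  ``parent_id`` is set on
    the two unidirectional halves produced by :func:`split_reversible` and
    points back at the original reaction, so that enzyme parameters keyed by
    original id apply to both directions.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -INF_FLUX
    upper_bound: float = INF_FLUX
    ec_number: str | None = None
    genes: list[str] = field(default_factory=list)
    is_exchange: bool = False
    is_biomass: bool = False
    compartment_tag: str = ""
    parent_id: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: stoichiometry must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def source_id(self) -> str:
        """Id of the original (pre-split) reaction this one derives from."""
        return self.parent_id if self.parent_id is not None else self.id


class MetabolicModel:
    """Container for metabolites + reactions with an optional biomass objective.

    The model validates on construction: every stoichiometry key must resolve
    to a declared metabolite, ids must be unique, exchange reactions must
    touch exactly one metabolite, and ``biomass_reaction_id`` (if given) must
    exist.
    """

    def __init__(
        self,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        biomass_reaction_id: str | None = None,
        split_map: dict[str, tuple[str, str | None]] | None = None,
    ):
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.biomass_reaction_id = biomass_reaction_id
        #: original-id -> (fwd-id, rev-id or None); populated by split_reversible.
        self.split_map = split_map
        self._validate()
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dups = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dups}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dups = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dups}")
        met_set = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - met_set
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references undeclared metabolites: {sorted(missing)}"
                )
            if r.is_exchange and len(r.stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange reaction {r.id!r} must touch exactly one metabolite, "
                    f"got {len(r.stoichiometry)}"
                )
        if self.biomass_reaction_id is not None and self.biomass_reaction_id not in set(rxn_ids):
            raise ModelValidationError(
                f"biomass_reaction_id {self.biomass_reaction_id!r} not among reactions"
            )

    # -- lookup -------------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def is_split(self) -> bool:
        """True once every reaction is unidirectional (lower bounds >= 0)."""
        return all(r.lower_bound >= 0 for r in self.reactions)

    @property
    def gene_to_reactions(self) -> dict[str, list[str]]:
        """Flat gene -> reaction-id map (no isozyme/complex boolean logic)."""
        out: dict[str, list[str]] = {}
        for r in self.reactions:
            for g in r.genes:
                out.setdefault(g, []).append(r.id)
        return out

    # -- matrix -------------------------------------------------------------

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """Assemble S (m x n), rows = metabolites, columns = reactions."""
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for met_id, coef in r.stoichiometry.items():
                rows.append(self._met_index[met_id])
                cols.append(j)
                vals.append(float(coef))
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n_metabolites, self.n_reactions)
        )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            [_copy.deepcopy(m) for m in self.metabolites],
            [_copy.deepcopy(r) for r in self.reactions],
            self.biomass_reaction_id,
            dict(self.split_map) if self.split_map is not None else None,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicModel {self.n_metabolites} metabolites, "
            f"{self.n_reactions} reactions, biomass={self.biomass_reaction_id!r}>"
        )


@dataclass
class Medium:
    """Growth-medium definition over exchange reactions.

    ``uptake_bounds`` maps exchange id -> maximal uptake flux (positive
    magnitude, mmol/(gDW·h)); members of ``unlimited_set`` (oxygen, water,
    inorganic ions, ammonia ...) may be taken up at the infinity sentinel.
    Exchanges listed in neither get uptake 0; secretion is always allowed.
    """

    uptake_bounds: dict[str, float] = field(default_factory=dict)
    unlimited_set: set[str] = field(default_factory=set)

    def __post_init__(self):
        for ex, b in self.uptake_bounds.items():
            if b < 0:
                raise ModelValidationError(f"medium bound for {ex!r} must be >= 0, got {b}")

    def with_uptake(self, exchange_id: str, bound: float) -> "Medium":
        new = dict(self.uptake_bounds)
        new[exchange_id] = bound
        return Medium(new, set(self.unlimited_set))


def split_reversible(model: MetabolicModel) -> MetabolicModel:
    """Split every reversible reaction into two unidirectional halves.

    A reaction R with bounds [lb, ub], lb < 0, becomes ``R__fwd`` (original
    stoichiometry, bounds [0, ub]) and ``R__rev`` (negated stoichiometry,
    bounds [0, -lb]); both carry R's enzyme metadata (EC number, genes) and
    ``parent_id = R``.  Irreversible reactions are kept as-is and map to
    ``(id, None)``.  The mapping original-id -> (fwd-id, rev-id) is stored on
    the returned model as ``split_map``.  Idempotent on already-split models.
    """
    new_reactions: list[Reaction] = []
    split_map: dict[str, tuple[str, str | None]] = {}
    for r in model.reactions:
        if not r.reversible:
            new_reactions.append(_copy.deepcopy(r))
            split_map[r.id] = (r.id, None)
            continue
        fwd = _copy.deepcopy(r)
        fwd.id = r.id + FWD_SUFFIX
        fwd.lower_bound = 0.0
        fwd.upper_bound = max(r.upper_bound, 0.0)
        fwd.parent_id = r.source_id
        rev = _copy.deepcopy(r)
        rev.id = r.id + REV_SUFFIX
        rev.stoichiometry = {m: -c for m, c in r.stoichiometry.items()}
        rev.lower_bound = 0.0
        rev.upper_bound = -r.lower_bound
        rev.parent_id = r.source_id
        new_reactions.extend([fwd, rev])
        split_map[r.id] = (fwd.id, rev.id)
    biomass = model.biomass_reaction_id
    if biomass is not None and biomass in split_map and split_map[biomass][1] is not None:
        biomass = split_map[biomass][0]
    return MetabolicModel(
        [_copy.deepcopy(m) for m in model.metabolites], new_reactions, biomass, split_map
    )


def net_fluxes(fluxes: dict[str, float], split_map: dict[str, tuple[str, str | None]] | None) -> dict[str, float]:
    """Collapse split-model fluxes back to net fluxes on the original ids."""
    if split_map is None:
        return dict(fluxes)
    out = {}
    for orig, (fwd, rev) in split_map.items():
        v = fluxes.get(fwd, 0.0)
        if rev is not None:
            v -= fluxes.get(rev, 0.0)
        out[orig] = v
    return out


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Return a copy of *model* with exchange bounds set from *medium*.

    Uptake of each listed exchange is bounded by the medium value, members of
    the unlimited set by the infinity sentinel, and all other exchanges are
    closed for uptake (secretion stays allowed).  A bound the model already
    set tighter is never relaxed.
    """
    exchange_ids = {r.id for r in model.reactions if r.is_exchange}
    unknown = (set(medium.uptake_bounds) | medium.unlimited_set) - exchange_ids
    if unknown:
        raise ModelValidationError(f"medium references unknown exchange ids: {sorted(unknown)}")
    out = model.copy()
    for r in out.reactions:
        if not r.is_exchange:
            continue
        if r.id in medium.uptake_bounds:
            uptake = medium.uptake_bounds[r.id]
        elif r.id in medium.unlimited_set:
            uptake = INF_FLUX
        else:
            uptake = 0.0
        # uptake is negative flux; never relax a bound the model set tighter
        new_lb = max(r.lower_bound, -uptake)
        if new_lb > r.upper_bound:
            raise ModelValidationError(
                f"exchange {r.id!r}: medium closes uptake but the model forces flux "
                f"<= {r.upper_bound} (forced uptake conflicts with the medium)"
            )
        r.lower_bound = new_lb
    return out
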