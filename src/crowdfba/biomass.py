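"""Biomass objective construction.

Proliferation is modelled as a pseudo-reaction draining precursor
metabolites in experimentally measured proportions (amino acids,
nucleotides, lipids, ...) plus a growth-associated ATP hydrolysis (GAM).
Mass-type components are given as g per g dry weight and converted to
mmol/gDW with the component's molecular weight; molar components are used
as-is.  Flux through the biomass reaction is the growth rate in 1/h.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass

import pandas as pd

from .core import (
    INF_FLUX,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    logger,
)

CLASS_TAGS = ("amino_acid", "nucleotide", "deoxynucleotide", "lipid", "energy", "other")

#: Reference whole-cell composition: mass budget 0.78 g/gDW amino acids +
#: 0.06 g/gDW nucleotides + 0.16 g/gDW lipids (closing to 1.00 g/gDW), plus
#: a growth-associated requirement of 24 mmol ATP per gDW produced.
REFERENCE_MASS_FRACTIONS = {"amino_acid": 0.78, "nucleotide": 0.06, "lipid": 0.16}
REFERENCE_GAM_ATP = 24.0


@dataclass
class BiomassComponent:
    """One biomass precursor.

    ``amount`` is a mass fraction in g/gDW when ``amount_kind == "mass"``
    (requiring ``molecular_weight`` in g/mol = mg/mmol) or directly a molar
    amount in mmol/gDW when ``amount_kind == "molar"``.  ``essential`` marks
    precursors the cell cannot synthesise (essential amino acids): they are
    assumed to flow straight from the medium into biomass, so a supply route
    is auto-created if the model lacks one.
    """

    metabolite_id: str
    amount: float
    amount_kind: str = "molar"
    molecular_weight: float | None = None
    class_tag: str = "other"
    essential: bool = False

    def __post_init__(self):
        if self.amount <= 0:
            raise ModelValidationError(f"{self.metabolite_id}: amount must be > 0")
        if self.amount_kind not in ("mass", "molar"):
            raise ModelValidationError(f"{self.metabolite_id}: amount_kind must be mass|molar")
        if self.amount_kind == "mass" and (
            self.molecular_weight is None or self.molecular_weight <= 0
        ):
            raise ModelValidationError(
                f"{self.metabolite_id}: mass components need molecular_weight > 0"
            )
        if self.class_tag not in CLASS_TAGS:
            raise ModelValidationError(f"{self.metabolite_id}: unknown class_tag {self.class_tag!r}")

    @property
    def molar_coefficient(self) -> float:
        """Precursor demand in mmol per gDW of biomass."""
        if self.amount_kind == "molar":
            return self.amount
        return self.amount / self.molecular_weight * 1000.0


#: default species ids for the GAM hydrolysis ATP + H2O -> ADP + Pi + H+
GAM_SPECIES = {"atp": "atp", "h2o": "h2o", "adp": "adp", "pi": "pi", "h": "h"}


def build_biomass_reaction(
    components: list[BiomassComponent],
    gam_atp: float = REFERENCE_GAM_ATP,
    reaction_id: str = "BIOMASS",
    biomass_metabolite: str = "biomass",
    gam_species: dict | None = None,
    mass_closure_tol: float = 0.05,
) -> Reaction:
    """Assemble the growth pseudo-reaction from a composition table.

    Reactants are the precursors at their molar coefficients plus
    ``gam_atp`` units of ATP hydrolysis (ATP + H2O -> ADP + Pi + H+; set a
    species id to None in *gam_species* to omit it, e.g. protons in a
    pseudo-balanced toy network); the single product is one unit of the
    biomass pseudo-metabolite.  Warns if mass-type fractions do not close to
    1 g/gDW within *mass_closure_tol*.
    """
    if not components:
        raise ModelValidationError("biomass component list is empty")
    seen = set()
    for c in components:
        if c.metabolite_id in seen:
            raise ModelValidationError(f"duplicate biomass component {c.metabolite_id!r}")
        seen.add(c.metabolite_id)

    mass_total = sum(c.amount for c in components if c.amount_kind == "mass")
    if mass_total and abs(mass_total - 1.0) > mass_closure_tol:
        logger.warning(
            "biomass mass fractions sum to %.3f g/gDW (expected ~1.0)", mass_total
        )

    stoich: dict[str, float] = {}
    for c in components:
        stoich[c.metabolite_id] = stoich.get(c.metabolite_id, 0.0) - c.molar_coefficient
    if gam_atp:
        if gam_atp < 0:
            raise ModelValidationError("gam_atp must be >= 0")
        sp = dict(GAM_SPECIES)
        if gam_species:
            sp.update(gam_species)
        for species, sign in (("atp", -1), ("h2o", -1), ("adp", +1), ("pi", +1), ("h", +1)):
            sid = sp.get(species)
            if sid is None:
                continue
            stoich[sid] = stoich.get(sid, 0.0) + sign * gam_atp
            if stoich[sid] == 0:
                del stoich[sid]
    stoich[biomass_metabolite] = stoich.get(biomass_metabolite, 0.0) + 1.0

    return Reaction(
        reaction_id, stoich, lower_bound=0.0, upper_bound=INF_FLUX, is_biomass=True
    )


def integrate_biomass(
    model: MetabolicModel,
    components: list[BiomassComponent],
    gam_atp: float = REFERENCE_GAM_ATP,
    reaction_id: str = "BIOMASS",
    biomass_metabolite: str = "biomass",
    gam_species: dict | None = None,
    external_compartment: str = "e",
) -> MetabolicModel:
    """Add the biomass reaction (plus sink) to a model.

    Every component metabolite must exist in the model, except *essential*
    components, for which an exchange + transport supply path
    (``met_e -> met``) is auto-created when absent.  The biomass
    pseudo-metabolite and its sink exchange are added, and the model's
    ``biomass_reaction_id`` is set.
    """
    mets = [_copy.deepcopy(m) for m in model.metabolites]
    rxns = [_copy.deepcopy(r) for r in model.reactions]
    met_ids = {m.id for m in mets}

    for c in components:
        if c.metabolite_id in met_ids:
            continue
        if not c.essential:
            raise ModelValidationError(
                f"biomass component {c.metabolite_id!r} not in model (and not essential)"
            )
        ext_id = f"{c.metabolite_id}_{external_compartment}"
        mets.append(Metabolite(c.metabolite_id, compartment="c"))
        mets.append(Metabolite(ext_id, compartment=external_compartment))
        met_ids.update({c.metabolite_id, ext_id})
        rxns.append(Reaction(f"EX_{c.metabolite_id}", {ext_id: -1.0}, -INF_FLUX, INF_FLUX, is_exchange=True))
        rxns.append(Reaction(f"{c.metabolite_id}_t", {ext_id: -1.0, c.metabolite_id: 1.0}, 0.0, INF_FLUX))
        logger.info("auto-created supply path for essential component %s", c.metabolite_id)

    biomass_rxn = build_biomass_reaction(
        components, gam_atp, reaction_id, biomass_metabolite, gam_species
    )
    if biomass_metabolite not in met_ids:
        mets.append(Metabolite(biomass_metabolite, name="biomass", compartment="c"))
    rxns.append(biomass_rxn)
    sink_id = f"EX_{biomass_metabolite}"
    rxns.append(Reaction(sink_id, {biomass_metabolite: -1.0}, 0.0, INF_FLUX, is_exchange=True))
    return MetabolicModel(mets, rxns, biomass_reaction_id=reaction_id)


# -- tabular I/O (biomass.tsv) ----------------------------------------------

BIOMASS_COLUMNS = ["metabolite_id", "amount", "amount_kind", "mw_g_per_mmol", "class_tag", "essential"]


def read_biomass_table(path) -> list[BiomassComponent]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        mw = row.get("mw_g_per_mmol")
        out.append(
            BiomassComponent(
                str(row["metabolite_id"]),
                float(row["amount"]),
                str(row["amount_kind"]),
                None if pd.isna(mw) else float(mw),
                str(row.get("class_tag", "other")),
                bool(int(row["essential"])) if "essential" in row and not pd.isna(row["essential"]) else False,
            )
        )
    return out


def write_biomass_table(components: list[BiomassComponent], path) -> None:
    rows = [
        {
            "metabolite_id": c.metabolite_id,
            "amount": c.amount,
            "amount_kind": c.amount_kind,
            "mw_g_per_mmol": c.molecular_weight if c.molecular_weight is not None else "",
            "class_tag": c.class_tag,
            "essential": int(c.essential),
        }
        for c in components
    ]
    pd.DataFrame(rows, columns=BIOMASS_COLUMNS).to_csv(path, sep="\t", index=False)
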