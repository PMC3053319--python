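"""Model readers and writers: a simple tabular dialect and SBML (+fbc).

Tabular dialect
---------------
``reactions.tsv`` columns: id, stoichiometry (``"metId:coeff; metId:coeff"``),
lb, ub, ec, genes (``"g1|g2"``), is_exchange, is_biomass, compartment_tag.
``metabolites.tsv`` columns: id, name, compartment, mw_mg_per_mmol.

Units: fluxes are mmol/(gDW·h).  Note 1 umol/(mgDW·h) == 1 mmol/(gDW·h), so
uptake rates quoted on either scale carry the same number.

SBML
----
Written as Level 3 Version 1 with the fbc-v2 package (flux bounds as global
parameters, flat gene products, the biomass reaction as the fbc objective).
On read, bounds are taken from fbc when present, else from COBRA-style
kinetic-law parameters (LOWER_BOUND/UPPER_BOUND), else defaulted to
[-1000, 1000] (reversible) with a warning.  Reversibility is inferred from
the bounds, not the SBML ``reversible`` flag, when the two disagree.
"""

from __future__ import annotations

import math

import libsbml
import pandas as pd

from .core import (
    INF_FLUX,
    FormatError,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    logger,
)

# --------------------------------------------------------------------------
# tabular dialect
# --------------------------------------------------------------------------

REACTION_COLUMNS = [
    "id", "stoichiometry", "lb", "ub", "ec", "genes", "is_exchange", "is_biomass", "compartment_tag",
]
METABOLITE_COLUMNS = ["id", "name", "compartment", "mw_mg_per_mmol"]


def parse_stoichiometry(cell: str) -> dict[str, float]:
    """Parse ``"glc_c:-1; pyr_c:2"`` into {"glc_c": -1.0, "pyr_c": 2.0}."""
    out: dict[str, float] = {}
    for term in str(cell).split(";"):
        term = term.strip()
        if not term:
            continue
        if ":" not in term:
            raise FormatError(f"malformed stoichiometry term {term!r} (expected 'metId:coeff')")
        met, coeff = term.rsplit(":", 1)
        met = met.strip()
        try:
            val = float(coeff)
        except ValueError as exc:
            raise FormatError(f"non-numeric coefficient in term {term!r}") from exc
        if met in out:
            raise FormatError(f"duplicate metabolite {met!r} in stoichiometry cell")
        out[met] = val
    if not out:
        raise FormatError(f"empty stoichiometry cell {cell!r}")
    return out


def format_stoichiometry(stoich: dict[str, float]) -> str:
    return "; ".join(f"{m}:{c:g}" for m, c in stoich.items())


def _split_genes(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
        return []
    return [g.strip() for g in str(cell).split("|") if g.strip()]


def read_tabular_model(reactions_path, metabolites_path) -> MetabolicModel:
    """Read the tabular dialect; semantics identical to the SBML reader."""
    mdf = pd.read_csv(metabolites_path, sep="\t", dtype=str)
    rdf = pd.read_csv(reactions_path, sep="\t", dtype=str)
    if len(rdf) == 0:
        raise ModelValidationError(f"{reactions_path}: no reactions")
    for frame, name in ((mdf, "metabolites"), (rdf, "reactions")):
        dups = frame["id"][frame["id"].duplicated()].tolist()
        if dups:
            raise ModelValidationError(f"duplicate {name} ids: {sorted(set(dups))}")

    mets = []
    for _, row in mdf.iterrows():
        mw = row.get("mw_mg_per_mmol")
        mets.append(
            Metabolite(
                row["id"],
                row.get("name") or "",
                row.get("compartment") or "c",
                None if mw in (None, "") or pd.isna(mw) else float(mw),
            )
        )
    rxns = []
    biomass_id = None
    for _, row in rdf.iterrows():
        is_biomass = str(row.get("is_biomass", "0")).strip() in ("1", "True", "true")
        r = Reaction(
            row["id"],
            parse_stoichiometry(row["stoichiometry"]),
            float(row["lb"]) if not pd.isna(row.get("lb")) else -INF_FLUX,
            float(row["ub"]) if not pd.isna(row.get("ub")) else INF_FLUX,
            ec_number=None if pd.isna(row.get("ec")) or row.get("ec") in (None, "") else str(row["ec"]),
            genes=_split_genes(row.get("genes")),
            is_exchange=str(row.get("is_exchange", "0")).strip() in ("1", "True", "true"),
            is_biomass=is_biomass,
            compartment_tag=("" if pd.isna(row.get("compartment_tag")) else str(row.get("compartment_tag") or "")),
        )
        rxns.append(r)
        if is_biomass and biomass_id is None:
            biomass_id = r.id
    return MetabolicModel(mets, rxns, biomass_reaction_id=biomass_id)


def write_tabular_model(model: MetabolicModel, reactions_path, metabolites_path) -> None:
    mrows = [
        {
            "id": m.id,
            "name": m.name,
            "compartment": m.compartment,
            "mw_mg_per_mmol": "" if m.molecular_weight is None else m.molecular_weight,
        }
        for m in model.metabolites
    ]
    rrows = [
        {
            "id": r.id,
            "stoichiometry": format_stoichiometry(r.stoichiometry),
            "lb": r.lower_bound,
            "ub": r.upper_bound,
            "ec": r.ec_number or "",
            "genes": "|".join(r.genes),
            "is_exchange": int(r.is_exchange),
            "is_biomass": int(r.is_biomass),
            "compartment_tag": r.compartment_tag,
        }
        for r in model.reactions
    ]
    pd.DataFrame(mrows, columns=METABOLITE_COLUMNS).to_csv(metabolites_path, sep="\t", index=False)
    pd.DataFrame(rrows, columns=REACTION_COLUMNS).to_csv(reactions_path, sep="\t", index=False)


# --------------------------------------------------------------------------
# SBML
# --------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version1/fbc/version2"


def _check(obj, what: str):
    if obj is None or (isinstance(obj, int) and obj != libsbml.LIBSBML_OPERATION_SUCCESS):
        raise FormatError(f"libsbml failure while building {what}")
    return obj


def write_sbml(model: MetabolicModel, path) -> None:
    """Write SBML L3V1 + fbc-v2 (bounds as parameters, flat gene products)."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId("model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites})
    for c in compartments:
        comp = sm.createCompartment()
        comp.setId(c)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name or m.id)
        sp.setCompartment(m.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        if m.molecular_weight is not None:
            sp.appendNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml"><p>MW_MG_PER_MMOL: {m.molecular_weight}</p></body>'
            )

    genes = sorted({g for r in model.reactions for g in r.genes})
    for g in genes:
        gp = mplug.createGeneProduct()
        gp.setId(f"G_{g}")
        gp.setLabel(g)

    bound_params: dict[float, str] = {}

    def bound_id(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(r.id)
        rx.setReversible(r.reversible)
        rx.setFast(False)
        for met, coeff in r.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(met)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_id(r.lower_bound))
        rplug.setUpperFluxBound(bound_id(r.upper_bound))
        if r.genes:
            gpa = rplug.createGeneProductAssociation()
            if len(r.genes) == 1:
                ref = gpa.createGeneProductRef()
                ref.setGeneProduct(f"G_{r.genes[0]}")
            else:
                orx = gpa.createOr()
                for g in r.genes:
                    ref = orx.createGeneProductRef()
                    ref.setGeneProduct(f"G_{g}")
        notes = []
        if r.ec_number:
            notes.append(f"<p>EC Number: {r.ec_number}</p>")
        if r.is_exchange:
            notes.append("<p>EXCHANGE: 1</p>")
        if r.compartment_tag:
            notes.append(f"<p>COMPARTMENT_TAG: {r.compartment_tag}</p>")
        if notes:
            rx.appendNotes(
                '<body xmlns="http://www.w3.org/1999/xhtml">' + "".join(notes) + "</body>"
            )

    if model.biomass_reaction_id is not None:
        objective = mplug.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        fo = objective.createFluxObjective()
        fo.setReaction(model.biomass_reaction_id)
        fo.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise FormatError(f"could not write SBML to {path}")


def _notes_fields(sbase) -> dict[str, str]:
    out = {}
    if sbase.isSetNotes():
        text = sbase.getNotesString()
        for line in text.replace("</p>", "\n").split("\n"):
            if "<p>" in line and ":" in line:
                body = line.split("<p>", 1)[1]
                key, _, val = body.partition(":")
                out[key.strip().upper()] = val.strip()
    return out


def read_sbml(path) -> MetabolicModel:
    """Read an SBML file (L2 or L3, with or without fbc) into a model."""
    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"unparsable SBML {path}: {err.getMessage().strip()}")
    sm = doc.getModel()
    if sm is None:
        raise FormatError(f"{path}: no <model> element")

    mets = []
    species_ids = set()
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        notes = _notes_fields(sp)
        mw = notes.get("MW_MG_PER_MMOL")
        mets.append(
            Metabolite(
                sp.getId(),
                sp.getName() or "",
                sp.getCompartment() or "c",
                float(mw) if mw else None,
            )
        )
        species_ids.add(sp.getId())

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }
    gene_labels = {}
    mplug = sm.getPlugin("fbc")
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    rxns = []
    for i in range(sm.getNumReactions()):
        rx = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            if ref.getSpecies() not in species_ids:
                raise FormatError(
                    f"reaction {rx.getId()!r} references undeclared species {ref.getSpecies()!r}"
                )
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            if ref.getSpecies() not in species_ids:
                raise FormatError(
                    f"reaction {rx.getId()!r} references undeclared species {ref.getSpecies()!r}"
                )
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}

        lb = ub = None
        rplug = rx.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            lb = params.get(rplug.getLowerFluxBound())
            ub = params.get(rplug.getUpperFluxBound())
        if lb is None and rx.isSetKineticLaw():
            kl = rx.getKineticLaw()
            for k in range(kl.getNumParameters()):
                p = kl.getParameter(k)
                if p.getId() == "LOWER_BOUND":
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND":
                    ub = p.getValue()
        if lb is None or ub is None:
            logger.warning(
                "reaction %s: no flux bounds in SBML; defaulting to [-%g, %g]",
                rx.getId(), INF_FLUX, INF_FLUX,
            )
            lb, ub = -INF_FLUX, INF_FLUX
        lb = max(lb, -INF_FLUX)
        ub = min(ub, INF_FLUX)

        genes = []
        if rplug is not None and rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()

            def collect(node):
                if node is None:
                    return
                if isinstance(node, libsbml.GeneProductRef):
                    genes.append(gene_labels.get(node.getGeneProduct(), node.getGeneProduct()))
                else:
                    for k in range(node.getNumAssociations()):
                        collect(node.getAssociation(k))

            collect(assoc)

        notes = _notes_fields(rx)
        is_exchange = notes.get("EXCHANGE") == "1" or (
            len(stoich) == 1 and "EXCHANGE" not in notes
        )
        rxns.append(
            Reaction(
                rx.getId(),
                stoich,
                lb,
                ub,
                ec_number=notes.get("EC NUMBER"),
                genes=genes,
                is_exchange=is_exchange,
                compartment_tag=notes.get("COMPARTMENT_TAG", ""),
            )
        )

    biomass_id = None
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            biomass_id = obj.getFluxObjective(0).getReaction()
    if biomass_id is not None:
        for r in rxns:
            if r.id == biomass_id:
                r.is_biomass = True
                r.is_exchange = False

    try:
        return MetabolicModel(mets, rxns, biomass_reaction_id=biomass_id)
    except ModelValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc
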