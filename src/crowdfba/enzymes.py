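"""Enzyme kinetic parameters and the solvent-capacity (crowding) constraint.

The enzyme mass needed to sustain flux v_i through reaction i is
``v_i * MW_i / kcat_i`` — molecular weight in mg/mmol, turnover number in
1/h.  Bounding the total over all enzyme-catalysed reactions by the cell's
metabolic protein budget C (mg enzyme per mg dry weight) yields one linear
inequality per cap group:

    sum_i  a_i * v_i  <=  C,      a_i = MW_i / kcat_i  (scaled)

Fluxes in this package are mmol/(gDW·h), so the raw mg/gDW enzyme mass is
scaled by 1e-3 to land on the mg/mgDW scale of C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FWD_SUFFIX, REV_SUFFIX, MetabolicModel, ModelValidationError

#: mg/gDW -> mg/mgDW conversion applied to the cost coefficients.
FLUX_SCALE = 1e-3

#: kcat source categories in decreasing precedence order.
KCAT_PRECEDENCE = ("human_wildtype", "nonhuman_wildtype", "sabio")
MEDIAN_FILL = "median_fill"


def strip_direction(rxn_id: str) -> str:
    """Map a split-reaction id (``X__fwd``/``X__rev``) to its original id."""
    for suffix in (FWD_SUFFIX, REV_SUFFIX):
        if rxn_id.endswith(suffix):
            return rxn_id[: -len(suffix)]
    return rxn_id


@dataclass
class EnzymeParams:
    """Kinetic parameters of the enzyme catalysing one reaction.

    ``kcat`` is stored in 1/h (inputs are 1/s and converted on ingestion);
    ``molecular_weight`` in mg/mmol.  ``exempt`` marks reactions that consume
    no enzyme budget (exchanges, the biomass pseudo-reaction, spontaneous or
    diffusion steps).
    """

    reaction_id: str
    kcat: float
    molecular_weight: float
    kcat_source: str = MEDIAN_FILL
    exempt: bool = False

    def __post_init__(self):
        if self.kcat <= 0:
            raise ModelValidationError(f"{self.reaction_id}: kcat must be > 0, got {self.kcat}")
        if not self.exempt and self.molecular_weight <= 0:
            raise ModelValidationError(
                f"{self.reaction_id}: molecular_weight must be > 0 for non-exempt reactions"
            )

    @property
    def cost_coefficient(self) -> float:
        """a_i = MW_i / kcat_i, scaled to (mg/mgDW) per unit mmol/(gDW·h)."""
        if self.exempt:
            return 0.0
        return self.molecular_weight / self.kcat * FLUX_SCALE


def compute_cap(total_protein_fraction: float, metabolic_fraction: float) -> float:
    """Metabolic-enzyme budget C = protein dry-mass fraction x metabolic share.

    Both inputs are dimensionless fractions in (0, 1]; the result is in
    mg/mgDW.  The unrounded product is returned; round to 3 decimals for
    reporting (0.779 x 0.1 -> 0.078).
    """
    for name, x in (
        ("total_protein_fraction", total_protein_fraction),
        ("metabolic_fraction", metabolic_fraction),
    ):
        if not 0 < x <= 1:
            raise ModelValidationError(f"{name} must be in (0, 1], got {x}")
    return total_protein_fraction * metabolic_fraction


@dataclass
class CrowdingParams:
    """Per-reaction cost coefficients plus one or more capacity caps.

    ``coefficients`` are keyed by *original* (pre-split) reaction id; both
    directions of a split reversible reaction share the coefficient.
    ``cap_groups`` is a list of (name, member-id set or None, cap); a member
    set of ``None`` means "every non-exempt reaction" (the default single
    global group).
    """

    coefficients: dict[str, float]
    cap_groups: list[tuple[str, frozenset | None, float]]
    exempt_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        for rid, a in self.coefficients.items():
            if a < 0:
                raise ModelValidationError(f"cost coefficient for {rid!r} must be >= 0")
        for _, _, cap in self.cap_groups:
            if cap <= 0:
                raise ModelValidationError("cap C must be > 0")

    @classmethod
    def from_enzyme_params(
        cls,
        params: list[EnzymeParams],
        cap: float,
        cap_groups: list[tuple[str, frozenset, float]] | None = None,
    ) -> "CrowdingParams":
        coeffs = {p.reaction_id: p.cost_coefficient for p in params if not p.exempt}
        exempt = frozenset(p.reaction_id for p in params if p.exempt)
        groups = cap_groups if cap_groups is not None else [("total", None, cap)]
        return cls(coeffs, list(groups), exempt)

    @property
    def cap(self) -> float:
        """Cap of the single global group (convenience for the common case)."""
        if len(self.cap_groups) != 1:
            raise ValueError("model has multiple cap groups; inspect cap_groups directly")
        return self.cap_groups[0][2]

    def with_cap(self, cap: float) -> "CrowdingParams":
        return CrowdingParams(
            dict(self.coefficients),
            [(name, members, cap) for name, members, _ in self.cap_groups],
            self.exempt_ids,
        )

    def scaled(self, factor: float) -> "CrowdingParams":
        """Multiply every cap by *factor* (coefficients unchanged)."""
        return CrowdingParams(
            dict(self.coefficients),
            [(name, members, cap * factor) for name, members, cap in self.cap_groups],
            self.exempt_ids,
        )

    def coefficient_for(self, rxn_id: str) -> float | None:
        """Cost coefficient for a (possibly split) reaction id; None if unknown."""
        base = strip_direction(rxn_id)
        if base in self.coefficients:
            return self.coefficients[base]
        if base in self.exempt_ids:
            return 0.0
        return None

    def is_member(self, rxn_id: str, members: frozenset | None) -> bool:
        base = strip_direction(rxn_id)
        if base in self.exempt_ids:
            return False
        if members is None:
            return base in self.coefficients
        return base in members


def assign_enzyme_params(
    model: MetabolicModel,
    kcat_table: pd.DataFrame,
    mw_table: pd.DataFrame,
    extra_exempt: set[str] | frozenset = frozenset(),
) -> list[EnzymeParams]:
    """Resolve a kcat and molecular weight for every reaction of *model*.

    ``kcat_table`` columns: ``reaction_id`` and/or ``ec``, ``kcat_per_s``,
    ``kcat_source`` (one of ``human_wildtype``/``nonhuman_wildtype``/``sabio``).
    ``mw_table`` columns: ``reaction_id`` and/or ``ec``, ``mw_mg_per_mmol``.

    Resolution per reaction: within the highest-precedence source category
    that has a matching row (by reaction id, else by EC number), take the
    *maximal* kcat.  Reactions with no match receive the median of the
    resolved known kcats (``median_fill``); the median is taken over one
    value per reaction, so duplicate table rows cannot shift it, and an even
    count averages the central pair.  Missing molecular weights are filled
    with the median known MW.  Exchange and biomass reactions (plus
    ``extra_exempt``) are marked exempt.  Both split directions of a
    reversible reaction receive identical parameters (output is keyed by
    original reaction id).
    """
    if kcat_table is None or len(kcat_table) == 0:
        raise ModelValidationError("kcat table is empty; the median fill is undefined")

    kt = kcat_table.copy()
    if "kcat_source" not in kt.columns:
        kt["kcat_source"] = "human_wildtype"

    def rows_for(df: pd.DataFrame, rid: str, ec: str | None) -> pd.DataFrame:
        masks = []
        if "reaction_id" in df.columns:
            masks.append(df["reaction_id"] == rid)
        if ec and "ec" in df.columns:
            masks.append(df["ec"] == ec)
        if not masks:
            return df.iloc[0:0]
        mask = masks[0]
        for m in masks[1:]:
            mask = mask | m
        return df[mask]

    # one entry per original reaction
    originals: dict[str, tuple[str | None, bool]] = {}
    for r in model.reactions:
        base = r.source_id
        exempt = r.is_exchange or r.is_biomass or base in extra_exempt or r.id in extra_exempt
        if base in originals:
            prev_ec, prev_ex = originals[base]
            originals[base] = (prev_ec or r.ec_number, prev_ex or exempt)
        else:
            originals[base] = (r.ec_number, exempt)

    resolved: dict[str, tuple[float, str] | None] = {}
    for base, (ec, _) in originals.items():
        cand = rows_for(kt, base, ec)
        hit = None
        for source in KCAT_PRECEDENCE:
            sub = cand[cand["kcat_source"] == source]
            if len(sub):
                hit = (float(sub["kcat_per_s"].max()) * 3600.0, source)
                break
        resolved[base] = hit

    known = sorted(v[0] for v in resolved.values() if v is not None)
    if not known:
        raise ModelValidationError("no reaction matched any kcat-table row")
    median_kcat = float(np.median(known))

    known_mw = (
        pd.to_numeric(mw_table["mw_mg_per_mmol"], errors="coerce").dropna()
        if mw_table is not None and len(mw_table)
        else pd.Series(dtype=float)
    )
    median_mw = float(known_mw.median()) if len(known_mw) else 1.0

    params: list[EnzymeParams] = []
    for base, (ec, exempt) in originals.items():
        hit = resolved[base]
        kcat, source = hit if hit is not None else (median_kcat, MEDIAN_FILL)
        mw_rows = rows_for(mw_table, base, ec) if mw_table is not None else None
        if mw_rows is not None and len(mw_rows):
            mw = float(pd.to_numeric(mw_rows["mw_mg_per_mmol"], errors="coerce").max())
        else:
            mw = median_mw
        if exempt:
            params.append(EnzymeParams(base, kcat, 0.0, source, exempt=True))
        else:
            params.append(EnzymeParams(base, kcat, mw, source))
    return params


def median_known_kcat(params: list[EnzymeParams]) -> float:
    """Median kcat (1/h) over non-median-filled, non-exempt parameters."""
    vals = [p.kcat for p in params if p.kcat_source != MEDIAN_FILL and not p.exempt]
    if not vals:
        raise ModelValidationError("no known kcat values")
    return float(np.median(vals))


def crowding_cost(
    fluxes: dict[str, float], params: CrowdingParams, tolerance: float = 1e-9
) -> dict[str, float]:
    """Enzyme mass (mg/mgDW) used by a flux distribution, per cap group.

    *fluxes* must be non-negative (a split-model solution); ids may carry
    ``__fwd``/``__rev`` suffixes.  A flux through a reaction that is neither
    parameterised nor exempt is an error.
    """
    for rid, v in fluxes.items():
        if v < -1e-6:
            raise ModelValidationError(f"negative flux {v} on {rid!r}; pass a split-model solution")
        if abs(v) > tolerance and params.coefficient_for(rid) is None:
            raise ModelValidationError(f"reaction {rid!r} has flux but no crowding parameters")
    out = {}
    for name, members, _cap in params.cap_groups:
        total = 0.0
        for rid, v in fluxes.items():
            if params.is_member(rid, members):
                total += params.coefficient_for(rid) * max(v, 0.0)
        out[name] = total
    return out


# -- tabular I/O (enzymes.tsv: one resolved row per reaction) ---------------

ENZYME_COLUMNS = ["reaction_id", "ec", "kcat_per_s", "kcat_source", "mw_mg_per_mmol", "exempt"]


def enzyme_params_to_frame(params: list[EnzymeParams], model: MetabolicModel | None = None) -> pd.DataFrame:
    ec_of = {}
    if model is not None:
        for r in model.reactions:
            ec_of.setdefault(r.source_id, r.ec_number)
    rows = [
        {
            "reaction_id": p.reaction_id,
            "ec": ec_of.get(p.reaction_id) or "",
            "kcat_per_s": p.kcat / 3600.0,
            "kcat_source": p.kcat_source,
            "mw_mg_per_mmol": p.molecular_weight,
            "exempt": int(p.exempt),
        }
        for p in params
    ]
    return pd.DataFrame(rows, columns=ENZYME_COLUMNS)


def enzyme_params_from_frame(df: pd.DataFrame) -> list[EnzymeParams]:
    params = []
    for _, row in df.iterrows():
        params.append(
            EnzymeParams(
                str(row["reaction_id"]),
                float(row["kcat_per_s"]) * 3600.0,
                float(row["mw_mg_per_mmol"]),
                str(row.get("kcat_source", MEDIAN_FILL)),
                exempt=bool(int(row["exempt"])) if "exempt" in row else False,
            )
        )
    return params


def read_enzyme_table(path) -> list[EnzymeParams]:
    return enzyme_params_from_frame(pd.read_csv(path, sep="\t"))


def write_enzyme_table(params: list[EnzymeParams], path, model: MetabolicModel | None = None) -> None:
    enzyme_params_to_frame(params, model).to_csv(path, sep="\t", index=False)
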