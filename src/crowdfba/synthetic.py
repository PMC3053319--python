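"""Synthetic fixtures: toy central-carbon network and data generators.

The toy network is a desk-scale stand-in for a genome-scale human model.
It keeps only the decisions that matter for overflow metabolism: glycolysis
(2 ATP per glucose), a lumped respiration reaction (pyruvate + NADH + 3 O2
-> 15 ATP, so full oxidation returns 2 + 2x15 = 32 ATP per glucose),
fermentation to lactate, and a biomass reaction demanding ATP, carbon
(pyruvate) and reducing power (NADH).  Costs: the respiratory machinery is
modelled as one lumped multi-MDa complex, so its enzyme mass per unit flux
dwarfs the glycolytic one — the configuration under which fermentation has
the higher growth yield per unit of enzyme cost and overflow metabolism
emerges once the capacity cap binds.

Everything here is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import SweepPoint, SweepResult
from .biomass import build_biomass_reaction, BiomassComponent
from .core import INF_FLUX, MetabolicModel, Medium, Metabolite, ModelValidationError, Reaction
from .enzymes import KCAT_PRECEDENCE, MEDIAN_FILL, CrowdingParams, EnzymeParams
from .solver import FluxRange

# --------------------------------------------------------------------------
# toy network
# --------------------------------------------------------------------------


@dataclass
class ToyNetworkSpec:
    """Parameters of the toy central-carbon fixture.

    ATP yields are per glucose; cost_* are enzyme-cost coefficients in
    (mg/mgDW) per unit flux (mmol/(gDW·h)); biomass demands are mmol per
    unit of biomass.  The default parameterization is Warburg-generating:
    fermentation's growth yield per unit cost exceeds respiration's.  With
    uniform costs (:meth:`uniform`) respiration dominates at every uptake
    and no lactate is ever secreted — the negative control.
    """

    atp_yield_fermentation: float = 2.0
    atp_yield_respiration: float = 32.0
    cost_glycolysis: float = 0.01
    cost_ldh: float = 0.01
    cost_resp: float = 2.0
    cost_transport: float = 0.01
    biomass_atp: float = 10.0
    biomass_carbon: float = 1.0
    cap: float = 0.078
    glucose_uptake: float = 1.0
    with_amino_acids: bool = False
    #: glutamine demand of biomass (mmol per unit) in the amino-acid variant;
    #: from glucose it must be synthesised via transamination + the
    #: ATP-consuming glutamine synthetase, so medium glutamine spares both
    #: ATP and enzyme capacity while glutamate spares only the first step
    biomass_gln: float = 0.5
    #: cost coefficient of the lumped amino-acid biosynthesis step (GDH);
    #: costlier than a transporter, so importing the amino acid pays off
    cost_biosynthesis: float = 0.05

    @classmethod
    def uniform(cls, cost: float = 0.01, **kw) -> "ToyNetworkSpec":
        """Uniform-cost negative control (every reaction the same coefficient)."""
        return cls(
            cost_glycolysis=cost, cost_ldh=cost, cost_resp=cost, cost_transport=cost, **kw
        )

    # -- closed-form two-strategy geometry (per unit glucose) --------------

    @property
    def resp_atp(self) -> float:
        """ATP per (pyruvate + NADH) pair through the lumped respiration."""
        return (self.atp_yield_respiration - self.atp_yield_fermentation) / 2.0

    def respiration_strategy(self) -> tuple[float, float]:
        """(growth yield, enzyme cost) per unit glucose, all pyruvate respired
        except the biomass carbon demand."""
        y = self.atp_yield_respiration / (self.biomass_atp + self.resp_atp * self.biomass_carbon)
        r = 2.0 - self.biomass_carbon * y  # respiration flux per glucose
        if r < 0:
            raise ModelValidationError("biomass carbon demand exceeds glycolytic pyruvate supply")
        cost = (
            self.cost_transport * (1.0 + 3.0 * r + 3.0 * r)  # GLC_t, O2_t, CO2_t
            + self.cost_glycolysis
            + self.cost_resp * r
        )
        return y, cost

    def fermentation_strategy(self) -> tuple[float, float]:
        """(growth yield, enzyme cost) per unit glucose, surplus pyruvate fermented."""
        y = self.atp_yield_fermentation / self.biomass_atp
        l = 2.0 - self.biomass_carbon * y  # lactate flux per glucose
        if l < 0:
            raise ModelValidationError("biomass carbon demand exceeds glycolytic pyruvate supply")
        cost = (
            self.cost_transport * (1.0 + l)  # GLC_t, LAC_t
            + self.cost_glycolysis
            + self.cost_ldh * l
        )
        return y, cost

    @property
    def warburg_generating(self) -> bool:
        ya, ca = self.respiration_strategy()
        yb, cb = self.fermentation_strategy()
        return yb / cb > ya / ca

    def validate(self, expect_warburg: bool = True) -> None:
        ya, ca = self.respiration_strategy()
        yb, cb = self.fermentation_strategy()
        if ya <= yb:
            raise ModelValidationError(
                f"respiration yield {ya:.4g} must exceed fermentation yield {yb:.4g}"
            )
        if expect_warburg and yb / cb <= ya / ca:
            raise ModelValidationError(
                f"Warburg-generating spec requires Y_B/C_B > Y_A/C_A, got {yb / cb:.4g} <= {ya / ca:.4g}"
            )


@dataclass
class ToyFixture:
    """Bundle returned by :func:`make_toy_network`."""

    model: MetabolicModel
    enzyme_params: list[EnzymeParams]
    medium: Medium
    spec: ToyNetworkSpec
    pathway_map: dict[str, list[str]] = field(default_factory=dict)

    @property
    def crowding(self) -> CrowdingParams:
        return CrowdingParams.from_enzyme_params(self.enzyme_params, self.spec.cap)


def _enzyme(rxn_id: str, cost: float, kcat_per_s: float, source: str) -> EnzymeParams:
    """EnzymeParams whose MW/kcat cost coefficient equals *cost* exactly."""
    kcat_h = kcat_per_s * 3600.0
    return EnzymeParams(rxn_id, kcat_h, cost * 1000.0 * kcat_h, source)


def make_toy_network(spec: ToyNetworkSpec | None = None) -> ToyFixture:
    """Build the toy central-carbon model, its enzyme table and medium.

    Metabolite/charge bookkeeping is pseudo-balanced (protons omitted); all
    listed routes are solvable under S·v = 0.  Anaerobic/aerobic maximal ATP
    yields are exactly ``atp_yield_fermentation`` / ``atp_yield_respiration``
    per glucose by construction.
    """
    spec = spec or ToyNetworkSpec()
    spec.validate(expect_warburg=False)
    a, b, k = spec.biomass_atp, spec.biomass_carbon, spec.resp_atp
    glyc_atp = spec.atp_yield_fermentation

    mets = [
        Metabolite("glc_e", "glucose (ext)", "e"),
        Metabolite("glc_c", "glucose", "c"),
        Metabolite("pyr", "pyruvate", "c"),
        Metabolite("lac_c", "lactate", "c"),
        Metabolite("lac_e", "lactate (ext)", "e"),
        Metabolite("o2_e", "oxygen (ext)", "e"),
        Metabolite("o2_c", "oxygen", "c"),
        Metabolite("co2_c", "CO2", "c"),
        Metabolite("co2_e", "CO2 (ext)", "e"),
        Metabolite("atp", "ATP", "c"),
        Metabolite("adp", "ADP", "c"),
        Metabolite("pi", "phosphate", "c"),
        Metabolite("nad", "NAD+", "c"),
        Metabolite("nadh", "NADH", "c"),
        Metabolite("h2o_e", "water (ext)", "e"),
        Metabolite("h2o", "water", "c"),
        Metabolite("biomass", "biomass", "c"),
    ]

    # the biomass reaction demands ATP (GAM-style hydrolysis), carbon
    # (pyruvate) and reducing power (NADH) in fixed proportions; the
    # amino-acid variant additionally drains glutamine
    components = [
        BiomassComponent("pyr", b, "molar", class_tag="other"),
        BiomassComponent("nadh", b, "molar", class_tag="other"),
    ]
    if spec.with_amino_acids and spec.biomass_gln > 0:
        components.append(
            BiomassComponent("gln_c", spec.biomass_gln, "molar", class_tag="amino_acid")
        )
    biomass_rxn = build_biomass_reaction(
        components,
        gam_atp=a,
        gam_species={"h": None},  # protons are omitted from the fixture
    )
    biomass_rxn.stoichiometry["nad"] = biomass_rxn.stoichiometry.get("nad", 0.0) + b

    rxns = [
        Reaction("EX_glc", {"glc_e": -1}, -INF_FLUX, INF_FLUX, is_exchange=True, compartment_tag="e"),
        Reaction("GLC_t", {"glc_e": -1, "glc_c": 1}, 0, INF_FLUX, genes=["gGLUT1"], compartment_tag="c"),
        Reaction(
            "GLYC",
            {
                "glc_c": -1, "adp": -glyc_atp, "pi": -glyc_atp, "nad": -2,
                "pyr": 2, "atp": glyc_atp, "nadh": 2,
            },
            0, INF_FLUX, ec_number="1.2.1.12", genes=["gGLYC1", "gGLYC2"], compartment_tag="c",
        ),
        # reversible on purpose: exercises reaction splitting on an enzymatic step
        Reaction(
            "LDH", {"pyr": -1, "nadh": -1, "lac_c": 1, "nad": 1},
            -INF_FLUX, INF_FLUX, ec_number="1.1.1.27", genes=["gLDHA"], compartment_tag="c",
        ),
        Reaction("LAC_t", {"lac_c": -1, "lac_e": 1}, 0, INF_FLUX, genes=["gMCT4"], compartment_tag="c"),
        Reaction("EX_lac", {"lac_e": -1}, 0, INF_FLUX, is_exchange=True, compartment_tag="e"),
        Reaction("EX_o2", {"o2_e": -1}, -INF_FLUX, INF_FLUX, is_exchange=True, compartment_tag="e"),
        Reaction("O2_t", {"o2_e": -1, "o2_c": 1}, 0, INF_FLUX, compartment_tag="m"),
        Reaction(
            "RESP",
            {
                "pyr": -1, "nadh": -1, "o2_c": -3, "adp": -k, "pi": -k,
                "co2_c": 3, "nad": 1, "atp": k,
            },
            0, INF_FLUX, ec_number="1.9.3.1", genes=["gRESP"], compartment_tag="m",
        ),
        Reaction("CO2_t", {"co2_c": -1, "co2_e": 1}, 0, INF_FLUX, compartment_tag="c"),
        Reaction("EX_co2", {"co2_e": -1}, 0, INF_FLUX, is_exchange=True, compartment_tag="e"),
        Reaction("EX_h2o", {"h2o_e": -1}, -INF_FLUX, INF_FLUX, is_exchange=True, compartment_tag="e"),
        Reaction("H2O_t", {"h2o_e": -1, "h2o": 1}, -INF_FLUX, INF_FLUX, compartment_tag="c"),
        Reaction("ATPM", {"atp": -1, "h2o": -1, "adp": 1, "pi": 1}, 0, INF_FLUX, compartment_tag="c"),
        biomass_rxn,
        Reaction("EX_biomass", {"biomass": -1}, 0, INF_FLUX, is_exchange=True, compartment_tag="e"),
    ]

    # enzyme parameters: lumped respiratory machinery is a multi-MDa complex
    # with a slow turnover; everything else is a ~36 kDa enzyme at 1/s
    params = [
        _enzyme("GLC_t", spec.cost_transport, 1.0, MEDIAN_FILL),
        _enzyme("GLYC", spec.cost_glycolysis, 1.0, "human_wildtype"),
        _enzyme("LDH", spec.cost_ldh, 1.0, "human_wildtype"),
        _enzyme("LAC_t", spec.cost_transport, 1.0, MEDIAN_FILL),
        _enzyme("O2_t", spec.cost_transport, 1.0, MEDIAN_FILL),
        _enzyme("RESP", spec.cost_resp, 0.5, "human_wildtype"),
        _enzyme("CO2_t", spec.cost_transport, 1.0, MEDIAN_FILL),
        EnzymeParams("H2O_t", 3600.0, 0.0, MEDIAN_FILL, exempt=True),  # diffusion
        EnzymeParams("ATPM", 3600.0, 0.0, MEDIAN_FILL, exempt=True),  # pseudo demand
        EnzymeParams("EX_glc", 3600.0, 0.0, MEDIAN_FILL, exempt=True),
        EnzymeParams("EX_lac", 3600.0, 0.0, MEDIAN_FILL, exempt=True),
        EnzymeParams("EX_o2", 3600.0, 0.0, MEDIAN_FILL, exempt=True),
        EnzymeParams("EX_co2", 3600.0, 0.0, MEDIAN_FILL, exempt=True),
        EnzymeParams("EX_h2o", 3600.0, 0.0, MEDIAN_FILL, exempt=True),
        EnzymeParams("BIOMASS", 3600.0, 0.0, MEDIAN_FILL, exempt=True),
        EnzymeParams("EX_biomass", 3600.0, 0.0, MEDIAN_FILL, exempt=True),
    ]

    unlimited = {"EX_o2", "EX_h2o"}

    if spec.with_amino_acids:
        mets += [
            Metabolite("gln_e", "glutamine (ext)", "e"),
            Metabolite("gln_c", "glutamine", "c"),
            Metabolite("glu_e", "glutamate (ext)", "e"),
            Metabolite("glu_c", "glutamate", "c"),
            Metabolite("ala_e", "alanine (ext)", "e"),  # no consuming reaction
        ]
        rxns += [
            Reaction("EX_gln", {"gln_e": -1}, -INF_FLUX, INF_FLUX, is_exchange=True, compartment_tag="e"),
            Reaction("GLN_t", {"gln_e": -1, "gln_c": 1}, 0, INF_FLUX, genes=["gASCT2"], compartment_tag="c"),
            Reaction("EX_glu", {"glu_e": -1}, -INF_FLUX, INF_FLUX, is_exchange=True, compartment_tag="e"),
            Reaction("GLU_t", {"glu_e": -1, "glu_c": 1}, 0, INF_FLUX, genes=["gEAAT"], compartment_tag="c"),
            Reaction("EX_ala", {"ala_e": -1}, -INF_FLUX, INF_FLUX, is_exchange=True, compartment_tag="e"),
            # lumped transamination: glutamate from pyruvate + reducing power
            Reaction(
                "GDH", {"pyr": -1, "nadh": -1, "glu_c": 1, "nad": 1},
                0, INF_FLUX, ec_number="1.4.1.3", genes=["gGDH"], compartment_tag="c",
            ),
            # glutamine synthetase: the ATP-consuming glutamate -> glutamine step
            Reaction(
                "GS", {"glu_c": -1, "atp": -1, "gln_c": 1, "adp": 1, "pi": 1},
                0, INF_FLUX, ec_number="6.3.1.2", genes=["gGS"], compartment_tag="c",
            ),
            # lumped glutaminolysis to pyruvate + reducing power
            Reaction(
                "GLNLYSIS", {"gln_c": -1, "nad": -1, "pyr": 1, "nadh": 1, "co2_c": 1},
                0, INF_FLUX, ec_number="3.5.1.2", genes=["gGLS"], compartment_tag="c",
            ),
        ]
        params += [
            _enzyme("GLN_t", spec.cost_transport, 1.0, MEDIAN_FILL),
            _enzyme("GLU_t", spec.cost_transport, 1.0, MEDIAN_FILL),
            _enzyme("GDH", spec.cost_biosynthesis, 1.0, "nonhuman_wildtype"),
            _enzyme("GS", spec.cost_glycolysis, 1.0, "nonhuman_wildtype"),
            _enzyme("GLNLYSIS", spec.cost_glycolysis, 1.0, "nonhuman_wildtype"),
            EnzymeParams("EX_gln", 3600.0, 0.0, MEDIAN_FILL, exempt=True),
            EnzymeParams("EX_glu", 3600.0, 0.0, MEDIAN_FILL, exempt=True),
            EnzymeParams("EX_ala", 3600.0, 0.0, MEDIAN_FILL, exempt=True),
        ]

    model = MetabolicModel(mets, rxns, biomass_reaction_id="BIOMASS")
    medium = Medium({"EX_glc": spec.glucose_uptake}, unlimited)
    pathways = {
        "glycolysis": ["GLYC"],
        "oxphos": ["RESP", "O2_t"],
        "fermentation": ["LDH", "LAC_t"],
    }
    return ToyFixture(model, params, medium, spec, pathways)


# --------------------------------------------------------------------------
# kcat resampling (robustness simulations)
# --------------------------------------------------------------------------


def resample_kcats(
    params: list[EnzymeParams],
    known_fraction: float,
    seed: int,
    mode: str = "resample",
) -> list[EnzymeParams]:
    """Simulate sparser kcat knowledge: keep a seeded random fraction of the
    known kcats, redraw every other non-exempt kcat.

    ``mode="resample"`` draws replacements uniformly from the empirical
    known-kcat distribution; ``mode="median_fill"`` assigns the median of
    the *retained* known kcats.  Molecular weights are untouched.
    known_fraction = 1 returns the parameters unchanged.
    """
    if not 0 < known_fraction <= 1:
        raise ModelValidationError("known_fraction must be in (0, 1]")
    if mode not in ("resample", "median_fill"):
        raise ModelValidationError(f"unknown mode {mode!r}")
    known_idx = [
        i for i, p in enumerate(params) if p.kcat_source in KCAT_PRECEDENCE and not p.exempt
    ]
    if not known_idx:
        raise ModelValidationError("no known (non-median-fill) kcats to resample from")
    if known_fraction == 1:
        return [replace(p) for p in params]
    known_values = np.array([params[i].kcat for i in known_idx])
    rng = np.random.default_rng(seed)
    n_keep = max(1, round(known_fraction * len(known_idx)))
    keep = set(np.asarray(known_idx)[rng.choice(len(known_idx), n_keep, replace=False)])
    retained = np.array([params[i].kcat for i in sorted(keep)])
    out = []
    for i, p in enumerate(params):
        if p.exempt or i in keep:
            out.append(replace(p))
        elif mode == "resample":
            out.append(replace(p, kcat=float(rng.choice(known_values))))
        else:
            out.append(replace(p, kcat=float(np.median(retained)), kcat_source=MEDIAN_FILL))
    return out


# --------------------------------------------------------------------------
# synthetic sweeps (unit fixture for the phase detector)
# --------------------------------------------------------------------------


def make_synthetic_sweep(
    boundaries: tuple[float, float],
    n_points: int = 101,
    noise_sd: float = 0.0,
    seed: int = 0,
    max_growth: float = 1.0,
    max_yield: float = 1.0,
    min_yield_factor: float = 0.3,
) -> SweepResult:
    """Piecewise sweep with known phase boundaries (fractions of max growth).

    Yield is flat at *max_yield* up to ``b1`` and declines linearly to
    ``min_yield_factor * max_yield`` at the maximum; the lactate FVA minimum
    is zero up to ``b2`` and ramps up after (lactate possible-but-optional
    below ``b2`` is represented in the FVA maximum).  Optional seeded
    Gaussian noise (sd = ``noise_sd * max_yield``) perturbs the yields.
    """
    b1, b2 = boundaries
    if not 0 < b1 <= b2 <= 1:
        raise ModelValidationError(f"boundaries must satisfy 0 < b1 <= b2 <= 1, got {boundaries}")
    rng = np.random.default_rng(seed)
    points = []
    for f in np.linspace(0.0, 1.0, n_points):
        if f <= b1 or b1 >= 1.0:
            y = max_yield
        else:
            y = max_yield * (1.0 - (1.0 - min_yield_factor) * (f - b1) / (1.0 - b1))
        if noise_sd > 0 and f > 0:
            y = max(0.05 * max_yield, y + rng.normal(0.0, noise_sd * max_yield))
        growth = f * max_growth
        uptake = growth / y
        lac_min = max(0.0, (f - b2) / max(1.0 - b2, 1e-12)) * uptake if f > b2 else 0.0
        lac_max = lac_min + 0.5 * uptake  # lactate is *possible* well before b2
        o2 = uptake * (2.0 if f <= b2 else 2.0 * (1.0 - (f - b2) / max(1.0 - b2, 1e-12)))
        points.append(
            SweepPoint(
                glucose_uptake=uptake,
                growth_rate=growth,
                growth_yield=y,
                lactate_range=FluxRange("EX_lac", lac_min, lac_max),
                oxygen_range=FluxRange("EX_o2", o2, o2),
                cap_binding=f > b1,
            )
        )
    return SweepResult(points, max_growth, points[-1].glucose_uptake)


# --------------------------------------------------------------------------
# synthetic expression (offline stand-in for a tumor-panel matrix)
# --------------------------------------------------------------------------


def make_synthetic_expression(
    concentrations: dict[str, float] | pd.Series,
    rho_target: float,
    n_columns: int,
    seed: int,
) -> pd.DataFrame:
    """Expression matrix whose columns have population Spearman ~ *rho_target*
    against the given per-gene concentrations.

    Uses a Gaussian-copula construction: each column is
    ``r·z + sqrt(1-r^2)·noise`` where ``z`` are normal scores of the
    concentration ranks and the Pearson parameter ``r = 2·sin(pi·rho/6)``
    yields the requested Spearman correlation for bivariate normal ranks.
    """
    if not -1 <= rho_target <= 1:
        raise ModelValidationError("rho_target must be in [-1, 1]")
    conc = pd.Series(concentrations, dtype=float)
    n = len(conc)
    if n < 3:
        raise ModelValidationError("need at least 3 genes")
    ranks = stats.rankdata(conc.to_numpy(), method="average")
    z = stats.norm.ppf(ranks / (n + 1))
    r = 2.0 * np.sin(np.pi * rho_target / 6.0)
    rng = np.random.default_rng(seed)
    cols = {}
    for j in range(n_columns):
        noise = rng.standard_normal(n)
        cols[f"sample_{j:03d}"] = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * noise
    return pd.DataFrame(cols, index=conc.index)
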