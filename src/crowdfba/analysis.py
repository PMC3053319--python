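"""Growth sweeps, overflow-phase detection and downstream analyses.

The central experiment: vary the glucose uptake bound from 0 up to the
uptake that saturates growth, solve capacity-constrained FBA at each point,
and record growth, growth yield (growth rate / glucose uptake) and FVA
ranges for lactate secretion and oxygen uptake.  Three regimes emerge on a
Warburg-generating network: (I) optimal-yield respiration while glucose is
the sole limiting factor, (II) declining yield once the enzyme-capacity cap
binds, and (III) obligatory lactate secretion (aerobic glycolysis) at the
highest growth rates.  Because optimal flux vectors are degenerate, phase
boundaries are defined through FVA *minima* (necessity), never through a
single solver-dependent solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MetabolicModel, Medium, ModelValidationError, logger
from .enzymes import CrowdingParams, EnzymeParams, strip_direction
from .solver import OPTIMAL, FluxRange, FluxSolution, REPORT_TOL, fba, fva

# --------------------------------------------------------------------------
# sweep data structures
# --------------------------------------------------------------------------


@dataclass
class SweepPoint:
    """One glucose-uptake operating point.

    ``lactate_range`` is the FVA range of lactate *secretion* and
    ``oxygen_range`` the range of oxygen *uptake*, both as positive
    magnitudes in mmol/(gDW·h).  ``growth_yield`` is growth rate per unit
    glucose uptake; at zero uptake it carries the analytic limit (the
    stoichiometric maximal yield) rather than 0/0.
    """

    glucose_uptake: float
    growth_rate: float
    growth_yield: float
    lactate_range: FluxRange
    oxygen_range: FluxRange
    cap_binding: bool


@dataclass
class SweepResult:
    points: list[SweepPoint]
    max_growth: float
    uptake_at_max: float

    def growth_fractions(self) -> np.ndarray:
        if self.max_growth <= 0:
            return np.zeros(len(self.points))
        return np.array([p.growth_rate / self.max_growth for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            u = p.glucose_uptake
            rows.append(
                {
                    "uptake": u,
                    "growth": p.growth_rate,
                    "yield": p.growth_yield,
                    "lactate_min": p.lactate_range.min_flux,
                    "lactate_max": p.lactate_range.max_flux,
                    "o2_min": p.oxygen_range.min_flux,
                    "o2_max": p.oxygen_range.max_flux,
                    "lactate_min_per_glc": p.lactate_range.min_flux / u if u > 0 else 0.0,
                    "lactate_max_per_glc": p.lactate_range.max_flux / u if u > 0 else 0.0,
                    "o2_min_per_glc": p.oxygen_range.min_flux / u if u > 0 else 0.0,
                    "o2_max_per_glc": p.oxygen_range.max_flux / u if u > 0 else 0.0,
                    "cap_binding": int(p.cap_binding),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class PhaseAnnotation:
    """Boundaries between the three growth regimes, as fractions of max growth.

    Phase I ends where the yield departs from the sweep's maximum
    (``boundary_I_II``); phase III starts where the lactate FVA minimum
    exceeds ``epsilon_lactate`` — i.e. where lactate secretion becomes
    *necessary*, not merely possible.  ``no_phase_III`` flags sweeps with no
    obligatory lactate anywhere (e.g. the uniform-cost negative control).
    """

    boundary_I_II: float
    boundary_II_III: float
    epsilon_lactate: float
    yield_tol: float = 0.01
    no_phase_III: bool = False

    def __post_init__(self):
        if not (0 < self.boundary_I_II <= self.boundary_II_III <= 1 + REPORT_TOL):
            raise ModelValidationError(
                f"phase boundaries out of order: {self.boundary_I_II}, {self.boundary_II_III}"
            )

    def to_dict(self) -> dict:
        return {
            "boundary_I_II": self.boundary_I_II,
            "boundary_II_III": self.boundary_II_III,
            "epsilon_lactate": self.epsilon_lactate,
            "yield_tol": self.yield_tol,
            "no_phase_III": self.no_phase_III,
        }


# --------------------------------------------------------------------------
# growth sweep
# --------------------------------------------------------------------------


def _growth_at(model, medium, crowding, glucose_exchange, uptake) -> FluxSolution:
    return fba(model, medium.with_uptake(glucose_exchange, uptake), crowding=crowding)


def find_saturating_uptake(
    model: MetabolicModel,
    medium: Medium,
    crowding: CrowdingParams,
    glucose_exchange: str = "EX_glc",
    tol: float = 1e-9,
    max_uptake: float = 1e6,
) -> float:
    """Smallest glucose uptake at which growth reaches its plateau.

    Growth is a concave non-decreasing function of the uptake bound (LP
    value function), so the plateau is found by doubling until the marginal
    growth vanishes, then bisecting on ``growth(U) >= plateau - tol``.
    """
    hi = 1.0
    g_hi = _growth_at(model, medium, crowding, glucose_exchange, hi).objective_value
    while hi < max_uptake:
        g_next = _growth_at(model, medium, crowding, glucose_exchange, 2 * hi).objective_value
        if g_next <= g_hi + tol:
            break
        hi, g_hi = 2 * hi, g_next
    else:
        raise ModelValidationError("growth does not saturate below the uptake ceiling")
    plateau = _growth_at(model, medium, crowding, glucose_exchange, 2 * hi).objective_value
    lo = 0.0
    hi = 2 * hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _growth_at(model, medium, crowding, glucose_exchange, mid).objective_value >= plateau - tol:
            hi = mid
        else:
            lo = mid
    return hi


def growth_sweep(
    model: MetabolicModel,
    medium: Medium,
    crowding: CrowdingParams | None,
    n_points: int = 100,
    glucose_exchange: str = "EX_glc",
    lactate_exchange: str = "EX_lac",
    oxygen_exchange: str = "EX_o2",
    max_uptake: float | None = None,
) -> SweepResult:
    """Sweep the glucose uptake bound and record growth, yield and FVA ranges.

    The grid runs from 0 to the saturating uptake (bisection-refined when
    *crowding* is given; without a cap growth never saturates, so
    *max_uptake* must then be supplied — the stoichiometric-only reference
    sweep).  Lactate/oxygen FVA is run at growth fraction 1 of each point's
    own optimum.
    """
    if n_points < 3:
        raise ModelValidationError("n_points must be >= 3")
    if max_uptake is not None:
        u_sat = float(max_uptake)
    elif crowding is not None:
        u_sat = find_saturating_uptake(model, medium, crowding, glucose_exchange)
    else:
        raise ModelValidationError(
            "without crowding the sweep does not saturate; pass max_uptake"
        )

    # analytic zero-uptake yield: the slope of growth in uptake at the origin,
    # where the cap cannot bind — i.e. the stoichiometric maximal yield
    yield0 = fba(model, medium.with_uptake(glucose_exchange, 1.0), crowding=None).objective_value

    points: list[SweepPoint] = []
    for u in np.linspace(0.0, u_sat, n_points):
        med = medium.with_uptake(glucose_exchange, float(u))
        sol = fba(model, med, crowding=crowding)
        if sol.status != OPTIMAL:
            raise ModelValidationError(f"sweep point uptake={u}: solver status {sol.status}")
        growth = sol.objective_value
        ranges = fva(
            model, med, crowding, [lactate_exchange, oxygen_exchange], growth_fraction=1.0
        )
        lac, o2 = ranges
        # lactate secretion and oxygen uptake as positive magnitudes
        lac_range = FluxRange(
            lactate_exchange, max(lac.min_flux, 0.0), max(lac.max_flux, 0.0)
        )
        o2_range = FluxRange(oxygen_exchange, max(-o2.max_flux, 0.0), max(-o2.min_flux, 0.0))
        points.append(
            SweepPoint(
                glucose_uptake=float(u),
                growth_rate=growth,
                growth_yield=growth / u if u > 0 else yield0,
                lactate_range=lac_range,
                oxygen_range=o2_range,
                cap_binding=sol.cap_binding,
            )
        )
    return SweepResult(points, points[-1].growth_rate, u_sat)


# --------------------------------------------------------------------------
# phase detection
# --------------------------------------------------------------------------


def detect_phases(
    sweep: SweepResult, epsilon_lactate: float = 1e-6, yield_tol: float = 0.01
) -> PhaseAnnotation:
    """Locate the phase boundaries from a sweep.

    boundary_I_II: largest growth fraction whose yield is within *yield_tol*
    (relative) of the sweep's maximal yield — the end of the optimal-yield
    regime.  boundary_II_III: smallest growth fraction whose lactate FVA
    minimum exceeds *epsilon_lactate* — where lactate secretion becomes
    necessary.  When lactate is never necessary the sweep has no phase III
    (``boundary_II_III = 1.0``, flag set).
    """
    if not sweep.points:
        raise ModelValidationError("empty sweep")
    fractions = sweep.growth_fractions()
    yields = np.array([p.growth_yield for p in sweep.points])
    lac_min = np.array([p.lactate_range.min_flux for p in sweep.points])

    max_yield = float(np.max(yields))
    near_opt = yields >= max_yield * (1 - yield_tol)
    b1 = float(np.max(fractions[near_opt])) if near_opt.any() else float(fractions[0])
    b1 = max(b1, REPORT_TOL)  # the zero-uptake point always has optimal yield

    necessary = lac_min > epsilon_lactate
    if necessary.any():
        b2 = float(np.min(fractions[necessary]))
        no_iii = False
    else:
        b2, no_iii = 1.0, True
    b1 = min(b1, b2)  # grid round-off can put yield departure after lactate onset
    return PhaseAnnotation(b1, min(b2, 1.0), epsilon_lactate, yield_tol, no_iii)


def phase_operating_points(sweep: SweepResult, phases: PhaseAnnotation) -> dict[str, float]:
    """Growth rates at the midpoints of the three phases (absolute, 1/h)."""
    b1, b2 = phases.boundary_I_II, phases.boundary_II_III
    return {
        "I": 0.5 * b1 * sweep.max_growth,
        "II": 0.5 * (b1 + b2) * sweep.max_growth,
        "III": 0.5 * (b2 + 1.0) * sweep.max_growth,
    }


# --------------------------------------------------------------------------
# two-strategy geometry
# --------------------------------------------------------------------------


@dataclass
class TwoStrategySpec:
    """The reduced two-route picture of the yield/cost trade-off.

    Strategy A: high growth yield per glucose (Y_A) but high enzyme cost per
    glucose (C_A) — respiration.  Strategy B: lower yield, much lower cost —
    fermentation.  U bounds total glucose uptake; C bounds total enzyme
    cost.  In the canonical overflow configuration Y_A > Y_B, C_A > C_B and
    Y_B/C_B > Y_A/C_A.
    """

    Y_A: float
    C_A: float
    Y_B: float
    C_B: float
    U: float
    C: float

    def __post_init__(self):
        for name in ("Y_A", "C_A", "Y_B", "C_B", "U", "C"):
            if getattr(self, name) <= 0:
                raise ModelValidationError(f"{name} must be > 0")


def two_strategy_optimum(spec: TwoStrategySpec) -> tuple[float, float, float]:
    """Closed-form optimum of max Y_A·u_A + Y_B·u_B over the 2-D polytope.

    Constraints: u_A + u_B <= U, C_A·u_A + C_B·u_B <= C, u >= 0.  Solved by
    enumerating the (at most five) vertices.  Ties are broken toward the
    larger u_A, so the glucose-limited regime reports the pure-A solution.
    Returns (u_A, u_B, growth).
    """
    Y_A, C_A, Y_B, C_B, U, C = spec.Y_A, spec.C_A, spec.Y_B, spec.C_B, spec.U, spec.C
    vertices = [
        (0.0, 0.0),
        (min(U, C / C_A), 0.0),
        (0.0, min(U, C / C_B)),
    ]
    if abs(C_A - C_B) > 1e-15:
        ua = (C - C_B * U) / (C_A - C_B)
        ub = U - ua
        if ua >= -1e-12 and ub >= -1e-12:
            vertices.append((max(ua, 0.0), max(ub, 0.0)))
    best = max(vertices, key=lambda v: (Y_A * v[0] + Y_B * v[1], v[0]))
    return best[0], best[1], Y_A * best[0] + Y_B * best[1]


def yield_to_cost_ratio(Y: float, C: float) -> float:
    """Growth yield per unit of enzyme-concentration cost, Y / C."""
    if C <= 0:
        raise ModelValidationError(f"cost must be > 0, got {C}")
    return Y / C


def round_to_sig(x: float, sig: int = 2) -> float:
    """Round to *sig* significant figures (for reporting alongside full precision)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


# --------------------------------------------------------------------------
# amino-acid sweep
# --------------------------------------------------------------------------


def amino_acid_sweep(
    model: MetabolicModel,
    medium: Medium,
    crowding: CrowdingParams | None,
    aa_exchange_ids: list[str],
    aa_uptake_bound: float | None = None,
    glucose_exchange: str = "EX_glc",
    modes: tuple[str, ...] = ("stoichiometric", "crowding"),
) -> pd.DataFrame:
    """Growth gain from adding each amino acid to the glucose medium.

    For each amino-acid exchange, maximal growth with glucose + that amino
    acid (uptake bounded by *aa_uptake_bound*, defaulting to the glucose
    bound) minus the glucose-only baseline, in both the stoichiometric-only
    and the capacity-constrained model.  Amino acids whose exchange is
    absent from the model are reported as NaN and the run continues.
    Returns a tidy frame: amino_acid, mode, gain_abs (1/h), gain_pct.
    """
    if aa_uptake_bound is None:
        if glucose_exchange not in medium.uptake_bounds:
            raise ModelValidationError("no glucose bound in medium to default the amino-acid bound to")
        aa_uptake_bound = medium.uptake_bounds[glucose_exchange]

    mode_crowding = {"stoichiometric": None, "crowding": crowding}
    rows = []
    for mode in modes:
        cr = mode_crowding[mode]
        if mode == "crowding" and cr is None:
            raise ModelValidationError("crowding mode requested but no CrowdingParams given")
        baseline = fba(model, medium, crowding=cr).objective_value
        for aa in aa_exchange_ids:
            if not model.has_reaction(aa):
                logger.warning("amino-acid exchange %s not in model; skipped", aa)
                rows.append({"amino_acid": aa, "mode": mode, "gain_abs": np.nan, "gain_pct": np.nan})
                continue
            growth = fba(model, medium.with_uptake(aa, aa_uptake_bound), crowding=cr).objective_value
            gain = growth - baseline
            rows.append(
                {
                    "amino_acid": aa,
                    "mode": mode,
                    "gain_abs": gain,
                    "gain_pct": 100.0 * gain / baseline if baseline > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# enzyme concentrations & expression correlation
# --------------------------------------------------------------------------


@dataclass
class GeneConcentration:
    gene: str
    concentration: float  # mg/mgDW

    def __post_init__(self):
        if self.concentration < -REPORT_TOL:
            raise ModelValidationError(f"{self.gene}: negative concentration")


def enzyme_concentrations(
    flux: FluxSolution,
    params: list[EnzymeParams],
    gene_to_reactions: dict[str, list[str]],
) -> list[GeneConcentration]:
    """Per-gene enzyme concentration implied by a flux distribution.

    Per reaction, c_i = v_i · MW_i / kcat_i (mg/mgDW, same scaling as the
    crowding constraint; exempt reactions contribute 0).  Per gene, the sum
    over all reactions the gene is associated with — a reaction shared by
    several genes is counted in full for each (documented double counting).
    """
    by_id = {p.reaction_id: p for p in params}
    per_reaction: dict[str, float] = {}
    for rid, v in flux.fluxes.items():
        base = strip_direction(rid)
        p = by_id.get(base)
        if p is None:
            continue
        per_reaction[base] = per_reaction.get(base, 0.0) + max(v, 0.0) * p.cost_coefficient
    out = []
    for gene, rxns in sorted(gene_to_reactions.items()):
        total = sum(per_reaction.get(strip_direction(r), 0.0) for r in rxns)
        out.append(GeneConcentration(gene, max(total, 0.0)))
    return out


@dataclass
class CorrelationResult:
    """Per-column Spearman correlations of predicted enzyme concentration
    vs. expression, plus an optional paired comparison of two models."""

    per_column: pd.Series
    mean_rho: float
    per_column_other: pd.Series | None = None
    mean_rho_other: float | None = None
    wilcoxon_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"rho": self.per_column})
        if self.per_column_other is not None:
            df["rho_other"] = self.per_column_other
        return df


def correlate_expression(
    concentrations: dict[str, float],
    expression: pd.DataFrame,
    other_concentrations: dict[str, float] | None = None,
    min_shared: int = 3,
    drop_all_zero: bool = False,
) -> CorrelationResult:
    """Rank-correlate predicted per-gene concentrations with expression.

    *expression* is genes x samples (e.g. cell lines).  For every column the
    Spearman rho over genes shared with the concentration vector is computed
    (ties handled by average ranks); columns with fewer than *min_shared*
    shared genes are skipped with a warning.  When a second model's
    concentrations are given, the per-column rhos of the two models are
    compared with a paired two-sided Wilcoxon signed-rank test.
    ``drop_all_zero`` removes genes with zero predicted concentration in
    both models before correlating (off by default).
    """
    conc = pd.Series(concentrations, dtype=float)
    other = pd.Series(other_concentrations, dtype=float) if other_concentrations is not None else None
    shared = conc.index.intersection(expression.index)
    if other is not None:
        shared = shared.intersection(other.index)
    if drop_all_zero:
        nz = conc.loc[shared] != 0
        if other is not None:
            nz = nz | (other.loc[shared] != 0)
        shared = shared[nz]

    rhos, rhos_other = {}, {}
    for col in expression.columns:
        x = expression.loc[shared, col].astype(float)
        ok = x.notna()
        if ok.sum() < min_shared:
            logger.warning("column %s: only %d shared genes; skipped", col, int(ok.sum()))
            continue
        rhos[col] = float(stats.spearmanr(conc.loc[shared][ok], x[ok]).statistic)
        if other is not None:
            rhos_other[col] = float(stats.spearmanr(other.loc[shared][ok], x[ok]).statistic)
    if not rhos:
        raise ModelValidationError("no expression column had enough shared genes")
    per_col = pd.Series(rhos)
    result = CorrelationResult(per_col, float(per_col.mean()))
    if other is not None:
        po = pd.Series(rhos_other)
        result.per_column_other = po
        result.mean_rho_other = float(po.mean())
        diff = per_col - po
        if np.allclose(diff, 0):
            result.wilcoxon_p = 1.0
        else:
            result.wilcoxon_p = float(stats.wilcoxon(per_col, po).pvalue)
    return result


# --------------------------------------------------------------------------
# optional plotting
# --------------------------------------------------------------------------


def plot_sweep(sweep: SweepResult, phases: PhaseAnnotation | None = None, path=None):
    """Simple two-panel sweep figure (yield; lactate/O2 per glucose)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = sweep.to_frame()
    frac = sweep.growth_fractions()
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    ax1.plot(frac, df["yield"], "k-")
    ax1.set_ylabel("growth yield (1/h per mmol/(gDW·h))")
    ax2.plot(frac, df["lactate_min_per_glc"], "r-", label="lactate (min)")
    ax2.plot(frac, df["lactate_max_per_glc"], "r--", label="lactate (max)")
    ax2.plot(frac, df["o2_min_per_glc"], "b-", label="O2 (min)")
    ax2.plot(frac, df["o2_max_per_glc"], "b--", label="O2 (max)")
    ax2.set_xlabel("fraction of maximal growth rate")
    ax2.set_ylabel("flux per glucose")
    ax2.legend(fontsize=8)
    if phases is not None:
        for ax in (ax1, ax2):
            ax.axvline(phases.boundary_I_II, ls=":", c="grey")
            ax.axvline(phases.boundary_II_III, ls=":", c="grey")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
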