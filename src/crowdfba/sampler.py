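"""Artificial-centering hit-and-run (ACHR) sampling of the flux polytope.

The feasible region — S·v = 0, bounds, capacity caps, optional growth
fixing — is a convex polytope inside the null space of S.  Warmup points
are obtained from per-reaction min/max LPs; every subsequent step moves
from the current point along the direction through a random warmup point
and the running center (differences of feasible points stay in the null
space, so the equality constraints are preserved exactly), truncates the
chord against all linear inequalities, and samples uniformly on it.

The coordinate-wise median of a sample set is the "typical" flux
distribution used for pathway activity summaries; note that a
coordinate-wise median of polytope points need not satisfy S·v = 0 itself,
so its mass-balance residual is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MetabolicModel, Medium, ModelValidationError, logger
from .enzymes import CrowdingParams
from .solver import _LP, OPTIMAL, FluxSolution, _prepare

_DEGENERATE_CHORD = 1e-12
_MAX_RETRIES = 50


def chord_limits(
    x: np.ndarray,
    d: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    A: np.ndarray | None = None,
    b: np.ndarray | None = None,
    tol: float = 1e-12,
) -> tuple[float, float]:
    """Feasible parameter interval [t_min, t_max] for the ray x + t·d.

    Considers the box lb <= x + t·d <= ub and, when given, the half-spaces
    A·(x + t·d) <= b.  Returns an empty interval (t_min > t_max) when the
    ray through x does not intersect the region.
    """
    t_min, t_max = -np.inf, np.inf
    pos = d > tol
    neg = d < -tol
    if pos.any():
        t_max = min(t_max, np.min((ub[pos] - x[pos]) / d[pos]))
        t_min = max(t_min, np.max((lb[pos] - x[pos]) / d[pos]))
    if neg.any():
        t_max = min(t_max, np.min((lb[neg] - x[neg]) / d[neg]))
        t_min = max(t_min, np.max((ub[neg] - x[neg]) / d[neg]))
    if A is not None and len(A):
        s = A @ d
        r = b - A @ x
        pos = s > tol
        neg = s < -tol
        if pos.any():
            t_max = min(t_max, np.min(r[pos] / s[pos]))
        if neg.any():
            t_min = max(t_min, np.max(r[neg] / s[neg]))
    return float(t_min), float(t_max)


@dataclass
class SampleSet:
    """Uniform samples from the constrained flux space (rows = samples)."""

    samples: np.ndarray
    reaction_ids: list[str]
    seed: int
    n_warmup: int
    thinning: int
    model: MetabolicModel = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.reaction_ids)

    def max_violation(self, crowding: CrowdingParams | None = None) -> dict[str, float]:
        """Worst-case constraint violations across all rows (diagnostics)."""
        out = {}
        S = self.model.stoichiometric_matrix()
        out["mass_balance"] = float(np.abs(S @ self.samples.T).max())
        lb = np.array([r.lower_bound for r in self.model.reactions])
        ub = np.array([r.upper_bound for r in self.model.reactions])
        out["bounds"] = float(
            max(np.max(lb[None, :] - self.samples, initial=0.0), np.max(self.samples - ub[None, :], initial=0.0))
        )
        if crowding is not None:
            lp = _LP(self.model, crowding)
            viol = 0.0
            for name, row, cap in lp.cap_rows:
                viol = max(viol, float(np.max(self.samples @ row - cap, initial=0.0)))
            out["crowding"] = viol
        return out


def achr_sample(
    model: MetabolicModel,
    medium: Medium | None = None,
    crowding: CrowdingParams | None = None,
    growth_fraction: float = 0.0,
    n_samples: int = 100,
    seed: int = 0,
    thinning: int = 100,
    max_warmup: int = 2000,
    objective_id: str | None = None,
) -> SampleSet:
    """Sample the flux polytope uniformly with ACHR.

    ``growth_fraction`` > 0 adds the half-space
    ``objective >= growth_fraction * optimum`` before sampling.  Warmup uses
    2 LPs (min and max) per reaction, capped at *max_warmup* points.
    Deterministic for a given seed and configuration.
    """
    work = _prepare(model, medium, crowding)
    lp = _LP(work, crowding)
    A_rows = [row for _, row, _ in lp.cap_rows]
    b_rows = [cap for _, _, cap in lp.cap_rows]
    if growth_fraction > 0:
        obj_id = objective_id or model.biomass_reaction_id
        obj = lp.column_vector({obj_id: 1.0})
        status, optimum, _ = lp.solve(obj, maximize=True)
        if status != OPTIMAL:
            raise ModelValidationError(f"growth-fixing optimum unavailable: {status}")
        A_rows.append(-obj)
        b_rows.append(-(growth_fraction * optimum - 1e-9))
    A = np.vstack(A_rows) if A_rows else None
    b = np.array(b_rows) if A_rows else None
    extra = list(zip(A_rows[len(lp.cap_rows):], b_rows[len(lp.cap_rows):]))

    rng = np.random.default_rng(seed)
    n = work.n_reactions
    idx_all = np.arange(n)
    if 2 * n > max_warmup:
        idx_all = rng.choice(n, max_warmup // 2, replace=False)
    warmup = []
    for j in idx_all:
        e = np.zeros(n)
        e[j] = 1.0
        for maximize in (False, True):
            status, _, x = lp.solve(e, maximize=maximize, extra_ub=extra)
            if status != OPTIMAL:
                raise ModelValidationError(f"warmup LP for column {j} not optimal: {status}")
            warmup.append(x)
    warmup = np.array(warmup)
    n_warmup = len(warmup)
    if np.ptp(warmup, axis=0).max() < _DEGENERATE_CHORD:
        # fully determined flux space: every sample is the unique point
        samples = np.repeat(warmup[:1], n_samples, axis=0)
        return SampleSet(samples, work.reaction_ids, seed, n_warmup, thinning, work)

    center = warmup.mean(axis=0)
    x = center.copy()
    count = n_warmup
    kept = np.empty((n_samples, n), dtype=float)
    n_kept = 0
    step = 0
    while n_kept < n_samples:
        for attempt in range(_MAX_RETRIES):
            d = warmup[rng.integers(n_warmup)] - center
            norm = np.linalg.norm(d)
            if norm < _DEGENERATE_CHORD:
                continue
            d = d / norm
            t_min, t_max = chord_limits(x, d, lp.lb, lp.ub, A, b)
            if t_max - t_min >= _DEGENERATE_CHORD:
                break
        else:
            raise ModelValidationError("ACHR: no non-degenerate chord found (region too thin)")
        x = x + rng.uniform(t_min, t_max) * d
        np.clip(x, lp.lb, lp.ub, out=x)
        center = (center * count + x) / (count + 1)
        count += 1
        step += 1
        if step % thinning == 0:
            kept[n_kept] = x
            n_kept += 1
    return SampleSet(kept, work.reaction_ids, seed, n_warmup, thinning, work)


def median_flux(sample_set: SampleSet) -> FluxSolution:
    """Coordinate-wise median flux distribution of a sample set.

    The median of polytope points is generally *not* mass-balanced; the
    residual ``||S·median||_inf`` is recorded in the binding report.
    """
    if len(sample_set.samples) < 1:
        raise ModelValidationError("empty sample set")
    med = np.median(sample_set.samples, axis=0)
    fluxes = dict(zip(sample_set.reaction_ids, map(float, med)))
    model = sample_set.model
    report = {}
    objective = float("nan")
    if model is not None:
        S = model.stoichiometric_matrix()
        report["mass_balance_residual_inf"] = float(np.abs(S @ med).max())
        if model.biomass_reaction_id is not None:
            objective = fluxes.get(model.biomass_reaction_id, float("nan"))
    return FluxSolution(fluxes, objective, OPTIMAL, report, model.split_map if model else None)


@dataclass
class PathwayActivity:
    pathway: str
    mean_flux: float
    member_reactions: list[str]


def pathway_activity(
    sample_set: SampleSet, pathway_map: dict[str, list[str]]
) -> list[PathwayActivity]:
    """Mean median-flux over each pathway's member reactions.

    Member ids refer to original (pre-split) reactions; their net median
    fluxes are collapsed from the split sample columns and averaged as
    magnitudes.  Pathways with no member present in the model are skipped
    with a warning.
    """
    med = median_flux(sample_set)
    nets = med.net()
    out = []
    for pathway, members in pathway_map.items():
        vals = [abs(nets[m]) for m in members if m in nets]
        if not vals:
            logger.warning("pathway %s: no member reactions in model; skipped", pathway)
            continue
        out.append(PathwayActivity(pathway, float(np.mean(vals)), list(members)))
    return out
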