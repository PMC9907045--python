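"""Vulnerability sets: star-sets, chokepoints, dead-end metabolites,
reaction classification, essentiality and blocked reactions.

All directional notions account for the flux directions the bounds allow:
a reversible reaction consumes and produces on both of its sides.  The
"structural" level ignores bounds and uses only stoichiometric signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from .model import (
    EPS,
    ConstraintBasedModel,
    apply_bounds,
)
from .lp import (
    GrowthContext,
    _Backend,
    fva,
    get_backend,
    knockout_optima,
)

__all__ = [
    "ReactionPartition",
    "VulnerabilityReport",
    "star_reactants",
    "star_products",
    "star_consumers",
    "star_producers",
    "chokepoints",
    "dead_end_metabolites",
    "classify_reactions",
    "essential_reactions",
    "growth_dependent_essential",
    "blocked_reactions",
    "growth_dependent_sets",
    "flux_level_report",
    "remove_dead_end_metabolites",
]


@dataclass(frozen=True)
class ReactionPartition:
    """Disjoint dead / reversible / non-reversible split of all reactions."""

    dead: frozenset[str]
    reversible: frozenset[str]
    non_reversible: frozenset[str]

    def __post_init__(self) -> None:
        if (
            self.dead & self.reversible
            or self.dead & self.non_reversible
            or self.reversible & self.non_reversible
        ):
            raise ValueError("reaction classes overlap")

    @property
    def all_reactions(self) -> frozenset[str]:
        return self.dead | self.reversible | self.non_reversible


@dataclass(frozen=True)
class VulnerabilityReport:
    """All vulnerability sets of one model at one analysis level."""

    chokepoints: frozenset[str]
    dead_end_metabolites: frozenset[str]
    essential: frozenset[str]
    blocked: frozenset[str]
    partition: ReactionPartition
    gamma: float | None = None
    level: str = "flux"  # "structural", "flux" or "growth"

    def validate(self) -> None:
        if self.chokepoints & self.partition.dead:
            raise AssertionError("a dead reaction cannot be a chokepoint")


# ---------------------------------------------------------------------------
# star-sets
# ---------------------------------------------------------------------------


def star_reactants(
    model: ConstraintBasedModel, reaction_id: str, epsilon: float = EPS
) -> set[str]:
    """Metabolites the reaction can consume in some admissible direction."""
    j = model.reaction_index(reaction_id)
    fwd = model.upper_bounds[j] > epsilon
    bwd = model.lower_bounds[j] < -epsilon
    col = model.stoichiometry.getcol(j).tocoo()
    return {
        model.metabolites[i]
        for i, v in zip(col.row, col.data)
        if (v < 0 and fwd) or (v > 0 and bwd)
    }


def star_products(
    model: ConstraintBasedModel, reaction_id: str, epsilon: float = EPS
) -> set[str]:
    """Metabolites the reaction can produce in some admissible direction."""
    j = model.reaction_index(reaction_id)
    fwd = model.upper_bounds[j] > epsilon
    bwd = model.lower_bounds[j] < -epsilon
    col = model.stoichiometry.getcol(j).tocoo()
    return {
        model.metabolites[i]
        for i, v in zip(col.row, col.data)
        if (v > 0 and fwd) or (v < 0 and bwd)
    }


def star_consumers(
    model: ConstraintBasedModel, metabolite_id: str, epsilon: float = EPS
) -> set[str]:
    """Reactions having the metabolite among their star-reactants."""
    i = model.metabolite_index(metabolite_id)
    row = model.stoichiometry.getrow(i).tocoo()
    out = set()
    for j, v in zip(row.col, row.data):
        fwd = model.upper_bounds[j] > epsilon
        bwd = model.lower_bounds[j] < -epsilon
        if (v < 0 and fwd) or (v > 0 and bwd):
            out.add(model.reactions[j])
    return out


def star_producers(
    model: ConstraintBasedModel, metabolite_id: str, epsilon: float = EPS
) -> set[str]:
    """Reactions having the metabolite among their star-products."""
    i = model.metabolite_index(metabolite_id)
    row = model.stoichiometry.getrow(i).tocoo()
    out = set()
    for j, v in zip(row.col, row.data):
        fwd = model.upper_bounds[j] > epsilon
        bwd = model.lower_bounds[j] < -epsilon
        if (v > 0 and fwd) or (v < 0 and bwd):
            out.add(model.reactions[j])
    return out


def _direction_matrices(
    model: ConstraintBasedModel, epsilon: float, structural: bool
) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
    """Boolean (metabolite x reaction) consumer and producer matrices."""
    S = model.stoichiometry
    pos = (S > 0).astype(np.int8)
    neg = (S < 0).astype(np.int8)
    if structural:
        producers = pos
        consumers = neg
    else:
        fwd = (model.upper_bounds > epsilon).astype(np.int8)
        bwd = (model.lower_bounds < -epsilon).astype(np.int8)
        consumers = neg.multiply(fwd[np.newaxis, :]) + pos.multiply(bwd[np.newaxis, :])
        producers = pos.multiply(fwd[np.newaxis, :]) + neg.multiply(bwd[np.newaxis, :])
    return sparse.csr_matrix(consumers), sparse.csr_matrix(producers)


def _analysis_rows(model: ConstraintBasedModel, include_boundary: bool) -> np.ndarray:
    if include_boundary:
        return np.arange(model.n_metabolites)
    return model.internal_rows()


def chokepoints(
    model: ConstraintBasedModel,
    epsilon: float = EPS,
    level: str = "flux",
    include_boundary: bool = False,
) -> frozenset[str]:
    """Reactions that are the unique consumer or unique producer of some
    metabolite, in the direction-aware sense (``level="flux"``) or from
    stoichiometric signs alone (``level="structural"``)."""
    consumers, producers = _direction_matrices(model, epsilon, level == "structural")
    found: set[str] = set()
    for mat in (consumers, producers):
        counts = np.asarray((mat != 0).sum(axis=1)).ravel()
        for i in _analysis_rows(model, include_boundary):
            if counts[i] == 1:
                row = mat.getrow(i)
                j = row.indices[np.flatnonzero(row.data)[0]]
                found.add(model.reactions[j])
    return frozenset(found)


def dead_end_metabolites(
    model: ConstraintBasedModel,
    epsilon: float = EPS,
    level: str = "flux",
    include_boundary: bool = False,
) -> frozenset[str]:
    """Metabolites with no consumer or no producer at the given level."""
    consumers, producers = _direction_matrices(model, epsilon, level == "structural")
    n_cons = np.asarray((consumers != 0).sum(axis=1)).ravel()
    n_prod = np.asarray((producers != 0).sum(axis=1)).ravel()
    return frozenset(
        model.metabolites[i]
        for i in _analysis_rows(model, include_boundary)
        if n_cons[i] == 0 or n_prod[i] == 0
    )


# ---------------------------------------------------------------------------
# reaction classification and essentiality
# ---------------------------------------------------------------------------


def classify_reactions(
    model: ConstraintBasedModel, epsilon: float = EPS
) -> ReactionPartition:
    """Partition reactions into dead, reversible and non-reversible.

    Dead: both bounds zero.  Reversible: strictly negative lower and
    strictly positive upper bound.  Everything else is non-reversible.
    """
    L, U = model.lower_bounds, model.upper_bounds
    dead, rev, nonrev = set(), set(), set()
    for j, r in enumerate(model.reactions):
        if abs(L[j]) <= epsilon and abs(U[j]) <= epsilon:
            dead.add(r)
        elif L[j] < -epsilon and U[j] > epsilon:
            rev.add(r)
        else:
            nonrev.add(r)
    return ReactionPartition(frozenset(dead), frozenset(rev), frozenset(nonrev))


def essential_reactions(
    model: ConstraintBasedModel,
    solver: str = "glpk",
    epsilon: float = EPS,
    optima=None,
) -> frozenset[str]:
    """Reactions whose knockout drives maximal growth to zero (or makes
    the knockout LP infeasible)."""
    optima = optima if optima is not None else knockout_optima(model, solver)
    return frozenset(
        r
        for r, res in optima.items()
        if not res.optimal or max(res.objective_value, 0.0) <= epsilon
    )


def growth_dependent_essential(
    model: ConstraintBasedModel,
    ctx: GrowthContext,
    solver: str = "glpk",
    epsilon_rel: float = EPS,
    optima=None,
) -> frozenset[str]:
    """Reactions whose knockout drops the growth optimum strictly below
    ``gamma * mu_max`` (or makes the knockout LP infeasible).

    The strict comparison carries a relative tolerance so alternate optima
    at exactly the floor are not misclassified; at ``gamma = 0`` the set
    contains only infeasible knockouts (none, in practice).
    """
    optima = optima if optima is not None else knockout_optima(model, solver)
    threshold = ctx.growth_floor * (1.0 - epsilon_rel)
    return frozenset(
        r
        for r, res in optima.items()
        if not res.optimal or max(res.objective_value, 0.0) < threshold
    )


def blocked_reactions(
    model: ConstraintBasedModel, solver: str = "glpk", epsilon: float = EPS
) -> frozenset[str]:
    """Reactions with zero flux at every steady state.

    Computed as the reactions whose flux variability interval without any
    growth floor collapses to [0, 0].
    """
    fb = fva(model, None, solver=solver, epsilon=epsilon)
    return frozenset(
        r
        for j, r in enumerate(model.reactions)
        if abs(fb.lower[j]) <= epsilon and abs(fb.upper[j]) <= epsilon
    )


# ---------------------------------------------------------------------------
# growth-dependent analysis
# ---------------------------------------------------------------------------


def growth_dependent_sets(
    model: ConstraintBasedModel,
    ctx: GrowthContext,
    solver: str = "glpk",
    epsilon: float = EPS,
    include_boundary: bool = False,
    optima=None,
) -> VulnerabilityReport:
    """Full vulnerability report of the FVA-constrained model at ``ctx.gamma``.

    FVA bounds at the given growth fraction replace the raw bounds before
    classification, chokepoint and dead-end analysis; growth-dependent
    essentiality is evaluated against the original model per its
    definition.  ``optima`` may carry precomputed knockout results.
    """
    bounds = fva(model, ctx, solver=solver, epsilon=epsilon)
    constrained = apply_bounds(model, bounds)
    partition = classify_reactions(constrained, epsilon)
    report = VulnerabilityReport(
        chokepoints=chokepoints(constrained, epsilon, include_boundary=include_boundary),
        dead_end_metabolites=dead_end_metabolites(
            constrained, epsilon, include_boundary=include_boundary
        ),
        essential=growth_dependent_essential(model, ctx, solver, optima=optima),
        blocked=blocked_reactions(model, solver, epsilon),
        partition=partition,
        gamma=ctx.gamma,
        level="growth",
    )
    report.validate()
    return report


def flux_level_report(
    model: ConstraintBasedModel,
    solver: str = "glpk",
    epsilon: float = EPS,
    include_boundary: bool = False,
    optima=None,
) -> VulnerabilityReport:
    """Vulnerability report on the raw bounds, before any FVA."""
    report = VulnerabilityReport(
        chokepoints=chokepoints(model, epsilon, include_boundary=include_boundary),
        dead_end_metabolites=dead_end_metabolites(
            model, epsilon, include_boundary=include_boundary
        ),
        essential=essential_reactions(model, solver, epsilon, optima=optima),
        blocked=blocked_reactions(model, solver, epsilon),
        partition=classify_reactions(model, epsilon),
        gamma=None,
        level="flux",
    )
    report.validate()
    return report


def remove_dead_end_metabolites(
    model: ConstraintBasedModel, epsilon: float = EPS, include_boundary: bool = False
) -> ConstraintBasedModel:
    """Iteratively delete structural dead-end metabolites until a fixpoint.

    A reaction that loses an entire (originally non-empty) reactant or
    product side to a deletion can no longer carry steady-state flux; it
    is deactivated — kept in the reaction set for comparability, but
    flagged in ``orphan_reactions``, clamped to zero flux, and ignored
    when looking for further dead ends.  Deactivation is what lets one
    removal expose the next, so passes repeat until none remain.
    """
    S = model.stoichiometry.toarray()
    present = np.ones(model.n_metabolites, dtype=bool)
    active = np.ones(model.n_reactions, dtype=bool)
    had_reactants = (S < 0).any(axis=0)
    had_products = (S > 0).any(axis=0)
    considered = np.ones(model.n_metabolites, dtype=bool)
    if not include_boundary:
        for i, m in enumerate(model.metabolites):
            if m in model.boundary_metabolites:
                considered[i] = False

    while True:
        sub = S[np.ix_(present, active)] if active.any() else S[present][:, :0]
        consumed = (sub < 0).any(axis=1)
        produced = (sub > 0).any(axis=1)
        rows = np.flatnonzero(present)
        dem_rows = [
            r
            for r, c, p in zip(rows, consumed, produced)
            if considered[r] and (not c or not p)
        ]
        if not dem_rows:
            break
        present[dem_rows] = False
        for j in np.flatnonzero(active):
            col = S[present, j]
            if (had_reactants[j] and not (col < 0).any()) or (
                had_products[j] and not (col > 0).any()
            ):
                active[j] = False

    keep = np.flatnonzero(present)
    removed = {model.metabolites[i] for i in np.flatnonzero(~present)}
    orphans = frozenset(model.reactions[j] for j in np.flatnonzero(~active))
    lower = model.lower_bounds.copy()
    upper = model.upper_bounds.copy()
    lower[~active] = 0.0
    upper[~active] = 0.0
    return replace(
        model,
        metabolites=tuple(model.metabolites[i] for i in keep),
        stoichiometry=sparse.csc_matrix(S[keep, :]),
        lower_bounds=lower,
        upper_bounds=upper,
        boundary_metabolites=model.boundary_metabolites - removed,
        orphan_reactions=model.orphan_reactions | orphans,
    )
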