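"""Synthetic test networks and an independent brute-force oracle.

``make_fixture`` builds small, feasible-by-construction networks (exchange
inputs feeding parallel pathways into a biomass reaction) with optional
planted dead-end metabolites, dead reactions and reversible links.
``brute_force_sets`` recomputes every vulnerability set by literal
evaluation of the definitions with a second LP backend, so the main code
path can be checked set-for-set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .model import DEFAULT_BOUND, EPS, ConstraintBasedModel
from .lp import GrowthContext, get_backend
from .sets import ReactionPartition, VulnerabilityReport

__all__ = ["FixtureSpec", "FixtureError", "make_fixture", "figure_like_nets",
           "brute_force_sets", "build_model"]


class FixtureError(ValueError):
    """The requested fixture cannot be constructed."""


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for the random network generator."""

    n_metabolites: int = 8
    n_reactions: int = 10
    reversible_fraction: float = 0.0
    n_parallel_paths: int = 1
    include_dem: bool = False
    include_dead: bool = False
    seed: int = 0
    path_capacities: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_metabolites < 1 or self.n_reactions < 1:
            raise FixtureError("need at least one metabolite and one reaction")
        if not 0.0 <= self.reversible_fraction <= 1.0:
            raise FixtureError("reversible_fraction must lie in [0, 1]")
        if self.n_parallel_paths < 1:
            raise FixtureError("need at least one pathway")
        if self.path_capacities is not None and len(self.path_capacities) != self.n_parallel_paths:
            raise FixtureError("one capacity per parallel path is required")


def build_model(
    reactions: dict[str, tuple[dict[str, float], float, float]],
    objective: str | None = None,
    boundary: set[str] | frozenset[str] = frozenset(),
    name: str = "",
) -> ConstraintBasedModel:
    """Assemble a model from ``{rid: (stoich_by_metabolite, lb, ub)}``.

    Negative stoichiometric entries are reactants, positive are products;
    metabolites appear in first-mention order.
    """
    metabolites: list[str] = []
    seen: set[str] = set()
    for stoich, _, _ in reactions.values():
        for m in stoich:
            if m not in seen:
                seen.add(m)
                metabolites.append(m)
    met_index = {m: i for i, m in enumerate(metabolites)}
    rids = list(reactions)
    rows, cols, data = [], [], []
    lower, upper = [], []
    for j, rid in enumerate(rids):
        stoich, lo, hi = reactions[rid]
        lower.append(lo)
        upper.append(hi)
        for m, v in stoich.items():
            rows.append(met_index[m])
            cols.append(j)
            data.append(float(v))
    S = sparse.coo_matrix(
        (data, (rows, cols)), shape=(len(metabolites), len(rids))
    ).tocsc()
    return ConstraintBasedModel(
        reactions=tuple(rids),
        metabolites=tuple(metabolites),
        stoichiometry=S,
        lower_bounds=np.array(lower, dtype=float),
        upper_bounds=np.array(upper, dtype=float),
        objective_reaction=objective,
        boundary_metabolites=frozenset(boundary),
        name=name,
    )


def make_fixture(spec: FixtureSpec) -> ConstraintBasedModel:
    """Deterministic random network per ``spec``.

    Layout: per parallel path an exchange input of some capacity followed
    by a chain of unit conversions ending in the shared biomass precursor;
    the biomass reaction drains the precursor.  Extra reaction budget is
    spent on chain length and on export sinks for random chain metabolites.
    The maximum growth rate equals the sum of the path capacities.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_parallel_paths
    fixed = 2 * k + 1 + int(spec.include_dem) + int(spec.include_dead)
    if spec.n_reactions < fixed:
        raise FixtureError(
            f"spec needs at least {fixed} reactions "
            f"({k} paths plus biomass and planted structures)"
        )
    if spec.path_capacities is not None:
        capacities = [float(c) for c in spec.path_capacities]
    else:
        capacities = [float(rng.integers(1, 6)) for _ in range(k)]

    spare = spec.n_reactions - fixed
    met_budget = max(spec.n_metabolites - (k + 1), 0)
    extra_chain = [0] * k
    for _ in range(spare):
        if sum(extra_chain) >= met_budget:
            break
        extra_chain[int(rng.integers(0, k))] += 1
    n_sinks = spare - sum(extra_chain)

    reactions: dict[str, tuple[dict[str, float], float, float]] = {}
    chain_mets: list[str] = []
    for p in range(k):
        head = f"m_p{p}_0"
        chain_mets.append(head)
        reactions[f"ex_{p}"] = ({head: 1.0}, 0.0, capacities[p])
        prev = head
        for s in range(extra_chain[p]):
            nxt = f"m_p{p}_{s + 1}"
            chain_mets.append(nxt)
            reactions[f"r_p{p}_{s}"] = ({prev: -1.0, nxt: 1.0}, 0.0, DEFAULT_BOUND)
            prev = nxt
        reactions[f"r_p{p}_bio"] = ({prev: -1.0, "m_bio": 1.0}, 0.0, DEFAULT_BOUND)
    reactions["r_growth"] = ({"m_bio": -1.0}, 0.0, DEFAULT_BOUND)

    for s in range(n_sinks):
        src = chain_mets[int(rng.integers(0, len(chain_mets)))]
        reactions[f"r_sink_{s}"] = ({src: -1.0}, 0.0, DEFAULT_BOUND)

    if spec.include_dem:
        src = chain_mets[int(rng.integers(0, len(chain_mets)))]
        reactions["r_dem"] = ({src: -1.0, "m_dem": 1.0}, 0.0, DEFAULT_BOUND)
    if spec.include_dead:
        src = chain_mets[int(rng.integers(0, len(chain_mets)))]
        reactions["r_dead"] = ({src: -1.0, "m_bio": 1.0}, 0.0, 0.0)

    # reversible internal conversions keep feasibility: backward flux is
    # optional, and forward capacity is unchanged
    for rid, (stoich, lo, hi) in list(reactions.items()):
        if rid.startswith("r_p") and not rid.endswith("_bio"):
            if rng.random() < spec.reversible_fraction:
                reactions[rid] = (stoich, -DEFAULT_BOUND, hi)

    return build_model(reactions, objective="r_growth", name=f"fixture_seed{spec.seed}")


def figure_like_nets() -> tuple[ConstraintBasedModel, ConstraintBasedModel]:
    """Two hand-built nets exercising the documented corner behaviours.

    ``net1`` (10 reactions, 7 metabolites): a mandatory branch (r1, r2)
    and an optimal branch (r3, r4) into biomass, a capacity-limited detour
    (r5, r7, r8) that keeps r3/r4 dispensable-but-optimal, and a
    produced-never-consumed metabolite mg.

    ``net2`` (8 reactions, 5 metabolites): reversible r3/r4, a dead r7, a
    dead-end metabolite md, and a lossy alternative route that dies at
    full growth, turning r4 into the sole consumer of ma and sole
    producer of mc.
    """
    net1 = build_model(
        {
            "r1": ({"ma": 1.0}, 0.0, 10.0),
            "r2": ({"ma": -1.0, "mb": 1.0}, 0.0, DEFAULT_BOUND),
            "r3": ({"md": 1.0}, 0.0, 10.0),
            "r4": ({"md": -1.0, "mc": 1.0}, 0.0, DEFAULT_BOUND),
            "r5": ({"me": 1.0}, 0.0, 3.0),
            "r7": ({"me": -1.0, "mf": 2.0}, 0.0, DEFAULT_BOUND),
            "r8": ({"mf": -2.0, "mc": 1.0}, 0.0, DEFAULT_BOUND),
            "r6": ({"mf": -1.0}, 0.0, DEFAULT_BOUND),
            "r9": ({"mf": -1.0, "mg": 1.0}, 0.0, DEFAULT_BOUND),
            "rg": ({"mb": -1.0, "mc": -1.0}, 0.0, DEFAULT_BOUND),
        },
        objective="rg",
        name="net1",
    )
    net2 = build_model(
        {
            "r1": ({"ma": 1.0}, 0.0, 10.0),
            "r2": ({"ma": -1.0, "mb": 1.0}, 0.0, DEFAULT_BOUND),
            "r3": ({"mb": -1.0, "me": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND),
            "r4": ({"ma": -1.0, "mc": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND),
            "r5": ({"me": -2.0, "mc": 1.0}, 0.0, DEFAULT_BOUND),
            "r6": ({"md": -1.0}, 0.0, DEFAULT_BOUND),
            "r7": ({"mc": -1.0, "me": 1.0}, 0.0, 0.0),
            "rg": ({"mc": -1.0}, 0.0, DEFAULT_BOUND),
        },
        objective="rg",
        name="net2",
    )
    return net1, net2


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

_ORACLE_MAX_REACTIONS = 20


def _oracle_lp(model, lb, ub, j, maximize, solver):
    """One LP with explicit bound overrides; no problem reuse on purpose."""
    import dataclasses

    patched = dataclasses.replace(
        model, lower_bounds=np.asarray(lb, float), upper_bounds=np.asarray(ub, float)
    )
    be = get_backend(patched, solver)
    return be.solve(j, maximize=maximize)


def brute_force_sets(
    model: ConstraintBasedModel,
    gamma: float,
    solver: str = "scipy",
    epsilon: float = EPS,
    include_boundary: bool = False,
) -> VulnerabilityReport:
    """Literal re-derivation of every vulnerability set at one gamma.

    Star-sets are evaluated by scanning all (metabolite, reaction) pairs,
    FVA and essentiality by one fresh LP per subproblem.  Intentionally
    naive; refuses models above 20 reactions.
    """
    if model.n_reactions > _ORACLE_MAX_REACTIONS:
        raise FixtureError(
            f"oracle is limited to {_ORACLE_MAX_REACTIONS} reactions, "
            f"model has {model.n_reactions}"
        )
    L = model.lower_bounds.copy()
    U = model.upper_bounds.copy()
    S = model.stoichiometry.toarray()
    n = model.n_reactions

    g = model.reaction_index(model.objective_reaction) if model.objective_reaction else None

    mu_max = 0.0
    if g is not None:
        res = _oracle_lp(model, L, U, g, True, solver)
        if res.optimal:
            mu_max = max(res.objective_value, 0.0)

    # FVA at gamma: floor as a raised lower bound of the growth reaction
    lbg, ubg = L.copy(), U.copy()
    floorL = L.copy()
    if g is not None and gamma * mu_max > epsilon:
        floorL[g] = max(L[g], gamma * mu_max)
    for j in range(n):
        lo = _oracle_lp(model, floorL, U, j, False, solver)
        hi = _oracle_lp(model, floorL, U, j, True, solver)
        lbg[j] = lo.objective_value if lo.optimal else -np.inf
        ubg[j] = hi.objective_value if hi.optimal else np.inf
        if abs(lbg[j]) < epsilon:
            lbg[j] = 0.0
        if abs(ubg[j]) < epsilon:
            ubg[j] = 0.0
        if lbg[j] > ubg[j]:
            lbg[j] = ubg[j] = 0.5 * (lbg[j] + ubg[j])

    # blocked: FVA with no floor at all
    blocked = set()
    for j in range(n):
        lo = _oracle_lp(model, L, U, j, False, solver)
        hi = _oracle_lp(model, L, U, j, True, solver)
        if (
            lo.optimal
            and hi.optimal
            and abs(lo.objective_value) <= epsilon
            and abs(hi.objective_value) <= epsilon
        ):
            blocked.add(model.reactions[j])

    dead, rev, nonrev = set(), set(), set()
    for j, r in enumerate(model.reactions):
        if abs(lbg[j]) <= epsilon and abs(ubg[j]) <= epsilon:
            dead.add(r)
        elif lbg[j] < -epsilon and ubg[j] > epsilon:
            rev.add(r)
        else:
            nonrev.add(r)

    considered = [
        i
        for i, m in enumerate(model.metabolites)
        if include_boundary or m not in model.boundary_metabolites
    ]
    consumers: dict[int, set[str]] = {}
    producers: dict[int, set[str]] = {}
    for i in considered:
        cons, prod = set(), set()
        for j in range(n):
            fwd = ubg[j] > epsilon
            bwd = lbg[j] < -epsilon
            if (S[i, j] < 0 and fwd) or (S[i, j] > 0 and bwd):
                cons.add(model.reactions[j])
            if (S[i, j] > 0 and fwd) or (S[i, j] < 0 and bwd):
                prod.add(model.reactions[j])
        consumers[i], producers[i] = cons, prod

    cps: set[str] = set()
    dems: set[str] = set()
    for i in considered:
        for group in (consumers[i], producers[i]):
            if len(group) == 1:
                cps.add(next(iter(group)))
            if len(group) == 0:
                dems.add(model.metabolites[i])

    essential: set[str] = set()
    if g is not None:
        for j, r in enumerate(model.reactions):
            koL, koU = L.copy(), U.copy()
            koL[j] = koU[j] = 0.0
            res = _oracle_lp(model, koL, koU, g, True, solver)
            value = max(res.objective_value, 0.0) if res.optimal else None
            if value is None or value < gamma * mu_max * (1.0 - epsilon):
                essential.add(r)

    return VulnerabilityReport(
        chokepoints=frozenset(cps),
        dead_end_metabolites=frozenset(dems),
        essential=frozenset(essential),
        blocked=frozenset(blocked),
        partition=ReactionPartition(frozenset(dead), frozenset(rev), frozenset(nonrev)),
        gamma=gamma,
        level="growth",
    )
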