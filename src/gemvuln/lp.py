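"""Linear-programming primitives.

Four operations are built on a reusable LP backend: maximum growth (flux
balance analysis), single-reaction knockout growth, flux variability
analysis under a growth floor ``gamma * mu_max <= v[r_g]``, and its
``gamma = 0`` specialization used for blocked-reaction detection.

Two interchangeable backends are provided: GLPK (simplex, via optlang;
the default) and HiGHS (via :func:`scipy.optimize.linprog`).  Both solve
``max/min c.v  s.t.  S_int.v = 0,  L <= v <= U`` where ``S_int`` is the
stoichiometric matrix restricted to non-boundary metabolites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .model import EPS, ConstraintBasedModel, FluxBoundsVector, ModelError

__all__ = [
    "LPResult",
    "GrowthContext",
    "SolverError",
    "ModelInfeasibleError",
    "UnboundedGrowthError",
    "SOLVERS",
    "get_backend",
    "max_growth",
    "knockout_growth",
    "knockout_optima",
    "fva",
]

logger = logging.getLogger(__name__)

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class SolverError(RuntimeError):
    """The LP backend returned an unexpected status."""


class ModelInfeasibleError(SolverError):
    """The base model admits no steady-state flux within its bounds."""


class UnboundedGrowthError(SolverError):
    """Growth is unbounded, typically from missing exchange bounds."""


@dataclass(frozen=True)
class LPResult:
    """Outcome of one linear program."""

    status: str
    objective_value: float | None = None
    flux_vector: np.ndarray | None = None

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


@dataclass(frozen=True)
class GrowthContext:
    """Maximum growth rate together with the growth fraction in force."""

    mu_max: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.mu_max < -EPS:
            raise ValueError(f"mu_max must be non-negative, got {self.mu_max}")

    @property
    def growth_floor(self) -> float:
        """The flux floor imposed on the growth reaction during FVA."""
        return self.gamma * max(self.mu_max, 0.0)


class _Backend:
    """Reusable LP over a fixed stoichiometry with mutable variable bounds."""

    def __init__(self, model: ConstraintBasedModel):
        self.model = model
        self._lb = model.lower_bounds.copy()
        self._ub = model.upper_bounds.copy()

    def set_bounds(self, index: int, lb: float, ub: float) -> None:
        self._lb[index] = lb
        self._ub[index] = ub

    def solve(self, objective_index: int, maximize: bool = True,
              want_fluxes: bool = False) -> LPResult:
        raise NotImplementedError


class ScipyBackend(_Backend):
    """HiGHS backend through :func:`scipy.optimize.linprog`."""

    def __init__(self, model: ConstraintBasedModel):
        super().__init__(model)
        rows = model.internal_rows()
        self._A = model.stoichiometry.tocsr()[rows, :] if len(rows) else None

    def solve(self, objective_index, maximize=True, want_fluxes=False):
        from scipy.optimize import linprog

        n = self.model.n_reactions
        c = np.zeros(n)
        c[objective_index] = -1.0 if maximize else 1.0
        kwargs = {}
        if self._A is not None:
            kwargs["A_eq"] = self._A
            kwargs["b_eq"] = np.zeros(self._A.shape[0])
        res = linprog(
            c,
            bounds=np.column_stack([self._lb, self._ub]),
            method="highs",
            **kwargs,
        )
        if res.status == 0:
            value = -res.fun if maximize else res.fun
            return LPResult(OPTIMAL, value, res.x if want_fluxes else None)
        if res.status == 2:
            return LPResult(INFEASIBLE)
        if res.status == 3:
            return LPResult(UNBOUNDED)
        raise SolverError(f"HiGHS returned status {res.status}: {res.message}")


class GlpkBackend(_Backend):
    """GLPK simplex backend through optlang; the problem is built once."""

    def __init__(self, model: ConstraintBasedModel):
        super().__init__(model)
        from optlang import glpk_interface as glpk
        from optlang.symbolics import Zero

        self._glpk = glpk
        self._vars = [
            glpk.Variable(f"v{i}", lb=self._finite(self._lb[i]),
                          ub=self._finite(self._ub[i]))
            for i in range(model.n_reactions)
        ]
        self._om = glpk.Model(name="gemvuln")
        self._om.add(self._vars)
        rows = model.internal_rows()
        S = model.stoichiometry.tocsr()
        constraints = []
        coeff_maps = []
        for i in rows:
            row = S.getrow(i).tocoo()
            if row.nnz == 0:
                continue
            constraints.append(glpk.Constraint(Zero, lb=0.0, ub=0.0, name=f"m{i}"))
            coeff_maps.append({self._vars[j]: float(v) for j, v in zip(row.col, row.data)})
        self._om.add(constraints)
        self._om.update()
        for con, coeffs in zip(constraints, coeff_maps):
            con.set_linear_coefficients(coeffs)
        self._om.objective = glpk.Objective(Zero, direction="max")
        self._obj_index: int | None = None

    @staticmethod
    def _finite(value: float) -> float | None:
        # GLPK treats a literal +/-inf double bound as a number; optlang
        # expects None for a free bound
        return float(value) if math.isfinite(value) else None

    def set_bounds(self, index, lb, ub):
        super().set_bounds(index, lb, ub)
        v = self._vars[index]
        lo, hi = self._finite(lb), self._finite(ub)
        # set in an order that never leaves lb > ub transiently
        if lo is not None and lo > (v.ub if v.ub is not None else math.inf):
            v.ub = hi
            v.lb = lo
        else:
            v.lb = lo
            v.ub = hi

    def solve(self, objective_index, maximize=True, want_fluxes=False):
        coeffs = {}
        if self._obj_index is not None and self._obj_index != objective_index:
            coeffs[self._vars[self._obj_index]] = 0.0
        coeffs[self._vars[objective_index]] = 1.0
        self._om.objective.set_linear_coefficients(coeffs)
        self._om.objective.direction = "max" if maximize else "min"
        self._obj_index = objective_index
        status = self._om.optimize()
        if status == "optimal" and not math.isfinite(self._om.objective.value):
            status = "unbounded"
        if status == "optimal":
            fluxes = None
            if want_fluxes:
                fluxes = np.array([v.primal for v in self._vars])
            return LPResult(OPTIMAL, float(self._om.objective.value), fluxes)
        if status == "infeasible":
            return LPResult(INFEASIBLE)
        if status in ("unbounded", "infeasible_or_unbounded"):
            return LPResult(UNBOUNDED)
        raise SolverError(f"GLPK returned status {status!r}")


SOLVERS = {"glpk": GlpkBackend, "scipy": ScipyBackend}


def get_backend(model: ConstraintBasedModel, solver: str = "glpk") -> _Backend:
    """Construct an LP backend over ``model``; ``solver`` is a SOLVERS key."""
    try:
        cls = SOLVERS[solver]
    except KeyError:
        raise SolverError(
            f"unknown solver {solver!r}; choose from {sorted(SOLVERS)}"
        ) from None
    return cls(model)


def _objective_index(model: ConstraintBasedModel) -> int:
    if model.objective_reaction is None:
        raise ModelError("model has no growth objective reaction")
    return model.reaction_index(model.objective_reaction)


def max_growth(
    model: ConstraintBasedModel,
    gamma: float = 1.0,
    solver: str = "glpk",
    backend: _Backend | None = None,
) -> GrowthContext:
    """Maximum growth rate by FBA on the growth reaction.

    Raises :class:`ModelInfeasibleError` if the bounds admit no steady
    state and :class:`UnboundedGrowthError` if growth is unbounded.
    """
    g = _objective_index(model)
    be = backend or get_backend(model, solver)
    res = be.solve(g, maximize=True)
    if res.status == INFEASIBLE:
        raise ModelInfeasibleError(
            "base model is infeasible: no steady-state flux satisfies the bounds"
        )
    if res.status == UNBOUNDED:
        raise UnboundedGrowthError(
            f"growth via {model.objective_reaction!r} is unbounded; "
            "check exchange bounds"
        )
    mu = max(res.objective_value, 0.0)
    if mu < EPS:
        mu = 0.0
    return GrowthContext(mu_max=mu, gamma=gamma)


def knockout_growth(
    model: ConstraintBasedModel,
    reaction_id: str,
    solver: str = "glpk",
    backend: _Backend | None = None,
) -> LPResult:
    """Maximum growth with the flux of one reaction pinned to zero.

    Infeasibility is reported through the result status rather than an
    exception, since essentiality screening counts infeasible knockouts.
    """
    g = _objective_index(model)
    j = model.reaction_index(reaction_id)
    be = backend or get_backend(model, solver)
    lb, ub = be._lb[j], be._ub[j]
    be.set_bounds(j, 0.0, 0.0)
    try:
        res = be.solve(g, maximize=True)
    finally:
        be.set_bounds(j, lb, ub)
    if res.status == UNBOUNDED:
        raise UnboundedGrowthError("knockout LP is unbounded; check exchange bounds")
    return res


def knockout_optima(
    model: ConstraintBasedModel,
    solver: str = "glpk",
    backend: _Backend | None = None,
) -> dict[str, LPResult]:
    """Knockout growth optimum for every reaction, reusing one backend."""
    be = backend or get_backend(model, solver)
    return {r: knockout_growth(model, r, backend=be) for r in model.reactions}


def fva(
    model: ConstraintBasedModel,
    ctx: GrowthContext | None = None,
    solver: str = "glpk",
    epsilon: float = EPS,
    backend: _Backend | None = None,
) -> FluxBoundsVector:
    """Flux variability analysis under an optional growth floor.

    For each reaction the minimum and maximum steady-state flux is
    computed subject to the model bounds and, when ``ctx`` carries a
    positive floor, to ``gamma * mu_max <= v[r_g]``.  Since the floor acts
    on a single variable it is imposed by raising the lower bound of the
    growth reaction.  Resulting values within ``epsilon`` of zero are
    snapped to exactly zero.
    """
    be = backend or get_backend(model, solver)
    floor_restore = None
    if ctx is not None and ctx.growth_floor > epsilon:
        g = _objective_index(model)
        floor_restore = (g, be._lb[g], be._ub[g])
        be.set_bounds(g, max(be._lb[g], ctx.growth_floor), be._ub[g])

    n = model.n_reactions
    lower = np.empty(n)
    upper = np.empty(n)
    try:
        for j in range(n):
            for maximize, target in ((False, lower), (True, upper)):
                res = be.solve(j, maximize=maximize)
                if res.status == OPTIMAL:
                    target[j] = res.objective_value
                elif res.status == UNBOUNDED:
                    target[j] = math.inf if maximize else -math.inf
                else:
                    raise ModelInfeasibleError(
                        f"FVA subproblem for {model.reactions[j]!r} is infeasible"
                    )
    finally:
        if floor_restore is not None:
            be.set_bounds(*floor_restore)

    lower[np.abs(lower) < epsilon] = 0.0
    upper[np.abs(upper) < epsilon] = 0.0
    # solver noise can cross the pair by a hair; never report lower > upper
    crossed = lower > upper
    if np.any(crossed):
        mid = 0.5 * (lower[crossed] + upper[crossed])
        lower[crossed] = mid
        upper[crossed] = mid
    return FluxBoundsVector(lower, upper, gamma=None if ctx is None else ctx.gamma)
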