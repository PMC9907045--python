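"""Constraint-based model container and SBML input/output.

A constraint-based model is the tuple of reactions, metabolites, a sparse
stoichiometric matrix and per-reaction flux bounds, together with the
identity of the growth (biomass) reaction.  Boundary metabolites (SBML
``boundaryCondition="true"``) are carried along but excluded from the
steady-state constraint and, by default, from producer/consumer analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

__all__ = [
    "DEFAULT_BOUND",
    "EPS",
    "ModelError",
    "SBMLReadError",
    "ConstraintBasedModel",
    "FluxBoundsVector",
    "read_sbml",
    "write_sbml",
    "apply_bounds",
    "structural_producers",
    "structural_consumers",
]

logger = logging.getLogger(__name__)

#: Default flux bound magnitude used when an SBML file omits bounds
#: (mmol per gDW per hour).
DEFAULT_BOUND = 1000.0

#: Default zero tolerance for flux and bound comparisons.
EPS = 1e-6


class ModelError(ValueError):
    """A model violates a structural contract (bounds, identifiers, ...)."""


class SBMLReadError(ModelError):
    """The SBML document could not be parsed or validated."""


@dataclass(frozen=True)
class FluxBoundsVector:
    """Per-reaction lower/upper flux bound pair.

    ``gamma`` records the growth fraction used if the bounds were derived
    by flux variability analysis, ``None`` for bounds as read from a file.
    """

    lower: np.ndarray
    upper: np.ndarray
    gamma: float | None = None

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape:
            raise ModelError("lower/upper bound vectors differ in length")
        if np.any(lower > upper + EPS):
            bad = int(np.argmax(lower - upper))
            raise ModelError(
                f"lower bound exceeds upper bound at position {bad}: "
                f"{lower[bad]} > {upper[bad]}"
            )

    def __len__(self) -> int:
        return self.lower.shape[0]


@dataclass
class ConstraintBasedModel:
    """Reactions, metabolites, stoichiometry and flux bounds.

    The stoichiometric matrix has one row per metabolite and one column per
    reaction; negative entries are consumed, positive entries produced.
    """

    reactions: tuple[str, ...]
    metabolites: tuple[str, ...]
    stoichiometry: sparse.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    objective_reaction: str | None = None
    boundary_metabolites: frozenset[str] = frozenset()
    orphan_reactions: frozenset[str] = frozenset()
    name: str = ""
    _rxn_index: dict[str, int] = field(init=False, repr=False, compare=False)
    _met_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.reactions = tuple(self.reactions)
        self.metabolites = tuple(self.metabolites)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float).copy()
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float).copy()
        self.boundary_metabolites = frozenset(self.boundary_metabolites)
        self.orphan_reactions = frozenset(self.orphan_reactions)
        self.stoichiometry = sparse.csc_matrix(self.stoichiometry, dtype=float)

        n_r, n_m = len(self.reactions), len(self.metabolites)
        if len(set(self.reactions)) != n_r:
            raise ModelError("reaction identifiers are not unique")
        if len(set(self.metabolites)) != n_m:
            raise ModelError("metabolite identifiers are not unique")
        if self.stoichiometry.shape != (n_m, n_r):
            raise ModelError(
                f"stoichiometry shape {self.stoichiometry.shape} does not "
                f"match ({n_m} metabolites, {n_r} reactions)"
            )
        if self.lower_bounds.shape != (n_r,) or self.upper_bounds.shape != (n_r,):
            raise ModelError("bound vector length does not match reaction count")
        if np.any(self.lower_bounds > self.upper_bounds + EPS):
            bad = self.reactions[int(np.argmax(self.lower_bounds - self.upper_bounds))]
            raise ModelError(f"lower bound exceeds upper bound for reaction {bad!r}")

        self._rxn_index = {r: i for i, r in enumerate(self.reactions)}
        self._met_index = {m: i for i, m in enumerate(self.metabolites)}

        if self.objective_reaction is not None:
            g = self.reaction_index(self.objective_reaction)
            if self.lower_bounds[g] < 0.0:
                logger.warning(
                    "negative lower bound %g on growth reaction %r clamped to 0",
                    self.lower_bounds[g],
                    self.objective_reaction,
                )
                self.lower_bounds[g] = 0.0
                if self.upper_bounds[g] < 0.0:
                    self.upper_bounds[g] = 0.0

        empty = np.flatnonzero(np.diff(self.stoichiometry.indptr) == 0)
        for j in empty:
            if self.reactions[j] not in self.orphan_reactions:
                logger.debug(
                    "reaction %r has an all-zero stoichiometry column",
                    self.reactions[j],
                )

    # -- lookups ---------------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self._met_index[metabolite_id]
        except KeyError:
            raise KeyError(f"unknown metabolite {metabolite_id!r}") from None

    @property
    def internal_metabolites(self) -> tuple[str, ...]:
        return tuple(m for m in self.metabolites if m not in self.boundary_metabolites)

    def internal_rows(self) -> np.ndarray:
        """Indices of rows that take part in the steady-state constraint."""
        return np.array(
            [i for i, m in enumerate(self.metabolites) if m not in self.boundary_metabolites],
            dtype=int,
        )

    @property
    def bounds(self) -> FluxBoundsVector:
        return FluxBoundsVector(self.lower_bounds.copy(), self.upper_bounds.copy())

    def copy(self) -> "ConstraintBasedModel":
        return replace(self)


def apply_bounds(
    model: ConstraintBasedModel, bounds: FluxBoundsVector
) -> ConstraintBasedModel:
    """Return a copy of ``model`` with flux bounds replaced by ``bounds``.

    The input model is left untouched; a dimension mismatch raises
    :class:`ModelError`.
    """
    if len(bounds) != model.n_reactions:
        raise ModelError(
            f"bounds vector has length {len(bounds)}, model has "
            f"{model.n_reactions} reactions"
        )
    return replace(
        model,
        lower_bounds=np.asarray(bounds.lower, dtype=float).copy(),
        upper_bounds=np.asarray(bounds.upper, dtype=float).copy(),
    )


def structural_producers(model: ConstraintBasedModel, metabolite_id: str) -> set[str]:
    """Reactions with a positive stoichiometric entry for the metabolite."""
    i = model.metabolite_index(metabolite_id)
    row = model.stoichiometry.getrow(i).tocoo()
    return {model.reactions[j] for j, v in zip(row.col, row.data) if v > 0}


def structural_consumers(model: ConstraintBasedModel, metabolite_id: str) -> set[str]:
    """Reactions with a negative stoichiometric entry for the metabolite."""
    i = model.metabolite_index(metabolite_id)
    row = model.stoichiometry.getrow(i).tocoo()
    return {model.reactions[j] for j, v in zip(row.col, row.data) if v < 0}


# ---------------------------------------------------------------------------
# SBML input/output (libsbml-backed)
# ---------------------------------------------------------------------------


def _reaction_bounds(sbml_model, reaction) -> tuple[float, float]:
    """Bounds for one SBML reaction: fbc, then kinetic-law, then defaults."""
    import libsbml

    fbc = reaction.getPlugin("fbc")
    if fbc is not None:
        lo_id = fbc.getLowerFluxBound() if fbc.isSetLowerFluxBound() else None
        hi_id = fbc.getUpperFluxBound() if fbc.isSetUpperFluxBound() else None
        if lo_id or hi_id:
            lo = hi = None
            if lo_id:
                p = sbml_model.getParameter(lo_id)
                lo = p.getValue() if p is not None else None
            if hi_id:
                p = sbml_model.getParameter(hi_id)
                hi = p.getValue() if p is not None else None
            if lo is None:
                lo = -DEFAULT_BOUND if reaction.getReversible() else 0.0
            if hi is None:
                hi = DEFAULT_BOUND
            return float(lo), float(hi)

    kl = reaction.getKineticLaw()
    if kl is not None:
        lo = hi = None
        for getter in (kl.getParameter, getattr(kl, "getLocalParameter", None)):
            if getter is None:
                continue
            p = getter("LOWER_BOUND")
            if p is not None and lo is None:
                lo = p.getValue()
            p = getter("UPPER_BOUND")
            if p is not None and hi is None:
                hi = p.getValue()
        if lo is not None or hi is not None:
            if lo is None:
                lo = -DEFAULT_BOUND if reaction.getReversible() else 0.0
            if hi is None:
                hi = DEFAULT_BOUND
            return float(lo), float(hi)

    if reaction.getReversible():
        return -DEFAULT_BOUND, DEFAULT_BOUND
    return 0.0, DEFAULT_BOUND


def _active_objective(sbml_model, reaction_ids: set[str]) -> str | None:
    """Growth reaction from the active fbc objective, if any."""
    mfbc = sbml_model.getPlugin("fbc")
    if mfbc is None:
        return None
    objective = mfbc.getActiveObjective()
    if objective is None and mfbc.getNumObjectives() > 0:
        objective = mfbc.getObjective(0)
    if objective is None:
        return None
    nonzero = [
        fo.getReaction()
        for fo in objective.getListOfFluxObjectives()
        if fo.getCoefficient() != 0.0 and fo.getReaction() in reaction_ids
    ]
    if not nonzero:
        return None
    if len(set(nonzero)) > 1:
        raise ModelError(
            "active objective has several nonzero coefficients "
            f"({sorted(set(nonzero))}); pass an explicit objective reaction"
        )
    return nonzero[0]


def read_sbml(path, objective: str | None = None) -> ConstraintBasedModel:
    """Read an SBML Level 1/2/3 model into a :class:`ConstraintBasedModel`.

    Flux bounds come from the fbc package (Level 3), from kinetic-law
    parameters named ``LOWER_BOUND``/``UPPER_BOUND`` (Level 2 convention),
    or default to ``(-1000, 1000)`` for reversible and ``(0, 1000)`` for
    irreversible reactions.  ``objective`` overrides the fbc active
    objective.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_FATAL) or doc.getNumErrors(
        libsbml.LIBSBML_SEV_ERROR
    ):
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        if err is None:
            err = doc.getError(0)
        raise SBMLReadError(f"SBML parse failure in {path}: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLReadError(f"{path} contains no SBML model")

    metabolites: list[str] = []
    boundary: set[str] = set()
    for sp in sbml_model.getListOfSpecies():
        sid = sp.getId()
        metabolites.append(sid)
        if sp.getBoundaryCondition():
            boundary.add(sid)
    met_index = {m: i for i, m in enumerate(metabolites)}

    reactions: list[str] = []
    lower: list[float] = []
    upper: list[float] = []
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []

    for j in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(j)
        reactions.append(rxn.getId())
        lo, hi = _reaction_bounds(sbml_model, rxn)
        lower.append(lo)
        upper.append(hi)
        for ref, sign in ((rxn.getListOfReactants(), -1.0), (rxn.getListOfProducts(), 1.0)):
            for sr in ref:
                st = sr.getStoichiometry()
                if st != st:  # NaN: unset stoichiometry defaults to 1
                    st = 1.0
                denom = getattr(sr, "getDenominator", lambda: 1)()
                if denom not in (0, 1):
                    st = st / denom
                rows.append(met_index[sr.getSpecies()])
                cols.append(j)
                data.append(sign * st)

    stoich = sparse.coo_matrix(
        (data, (rows, cols)), shape=(len(metabolites), len(reactions))
    ).tocsc()
    stoich.sum_duplicates()

    obj = objective if objective is not None else _active_objective(sbml_model, set(reactions))
    if objective is not None and objective not in set(reactions):
        raise ModelError(f"objective reaction {objective!r} not in model")

    return ConstraintBasedModel(
        reactions=tuple(reactions),
        metabolites=tuple(metabolites),
        stoichiometry=stoich,
        lower_bounds=np.array(lower),
        upper_bounds=np.array(upper),
        objective_reaction=obj,
        boundary_metabolites=frozenset(boundary),
        name=sbml_model.getId() or "",
    )


def write_sbml(model: ConstraintBasedModel, path) -> None:
    """Write the model as SBML Level 3 with fbc v2 bounds and objective."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.name or "model")
    mfbc = sm.getPlugin("fbc")
    mfbc.setStrict(True)

    comp = sm.createCompartment()
    comp.setId("c")
    comp.setConstant(True)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(m)
        sp.setCompartment("c")
        sp.setBoundaryCondition(m in model.boundary_metabolites)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    bound_params: dict[float, str] = {}

    def _param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    S = model.stoichiometry.tocsc()
    for j, rid in enumerate(model.reactions):
        rxn = sm.createReaction()
        rxn.setId(rid)
        rxn.setFast(False)
        rxn.setReversible(bool(model.lower_bounds[j] < 0))
        col = S.getcol(j).tocoo()
        for i, v in zip(col.row, col.data):
            ref = rxn.createReactant() if v < 0 else rxn.createProduct()
            ref.setSpecies(model.metabolites[i])
            ref.setStoichiometry(abs(float(v)))
            ref.setConstant(True)
        rfbc = rxn.getPlugin("fbc")
        rfbc.setLowerFluxBound(_param(model.lower_bounds[j]))
        rfbc.setUpperFluxBound(_param(model.upper_bounds[j]))

    if model.objective_reaction is not None:
        objective = mfbc.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        fo = objective.createFluxObjective()
        fo.setReaction(model.objective_reaction)
        fo.setCoefficient(1.0)
        mfbc.setActiveObjectiveId("obj")

    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise OSError(f"could not write SBML to {path}")
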