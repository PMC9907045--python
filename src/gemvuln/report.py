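"""Gamma-sweep driver and export of results to spreadsheet/TSV/HTML."""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import EPS, ConstraintBasedModel, apply_bounds
from .lp import GrowthContext, fva, get_backend, knockout_optima, max_growth
from .sets import (
    VulnerabilityReport,
    blocked_reactions,
    chokepoints,
    classify_reactions,
    dead_end_metabolites,
    essential_reactions,
    growth_dependent_essential,
)

__all__ = ["DEFAULT_GAMMAS", "GammaSweepResult", "run_sweep", "export_report"]

logger = logging.getLogger(__name__)

DEFAULT_GAMMAS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99, 1.0)

#: Order of the set columns in summaries.
_SET_KEYS = ("NR", "RR", "CP", "DR", "ER", "DEM", "flexible")


@dataclass
class GammaSweepResult:
    """Set memberships across a grid of growth fractions.

    ``baseline`` holds the pre-FVA (raw bound) sets; ``per_gamma`` one
    mapping per grid value with keys NR, RR, CP, DR, ER, DEM and
    ``flexible`` (reactions neither essential nor dead).  Sizes are always
    derived from the memberships.
    """

    gammas: tuple[float, ...]
    reactions: tuple[str, ...]
    mu_max: float
    baseline: dict[str, frozenset[str]]
    per_gamma: list[dict[str, frozenset[str]]] = field(default_factory=list)

    def sizes(self) -> pd.DataFrame:
        rows = []
        for label, sets in itertools.chain(
            [("baseline", self.baseline)], zip(self.gammas, self.per_gamma)
        ):
            row = {"gamma": label}
            row.update({k: len(sets[k]) for k in _SET_KEYS if k in sets})
            rows.append(row)
        return pd.DataFrame(rows)

    def memberships(self) -> pd.DataFrame:
        records = []
        for label, sets in itertools.chain(
            [("baseline", self.baseline)], zip(self.gammas, self.per_gamma)
        ):
            for key in _SET_KEYS:
                for member in sorted(sets.get(key, ())):
                    records.append({"gamma": label, "set": key, "member": member})
        return pd.DataFrame(records, columns=["gamma", "set", "member"])


def _flexible(reactions, essential, dead) -> frozenset[str]:
    return frozenset(reactions) - (essential | dead)


def run_sweep(
    model: ConstraintBasedModel,
    gammas=DEFAULT_GAMMAS,
    solver: str = "glpk",
    epsilon: float = EPS,
    include_boundary: bool = False,
) -> GammaSweepResult:
    """Baseline sets plus growth-dependent sets at every grid value.

    Knockout LPs are solved once and reused for every gamma threshold;
    each grid value costs one FVA plus the classification passes.
    """
    gammas = tuple(float(g) for g in gammas)
    if not gammas:
        raise ValueError("gamma grid must not be empty")
    if any(g < 0.0 or g > 1.0 for g in gammas):
        raise ValueError("gamma values must lie in [0, 1]")

    backend = get_backend(model, solver)
    ctx = max_growth(model, backend=backend)
    if ctx.mu_max == 0.0:
        logger.warning("mu_max is zero; every gamma behaves like gamma = 0")
    optima = knockout_optima(model, backend=backend)

    part = classify_reactions(model, epsilon)
    er = essential_reactions(model, epsilon=epsilon, optima=optima)
    baseline = {
        "NR": part.non_reversible,
        "RR": part.reversible,
        "CP": chokepoints(model, epsilon, include_boundary=include_boundary),
        "DR": part.dead,
        "ER": er,
        "DEM": dead_end_metabolites(model, epsilon, include_boundary=include_boundary),
        "flexible": _flexible(model.reactions, er, part.dead),
    }

    result = GammaSweepResult(
        gammas=gammas,
        reactions=model.reactions,
        mu_max=ctx.mu_max,
        baseline=baseline,
    )
    for gamma in gammas:
        t0 = time.perf_counter()
        gctx = GrowthContext(mu_max=ctx.mu_max, gamma=gamma)
        bounds = fva(model, gctx, epsilon=epsilon, backend=backend)
        constrained = apply_bounds(model, bounds)
        gpart = classify_reactions(constrained, epsilon)
        ger = growth_dependent_essential(model, gctx, optima=optima)
        result.per_gamma.append(
            {
                "NR": gpart.non_reversible,
                "RR": gpart.reversible,
                "CP": chokepoints(constrained, epsilon, include_boundary=include_boundary),
                "DR": gpart.dead,
                "ER": ger,
                "DEM": dead_end_metabolites(
                    constrained, epsilon, include_boundary=include_boundary
                ),
                "flexible": _flexible(model.reactions, ger, gpart.dead),
            }
        )
        logger.info("gamma=%.3f analyzed in %.2fs", gamma, time.perf_counter() - t0)
    return result


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def _intersections(result: GammaSweepResult) -> pd.DataFrame:
    pairs = [("CP", "ER"), ("CP", "DR"), ("ER", "DR"), ("CP", "flexible")]
    rows = []
    for label, sets in itertools.chain(
        [("baseline", result.baseline)], zip(result.gammas, result.per_gamma)
    ):
        row = {"gamma": label}
        for a, b in pairs:
            row[f"{a}&{b}"] = len(sets[a] & sets[b])
        rows.append(row)
    return pd.DataFrame(rows)


def export_report(
    result: GammaSweepResult,
    out_dir,
    formats=("xlsx", "html"),
    report: VulnerabilityReport | None = None,
) -> list[Path]:
    """Write the sweep as spreadsheet and/or TSV and/or standalone HTML.

    The spreadsheet holds a summary sheet of sizes plus one sheet per set
    per gamma; the TSV flavour writes ``summary.tsv`` and a long-format
    ``memberships.tsv``; the HTML file repeats both views and a set
    intersection table.  Returns the created paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary = result.sizes()
    memberships = result.memberships()

    if "xlsx" in formats:
        path = out_dir / "vulnerability_report.xlsx"
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            summary.to_excel(xl, sheet_name="summary", index=False)
            _intersections(result).to_excel(xl, sheet_name="intersections", index=False)
            for label, sets in itertools.chain(
                [("base", result.baseline)], zip(result.gammas, result.per_gamma)
            ):
                tag = label if isinstance(label, str) else f"g{label:g}"
                for key in _SET_KEYS:
                    name = f"{key}_{tag}"[:31]
                    pd.DataFrame({key: sorted(sets[key])}).to_excel(
                        xl, sheet_name=name, index=False
                    )
        written.append(path)

    if "tsv" in formats:
        p1 = out_dir / "summary.tsv"
        p2 = out_dir / "memberships.tsv"
        summary.to_csv(p1, sep="\t", index=False)
        memberships.to_csv(p2, sep="\t", index=False)
        written.extend([p1, p2])

    if "html" in formats:
        path = out_dir / "vulnerability_report.html"
        parts = [
            "<!DOCTYPE html><html><head><meta charset='utf-8'>",
            "<title>Vulnerability report</title>",
            "<style>body{font-family:sans-serif;margin:2em;}table{border-collapse:"
            "collapse;}td,th{border:1px solid #999;padding:2px 8px;}</style>",
            "</head><body>",
            "<h1>Vulnerability report</h1>",
            f"<p>{len(result.reactions)} reactions; maximum growth rate "
            f"{result.mu_max:g}.</p>",
            "<h2>Set sizes</h2>",
            summary.to_html(index=False),
            "<h2>Set intersections</h2>",
            _intersections(result).to_html(index=False),
            "<h2>Memberships</h2>",
            memberships.to_html(index=False),
            "</body></html>",
        ]
        path.write_text("\n".join(parts))
        written.append(path)

    return written
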