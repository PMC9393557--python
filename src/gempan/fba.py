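"""Flux balance analysis.

FBA maximizes the flux through an objective reaction (biomass) subject to
steady state S @ v = 0 and per-reaction flux bounds; medium composition
enters through the lower bounds of exchange reactions. The linear program
is solved behind a small ``solve_lp`` contract so the backend can be
swapped; the default is scipy's HiGHS interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .model import Model

__all__ = ["FBAResult", "FBAUnboundedError", "solve_fba", "solve_lp", "GROWTH_EPSILON"]

# zero-growth threshold on the objective (h^-1); "growth above zero" is
# numerically unusable verbatim
GROWTH_EPSILON = 1e-6


class FBAUnboundedError(RuntimeError):
    pass


@dataclass
class FBAResult:
    status: str  # "optimal" | "infeasible"
    objective_value: float = 0.0
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def grows(self) -> bool:
        return self.status == "optimal" and self.objective_value > GROWTH_EPSILON


def solve_lp(
    c: np.ndarray,
    A_eq: Optional[np.ndarray],
    b_eq: Optional[np.ndarray],
    bounds: Sequence[Tuple[Optional[float], Optional[float]]],
    maximize: bool = True,
) -> Tuple[str, float, Optional[np.ndarray]]:
    """Solve max/min c @ x s.t. A_eq x = b_eq, bounds. Returns
    (status, objective, x) with status in {optimal, infeasible, unbounded}.
    """
    sign = -1.0 if maximize else 1.0
    res = linprog(sign * c, A_eq=A_eq, b_eq=b_eq, bounds=list(bounds), method="highs")
    if res.status == 0:
        return "optimal", sign * res.fun, res.x
    if res.status == 2:
        return "infeasible", 0.0, None
    if res.status == 3:
        return "unbounded", 0.0, None
    raise RuntimeError(f"LP solver failure: {res.message}")  # pragma: no cover


def _apply_media(model: Model, media: Mapping[str, float]):
    """Effective per-reaction bounds: media overrides exchange lower bounds;
    exchanges absent from the media get lower bound 0 (no uptake)."""
    exchange_ids = {r.id for r in model.exchanges}
    unknown = set(media) - exchange_ids
    if unknown:
        raise KeyError(
            f"media entries are not exchange reactions of model {model.id!r}: {sorted(unknown)}"
        )
    bounds = []
    for rxn in model.reactions.values():
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if rxn.id in exchange_ids:
            lb = float(media.get(rxn.id, 0.0))
        bounds.append((lb, ub))
    return bounds


def solve_fba(model: Model, media: Mapping[str, float]) -> FBAResult:
    """Maximize the objective flux on the given medium.

    Raises :class:`FBAUnboundedError` when the LP is unbounded (typically an
    exchange left open at -inf/+inf both ways - audit the bounds).
    """
    if not model.objective:
        raise ValueError(f"model {model.id!r} has no objective reaction")
    S, _met_ids, rxn_ids = model.stoichiometric_matrix()
    bounds = _apply_media(model, media)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(model.objective)] = 1.0
    status, obj, x = solve_lp(c, S, np.zeros(S.shape[0]), bounds, maximize=True)
    if status == "unbounded":
        raise FBAUnboundedError(
            f"FBA objective unbounded for model {model.id!r}: audit exchange bounds "
            "(an exchange open at -inf/+inf in both directions?)"
        )
    if status == "infeasible":
        return FBAResult(status="infeasible")
    fluxes = {rid: float(v) for rid, v in zip(rxn_ids, x)}
    return FBAResult(status="optimal", objective_value=float(obj), fluxes=fluxes)
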