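"""Sole-source nutrient screening by FBA.

Each condition asks whether a candidate compound can serve as a strain's
sole source of one element class (carbon, nitrogen, phosphorus or sulfur):
starting from M9, the class's default source (glucose / ammonium /
phosphate / sulfate) is removed (lower bound 0) and the candidate's
exchange is opened at the class uptake bound (carbon -20, N/P/S -1000,
mirroring the default-source magnitudes). Growth above the threshold
epsilon classifies the condition as growth-supporting for that strain; the
strains x conditions binary matrix feeds the downstream clustering and PCA.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd

from .fba import GROWTH_EPSILON, FBAUnboundedError, solve_fba
from .media import CLASS_BOUNDS, DEFAULT_SOURCES, MediaDefinition, m9_base
from .model import Model

__all__ = [
    "NutrientCondition",
    "GrowthMatrix",
    "sole_source_media",
    "screen",
    "growth_support_summary",
    "read_conditions_tsv",
    "write_conditions_tsv",
]

ELEMENT_CLASSES = ("carbon", "nitrogen", "phosphorus", "sulfur")


@dataclass(frozen=True)
class NutrientCondition:
    """A sole-source growth condition: test `exchange_id` as the only
    `element_class` source. `bound` defaults to the class uptake bound."""

    element_class: str
    exchange_id: str
    bound: Optional[float] = None
    condition_id: str = ""

    def __post_init__(self):
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class {self.element_class!r}")
        if self.bound is not None and self.bound >= 0:
            raise ValueError(f"candidate uptake bound must be negative, got {self.bound}")
        if not self.condition_id:
            object.__setattr__(
                self, "condition_id", f"{self.element_class[0].upper()}:{self.exchange_id}"
            )

    @property
    def candidate_lb(self) -> float:
        return self.bound if self.bound is not None else CLASS_BOUNDS[self.element_class]


@dataclass
class GrowthMatrix:
    """Strains x conditions growth rates and binary calls (rate > epsilon)."""

    rates: pd.DataFrame
    calls: pd.DataFrame
    epsilon: float
    statuses: pd.DataFrame  # "optimal" | "infeasible" | error description

    @property
    def shape(self):
        return self.calls.shape


def sole_source_media(base: MediaDefinition, condition: NutrientCondition) -> MediaDefinition:
    """Swap the element class's default source for the candidate compound.

    Only the class default is zeroed and the candidate opened; ions,
    cobalamin, O2 and the other classes' defaults are untouched.
    """
    default_ex = DEFAULT_SOURCES[condition.element_class]
    for other_class, other_default in DEFAULT_SOURCES.items():
        if other_class != condition.element_class and condition.exchange_id == other_default:
            raise ValueError(
                f"ambiguous condition: candidate {condition.exchange_id} is the "
                f"default {other_class} source but is declared as {condition.element_class}"
            )
    changes = {default_ex: 0.0, condition.exchange_id: condition.candidate_lb}
    return MediaDefinition(
        {**dict(base), **changes},
        name=f"{base.name}|{condition.condition_id}",
    )


def screen(
    models: Mapping[str, Model] | Iterable[Model],
    conditions: Sequence[NutrientCondition],
    base_media: Optional[Mapping[str, MediaDefinition]] = None,
    epsilon: float = GROWTH_EPSILON,
) -> GrowthMatrix:
    """FBA every model on every sole-source condition.

    `base_media` may supply a per-strain base medium; by default M9 +
    glucose is built from each model. A candidate exchange missing from a
    model, or any solver failure, is recorded as no-growth with a flagged
    status, never silently dropped.
    """
    if not isinstance(models, Mapping):
        models = {m.id: m for m in models}
    if not models or not conditions:
        raise ValueError("need at least one model and one condition")
    cond_ids = [c.condition_id for c in conditions]
    if len(set(cond_ids)) != len(cond_ids):
        raise ValueError("condition ids are not unique")
    strains = list(models)
    rates = pd.DataFrame(0.0, index=strains, columns=cond_ids)
    statuses = pd.DataFrame("optimal", index=strains, columns=cond_ids, dtype=object)
    for sid in strains:
        model = models[sid]
        base = base_media[sid] if base_media else m9_base(model)
        exchange_ids = {r.id for r in model.exchanges}
        for cond in conditions:
            if cond.exchange_id not in exchange_ids:
                statuses.loc[sid, cond.condition_id] = "missing_exchange"
                continue
            media = sole_source_media(base, cond)
            media = MediaDefinition(
                {k: v for k, v in media.items() if k in exchange_ids}, media.name
            )
            try:
                res = solve_fba(model, media)
            except FBAUnboundedError as exc:
                statuses.loc[sid, cond.condition_id] = f"error: {exc}"
                continue
            if res.status != "optimal":
                statuses.loc[sid, cond.condition_id] = res.status
                continue
            rates.loc[sid, cond.condition_id] = res.objective_value
    calls = (rates > epsilon).astype(int)
    calls[statuses != "optimal"] = 0
    rates.index.name = calls.index.name = statuses.index.name = "strain"
    return GrowthMatrix(rates=rates, calls=calls, epsilon=epsilon, statuses=statuses)


def growth_support_summary(matrix: GrowthMatrix) -> pd.DataFrame:
    """Per-condition fraction of strains growing and a coarse classification:
    universal (all strains), variable, rare (<= 10% of strains), none."""
    if matrix.calls.empty:
        raise ValueError("empty growth matrix")
    frac = matrix.calls.mean(axis=0)

    def classify(f: float) -> str:
        if f == 1.0:
            return "universal"
        if f == 0.0:
            return "none"
        if f <= 0.1:
            return "rare"
        return "variable"

    out = pd.DataFrame(
        {
            "fraction_growing": frac,
            "n_growing": matrix.calls.sum(axis=0),
            "classification": frac.map(classify),
        }
    )
    out.index.name = "condition"
    return out


# -- condition list TSV ----------------------------------------------------

def read_conditions_tsv(path) -> List[NutrientCondition]:
    """Columns: condition_id, element_class, exchange_id, bound (optional)."""
    out: List[NutrientCondition] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            bound = row.get("bound", "")
            out.append(
                NutrientCondition(
                    element_class=row["element_class"],
                    exchange_id=row["exchange_id"],
                    bound=float(bound) if bound not in ("", None) else None,
                    condition_id=row.get("condition_id", "") or "",
                )
            )
    return out


def write_conditions_tsv(conditions: Sequence[NutrientCondition], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["condition_id", "element_class", "exchange_id", "bound"])
        for c in conditions:
            writer.writerow(
                [c.condition_id, c.element_class, c.exchange_id,
                 "" if c.bound is None else c.bound]
            )
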