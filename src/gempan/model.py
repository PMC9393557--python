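"""Constraint-based metabolic model data structures and JSON I/O.

A :class:`Model` holds reactions (stoichiometry, flux bounds, GPR rule,
subsystem), metabolites and genes, an objective reaction (normally biomass)
and derives the stoichiometric matrix S on demand. The on-disk format is a
BiGG-style model JSON dialect: top-level lists ``reactions``,
``metabolites`` and ``genes``; each reaction carries ``id``, ``name``,
``metabolites`` (signed coefficients, negative = consumed), ``lower_bound``,
``upper_bound``, ``gene_reaction_rule``, ``subsystem`` and an
``objective_coefficient`` marking the objective.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

from .gpr import Gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "Model",
    "ModelValidationError",
    "read_model",
    "write_model",
    "DEFAULT_REVERSIBLE_BOUNDS",
    "DEFAULT_IRREVERSIBLE_BOUNDS",
]

# defaults when a file or constructor omits bounds (mmol gDW^-1 h^-1)
DEFAULT_REVERSIBLE_BOUNDS = (-1000.0, 1000.0)
DEFAULT_IRREVERSIBLE_BOUNDS = (0.0, 1000.0)

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: Optional[Dict[str, int]] = None
    charge: Optional[int] = None

    def formula_string(self) -> str:
        if not self.formula:
            return ""
        # Hill order: C, H, then alphabetical
        keys = sorted(self.formula, key=lambda e: (e != "C", e != "H", e))
        return "".join(f"{k}{self.formula[k] if self.formula[k] != 1 else ''}" for k in keys)

    @staticmethod
    def parse_formula(s: str) -> Optional[Dict[str, int]]:
        if not s:
            return None
        out: Dict[str, int] = {}
        for elem, count in _FORMULA_RE.findall(s):
            if elem:
                out[elem] = out.get(elem, 0) + (int(count) if count else 1)
        return out or None


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = DEFAULT_REVERSIBLE_BOUNDS[0]
    upper_bound: float = DEFAULT_REVERSIBLE_BOUNDS[1]
    gpr: Gpr = field(default_factory=Gpr.empty)
    name: str = ""
    subsystem: str = ""

    def __post_init__(self):
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        """Boundary pseudo-reaction: one extracellular metabolite, coefficient -1
        (negative flux = uptake)."""
        if len(self.stoichiometry) != 1:
            return False
        (met, coeff), = self.stoichiometry.items()
        return coeff == -1 and met.endswith("_e")

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


class Model:
    """A strain-specific (or universal) metabolic network.

    Reactions and metabolites keep insertion order; equality compares
    content, not order.
    """

    def __init__(
        self,
        id: str,
        reactions: Iterable[Reaction],
        metabolites: Iterable[Metabolite] = (),
        genes: Optional[Iterable[str]] = None,
        objective: str = "",
        biomass_reaction_id: str = "",
        compartments: Optional[Mapping[str, str]] = None,
    ):
        self.id = id
        self.reactions: Dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.id in self.reactions:
                raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
            self.reactions[rxn.id] = rxn
        self.metabolites: Dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
            self.metabolites[met.id] = met
        self._auto_register_metabolites()
        self.genes: set = set(genes) if genes is not None else self._gpr_genes()
        self.objective = objective or biomass_reaction_id
        self.biomass_reaction_id = biomass_reaction_id or self.objective
        self.compartments = dict(compartments) if compartments else self._infer_compartments()
        self.validate()

    # -- bookkeeping -------------------------------------------------------
    def _auto_register_metabolites(self):
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    comp = met_id.rsplit("_", 1)[-1] if "_" in met_id else ""
                    self.metabolites[met_id] = Metabolite(id=met_id, compartment=comp)

    def _gpr_genes(self) -> set:
        out = set()
        for rxn in self.reactions.values():
            out |= rxn.gpr.genes()
        return out

    def _infer_compartments(self) -> Dict[str, str]:
        comps = {m.compartment for m in self.metabolites.values() if m.compartment}
        names = {"c": "cytosol", "e": "extracellular", "p": "periplasm"}
        return {c: names.get(c, c) for c in sorted(comps)}

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                    )
            missing = rxn.gpr.genes() - self.genes
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} GPR uses genes not in model: {sorted(missing)}"
                )
        for met in self.metabolites.values():
            if met.compartment and met.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {met.id!r} in undeclared compartment {met.compartment!r}"
                )
        if self.objective and self.objective not in self.reactions:
            raise ModelValidationError(f"objective reaction {self.objective!r} not in model")
        if self.biomass_reaction_id and self.biomass_reaction_id not in self.reactions:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )

    # -- views -------------------------------------------------------------
    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def stoichiometric_matrix(self) -> Tuple[np.ndarray, List[str], List[str]]:
        """Dense S (metabolites x reactions); steady state is S @ v == 0."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met_id, coeff in self.reactions[rid].stoichiometry.items():
                S[met_index[met_id], j] = coeff
        return S, met_ids, rxn_ids

    # -- pure editing ------------------------------------------------------
    def copy(self) -> "Model":
        return Model(
            self.id,
            list(self.reactions.values()),
            list(self.metabolites.values()),
            set(self.genes),
            objective=self.objective,
            biomass_reaction_id=self.biomass_reaction_id,
            compartments=self.compartments,
        )

    def delete_reactions(self, ids: Iterable[str]) -> "Model":
        ids = list(ids)
        for rid in ids:
            if rid not in self.reactions:
                raise KeyError(f"cannot delete unknown reaction {rid!r}")
            if rid == self.objective or rid == self.biomass_reaction_id:
                raise ModelValidationError(
                    f"cannot delete {rid!r}: the objective must remain resolvable"
                )
        drop = set(ids)
        kept = [r for r in self.reactions.values() if r.id not in drop]
        used = {m for r in kept for m in r.stoichiometry}
        mets = [m for m in self.metabolites.values() if m.id in used]
        genes = set().union(*(r.gpr.genes() for r in kept)) if kept else set()
        return Model(
            self.id, kept, mets, genes,
            objective=self.objective,
            biomass_reaction_id=self.biomass_reaction_id,
            compartments=self.compartments,
        )

    def add_reactions(self, reactions: Iterable[Reaction]) -> "Model":
        """Add reactions (new metabolites auto-registered, GPR genes adopted)."""
        new = list(reactions)
        for rxn in new:
            if rxn.id in self.reactions:
                raise ModelValidationError(f"reaction {rxn.id!r} already in model")
        genes = set(self.genes)
        for rxn in new:
            genes |= rxn.gpr.genes()
        return Model(
            self.id,
            list(self.reactions.values()) + new,
            list(self.metabolites.values()),
            genes,
            objective=self.objective,
            biomass_reaction_id=self.biomass_reaction_id,
        )

    # -- equality ----------------------------------------------------------
    def content_equal(self, other: "Model") -> bool:
        """Equal up to reaction/metabolite order."""
        return (
            self.id == other.id
            and dict(self.reactions) == dict(other.reactions)
            and dict(self.metabolites) == dict(other.metabolites)
            and self.genes == other.genes
            and self.objective == other.objective
            and self.biomass_reaction_id == other.biomass_reaction_id
        )

    def __repr__(self):  # pragma: no cover
        return (
            f"<Model {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites, {len(self.genes)} genes>"
        )


# -- JSON dialect ----------------------------------------------------------

def model_to_dict(model: Model) -> dict:
    reactions = []
    for rxn in model.reactions.values():
        entry = {
            "id": rxn.id,
            "name": rxn.name,
            "metabolites": {m: rxn.stoichiometry[m] for m in sorted(rxn.stoichiometry)},
            "lower_bound": rxn.lower_bound,
            "upper_bound": rxn.upper_bound,
            "gene_reaction_rule": rxn.gpr.to_string(),
            "subsystem": rxn.subsystem,
            "objective_coefficient": 1.0 if rxn.id == model.objective else 0.0,
        }
        reactions.append(entry)
    metabolites = [
        {
            "id": m.id,
            "name": m.name,
            "compartment": m.compartment,
            "formula": m.formula_string(),
            "charge": m.charge,
        }
        for m in model.metabolites.values()
    ]
    out = {
        "id": model.id,
        "compartments": model.compartments,
        "reactions": reactions,
        "metabolites": metabolites,
        "genes": [{"id": g} for g in sorted(model.genes)],
    }
    if model.biomass_reaction_id != model.objective:
        out["biomass_reaction_id"] = model.biomass_reaction_id
    return out


def model_from_dict(data: dict) -> Model:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", ""),
                formula=Metabolite.parse_formula(m.get("formula") or ""),
                charge=m.get("charge"),
            )
            for m in data.get("metabolites", [])
        ]
        objective = ""
        rxns = []
        for r in data.get("reactions", []):
            rid = r["id"]
            stoich = {str(k): float(v) for k, v in r["metabolites"].items()}
            lb = float(r.get("lower_bound", DEFAULT_REVERSIBLE_BOUNDS[0]))
            ub = float(r.get("upper_bound", DEFAULT_REVERSIBLE_BOUNDS[1]))
            gpr = Gpr.parse(r.get("gene_reaction_rule", ""))
            rxns.append(
                Reaction(
                    id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                    gpr=gpr, name=r.get("name", ""), subsystem=r.get("subsystem", ""),
                )
            )
            if r.get("objective_coefficient"):
                objective = rid
    except KeyError as exc:
        raise ModelValidationError(f"malformed model JSON: missing field {exc}") from exc
    declared = {m.id for m in mets}
    for r in rxns:
        undeclared = set(r.stoichiometry) - declared
        if undeclared:
            raise ModelValidationError(
                f"reaction {r.id!r} references undeclared metabolite(s) "
                f"{sorted(undeclared)}"
            )
    genes = {g["id"] for g in data.get("genes", [])} or None
    return Model(
        data.get("id", ""),
        rxns,
        mets,
        genes,
        objective=objective,
        biomass_reaction_id=data.get("biomass_reaction_id", "") or objective,
        compartments=data.get("compartments") or None,
    )


def read_model(path, format: str = "model-json") -> Model:
    """Read a model from a BiGG-style model JSON file."""
    if format != "model-json":
        raise ValueError(f"unsupported model format {format!r}; use 'model-json'")
    path = Path(path)
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"{path}: not valid JSON ({exc})") from exc
    try:
        return model_from_dict(data)
    except ModelValidationError as exc:
        raise ModelValidationError(f"{path}: {exc}") from exc


def write_model(model: Model, path, format: str = "model-json") -> None:
    """Write a model; write_model then read_model is lossless, and writing a
    just-read model reproduces the canonicalized file byte for byte."""
    if format != "model-json":
        raise ValueError(f"unsupported model format {format!r}; use 'model-json'")
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")
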