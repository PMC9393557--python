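"""Core / accessory / pan analytics over presence-absence matrices.

A presence matrix (strains x features, binary) may hold gene families or
reactions. Core features are present in every strain, the pan set in at
least one; accumulation curves track core and pan sizes as strains are
added in random order, replicated over seeded permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .model import Model

__all__ = [
    "CorePanPartition",
    "AccumulationCurve",
    "core_pan",
    "subsystem_conservation",
    "accumulation_curves",
    "reaction_presence_matrix",
]


@dataclass
class CorePanPartition:
    core: List[str]
    accessory: List[str]
    pan: List[str]
    carrier_counts: pd.Series  # per pan feature, number of strains carrying it
    n_strains: int


@dataclass
class AccumulationCurve:
    """Replicated rarefaction of core and pan sizes.

    ``core`` / ``pan`` are (n_orders x n_strains) arrays; column k-1 is the
    size after the first k strains of each random order.
    """

    core: np.ndarray
    pan: np.ndarray
    n_orders: int

    def summary(self, band: str = "normal") -> pd.DataFrame:
        """Mean trajectory with a 95% band: mean +/- 1.96 sd across
        replicates (``band="normal"``) or 2.5/97.5 percentiles
        (``band="percentile"``)."""
        x = np.arange(1, self.core.shape[1] + 1)
        rows = {}
        for label, arr in (("core", self.core), ("pan", self.pan)):
            mean = arr.mean(axis=0)
            if band == "normal":
                sd = arr.std(axis=0, ddof=1) if self.n_orders > 1 else np.zeros_like(mean)
                lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
            elif band == "percentile":
                lo = np.percentile(arr, 2.5, axis=0)
                hi = np.percentile(arr, 97.5, axis=0)
            else:
                raise ValueError(f"unknown band type {band!r}")
            rows[f"{label}_mean"] = mean
            rows[f"{label}_lo"] = lo
            rows[f"{label}_hi"] = hi
        return pd.DataFrame({"n_strains": x, **rows})

    def to_frame(self) -> pd.DataFrame:
        records = []
        for rep in range(self.n_orders):
            for k in range(self.core.shape[1]):
                records.append(
                    {
                        "replicate": rep,
                        "n_strains": k + 1,
                        "core": int(self.core[rep, k]),
                        "pan": int(self.pan[rep, k]),
                    }
                )
        return pd.DataFrame(records)


def _check_binary(matrix: pd.DataFrame) -> None:
    vals = matrix.to_numpy()
    if vals.size == 0:
        raise ValueError("empty presence matrix")
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("presence matrix entries must be 0/1")


def core_pan(matrix: pd.DataFrame) -> CorePanPartition:
    """Exact core/accessory/pan partition; invariant under row order."""
    _check_binary(matrix)
    counts = matrix.sum(axis=0)
    n = len(matrix.index)
    pan = sorted(counts.index[counts > 0])
    core = sorted(counts.index[counts == n])
    accessory = sorted(set(pan) - set(core))
    return CorePanPartition(
        core=core,
        accessory=accessory,
        pan=pan,
        carrier_counts=counts[pan],
        n_strains=n,
    )


def subsystem_conservation(
    models: Mapping[str, Model] | Iterable[Model], partition: CorePanPartition
) -> pd.DataFrame:
    """Per metabolic subsystem: core reaction count, total (pan) count and
    percent conserved, rounded to the nearest integer. Reactions without a
    subsystem are bucketed as "unassigned"."""
    if not isinstance(models, Mapping):
        models = {m.id: m for m in models}
    subsystem_of: Dict[str, str] = {}
    for model in models.values():
        for rxn in model.reactions.values():
            subsystem_of.setdefault(rxn.id, rxn.subsystem or "unassigned")
    core = set(partition.core)
    rows: Dict[str, Dict[str, int]] = {}
    for rid in partition.pan:
        sub = subsystem_of.get(rid, "unassigned")
        entry = rows.setdefault(sub, {"core_reactions": 0, "total_reactions": 0})
        entry["total_reactions"] += 1
        if rid in core:
            entry["core_reactions"] += 1
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out["percent_conserved"] = (
        100.0 * out["core_reactions"] / out["total_reactions"]
    ).round().astype(int)
    out.index.name = "subsystem"
    return out


def accumulation_curves(
    matrix: pd.DataFrame,
    n_orders: int = 10,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> AccumulationCurve:
    """Core/pan sizes as strains are added in random order, `n_orders`
    independent uniformly random permutations from the seeded generator."""
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    _check_binary(matrix)
    if rng is None:
        rng = np.random.default_rng(seed)
    vals = matrix.to_numpy(dtype=bool)
    n_strains = vals.shape[0]
    core = np.zeros((n_orders, n_strains), dtype=int)
    pan = np.zeros((n_orders, n_strains), dtype=int)
    for rep in range(n_orders):
        order = rng.permutation(n_strains)
        running_core = np.ones(vals.shape[1], dtype=bool)
        running_pan = np.zeros(vals.shape[1], dtype=bool)
        for k, idx in enumerate(order):
            running_core &= vals[idx]
            running_pan |= vals[idx]
            core[rep, k] = int(running_core.sum())
            pan[rep, k] = int(running_pan.sum())
    return AccumulationCurve(core=core, pan=pan, n_orders=n_orders)


def reaction_presence_matrix(models: Mapping[str, Model] | Iterable[Model]) -> pd.DataFrame:
    """Strains x reactions binary matrix from a model collection."""
    if not isinstance(models, Mapping):
        models = {m.id: m for m in models}
    all_rxns = sorted({rid for m in models.values() for rid in m.reactions})
    data = {
        sid: [1 if rid in m.reactions else 0 for rid in all_rxns]
        for sid, m in models.items()
    }
    out = pd.DataFrame.from_dict(data, orient="index", columns=all_rxns)
    out = out.sort_index()
    out.index.name = "strain"
    return out
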