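"""Independent brute-force oracles used to validate the package's optimized
implementations. Everything here is deliberately naive: vertex enumeration
for LPs, full subset enumeration for gap-filling, quadratic scans for best
hits, and step-by-step agglomeration recomputed from the raw distance
matrix."""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from gempan.fba import solve_fba
from gempan.model import Model, Reaction
from gempan.orthology import HitRecord, Proteome, align_pair


# -- LP oracle: enumerate basic feasible solutions -------------------------

def lp_oracle(model: Model, media) -> Tuple[str, float]:
    """Maximize the objective by enumerating every vertex of the flux
    polytope {v : S v = 0, lb <= v <= ub} (finite bounds assumed).
    Returns (status, optimum)."""
    S, _mets, rxn_ids = model.stoichiometric_matrix()
    exchange_ids = {r.id for r in model.exchanges}
    lb, ub = [], []
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        l = float(media.get(rid, 0.0)) if rid in exchange_ids else rxn.lower_bound
        lb.append(l)
        ub.append(rxn.upper_bound)
    lb, ub = np.array(lb), np.array(ub)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(model.objective)] = 1.0

    n = len(rxn_ids)
    r = int(np.linalg.matrix_rank(S)) if S.size else 0
    best: Optional[float] = None
    for free in itertools.combinations(range(n), r):
        Sf = S[:, list(free)]
        if r and np.linalg.matrix_rank(Sf) < r:
            continue
        fixed = [j for j in range(n) if j not in free]
        for assignment in itertools.product((0, 1), repeat=len(fixed)):
            v = np.zeros(n)
            for j, a in zip(fixed, assignment):
                v[j] = ub[j] if a else lb[j]
            if r:
                rhs = -S[:, fixed] @ v[fixed] if fixed else np.zeros(S.shape[0])
                sol, *_ = np.linalg.lstsq(Sf, rhs, rcond=None)
                v[list(free)] = sol
            if np.abs(S @ v).max() > 1e-8 if S.size else False:
                continue
            if (v < lb - 1e-9).any() or (v > ub + 1e-9).any():
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    if best is None:
        return "infeasible", 0.0
    return "optimal", best


# -- gap-fill oracle: exhaustive subset search ------------------------------

def gapfill_oracle(
    draft: Model, universal: Model, media, min_growth: float
) -> Optional[int]:
    """Size of the smallest candidate subset restoring growth, or None if
    even the full universal cannot. Checks every subset, smallest first."""
    from gempan.reconstruction import _grows, _strip_gpr

    candidates = [
        _strip_gpr(r) for r in universal.reactions.values() if r.id not in draft.reactions
    ]
    for k in range(0, len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            ok, _ = _grows(draft, list(combo), media, min_growth)
            if ok:
                return k
    return None


def subset_grows(draft: Model, universal: Model, ids: Sequence[str], media,
                 min_growth: float) -> bool:
    from gempan.reconstruction import _grows, _strip_gpr

    add = [_strip_gpr(universal.reactions[i]) for i in ids]
    ok, _ = _grows(draft, add, media, min_growth)
    return ok


# -- BBH oracle: quadratic scan over all alignments -------------------------

def bbh_oracle(
    ref: Proteome, strain: Proteome, min_identity: float = 70.0,
    min_coverage: float = 70.0,
) -> Dict[str, str]:
    """All-vs-all alignment, then the bidirectional-best rule applied
    literally, without any prescreen or shared selection code."""

    def all_hits(q: Proteome, s: Proteome):
        hits: Dict[str, List[HitRecord]] = {}
        for qg, qseq in q.sequences.items():
            for sg, sseq in s.sequences.items():
                h = align_pair(qseq, sseq, qg, sg)
                if (
                    h.percent_identity >= min_identity
                    and h.query_coverage >= min_coverage
                    and h.subject_coverage >= min_coverage
                ):
                    hits.setdefault(qg, []).append(h)
        return hits

    def pick(hs: List[HitRecord]) -> str:
        top = max(h.score for h in hs)
        return sorted(h.subject_gene for h in hs if h.score == top)[0]

    fwd = {q: pick(hs) for q, hs in all_hits(ref, strain).items()}
    rev = {q: pick(hs) for q, hs in all_hits(strain, ref).items()}
    return {r: s for r, s in fwd.items() if rev.get(s) == r}


# -- agglomeration oracle ---------------------------------------------------

def agglomeration_oracle(labels: List[str], dist: np.ndarray,
                         method: str = "average") -> List[Tuple[tuple, tuple, float]]:
    """Merge order of naive agglomerative clustering, recomputing every
    cluster-pair linkage from the raw matrix at each step. Ties resolved by
    the lexicographically smallest pair of leaf-sorted cluster tuples."""
    idx = {l: i for i, l in enumerate(labels)}
    clusters: List[tuple] = [(l,) for l in labels]
    merges = []

    def linkage(a: tuple, b: tuple) -> float:
        vals = [dist[idx[x], idx[y]] for x in a for y in b]
        if method == "average":
            return sum(vals) / len(vals)
        if method == "single":
            return min(vals)
        return max(vals)

    while len(clusters) > 1:
        options = []
        for a, b in itertools.combinations(clusters, 2):
            options.append((linkage(a, b), tuple(sorted((a, b)))))
        d, (a, b) = min(options)
        merges.append((a, b, d))
        clusters = [c for c in clusters if c not in (a, b)]
        clusters.append(tuple(sorted(a + b)))
    return merges


# -- random small networks for the FBA oracle -------------------------------

def random_network(rng: np.random.Generator) -> Tuple[Model, dict]:
    """A random metabolic network with <= 8 reactions, finite bounds, one
    or two genuine exchange/transport pairs and a demand objective."""
    n_c = int(rng.integers(2, 4))
    c_mets = [f"m{i}_c" for i in range(n_c)]
    n_e = int(rng.integers(1, 3))
    reactions = []
    media = {}
    for i in range(n_e):
        em = f"x{i}_e"
        reactions.append(Reaction(id=f"EX_x{i}_e", stoichiometry={em: -1},
                                  lower_bound=-1000, upper_bound=1000))
        target = c_mets[int(rng.integers(0, n_c))]
        reactions.append(Reaction(id=f"T{i}", stoichiometry={em: -1, target: 1},
                                  lower_bound=0, upper_bound=float(rng.integers(1, 11))))
        media[f"EX_x{i}_e"] = -float(np.round(rng.uniform(0, 5), 3))
    obj_met = c_mets[int(rng.integers(0, n_c))]
    reactions.append(Reaction(id="OBJ", stoichiometry={obj_met: -1},
                              lower_bound=0, upper_bound=float(rng.integers(1, 11))))
    n_internal = int(rng.integers(0, 8 - len(reactions) + 1))
    for k in range(n_internal):
        n_sub = int(rng.integers(1, min(3, n_c) + 1))
        mets = list(rng.choice(c_mets, size=n_sub, replace=False))
        stoich = {m: float(rng.choice([-2, -1, 1, 2])) for m in mets}
        reversible = bool(rng.random() < 0.5)
        lb = -float(rng.integers(1, 11)) if reversible else 0.0
        reactions.append(Reaction(id=f"R{k}", stoichiometry=stoich,
                                  lower_bound=lb, upper_bound=float(rng.integers(1, 11))))
    model = Model(f"net{rng.integers(1e6)}", reactions, objective="OBJ",
                  biomass_reaction_id="OBJ")
    return model, media
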