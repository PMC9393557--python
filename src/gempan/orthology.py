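"""Bidirectional best-hit (BBH) orthology and gene-family clustering.

Orthologs between a reference proteome and a strain proteome are called as
bidirectional best hits: gene pairs that are each other's highest-scoring
match with percent identity and alignment coverage both above a cutoff
(default 70% identity over at least 70% of BOTH protein lengths, the
stricter symmetric reading of "70% over at least 70% of the protein
length").

Alignment is deterministic global Needleman-Wunsch (BLOSUM62, affine gaps
-11/-1). A cheap edit-distance prescreen (edlib) skips pairs whose identity
cannot plausibly reach the cutoff; it is applied with a 10-point safety
margin so it never rejects a pair the full aligner would accept at
realistic divergences.

Gene families for pan-genome analytics are the connected components of the
all-pairs BBH graph (single linkage). This is a deliberately simple
stand-in for dedicated pan-genome family pipelines, adequate when paralogy
is limited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import edlib
import networkx as nx
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "Proteome",
    "HitRecord",
    "OrthologMap",
    "align_pair",
    "best_hits",
    "bidirectional_best_hits",
    "cluster_gene_families",
    "read_fasta_proteome",
    "write_fasta_proteome",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

DEFAULT_MIN_IDENTITY = 70.0
DEFAULT_MIN_COVERAGE = 70.0
_PRESCREEN_MARGIN = 10.0


@dataclass(frozen=True)
class Proteome:
    strain_id: str
    sequences: Mapping[str, str]

    def __post_init__(self):
        if not self.sequences:
            raise ValueError(f"proteome {self.strain_id!r} is empty")
        for gene, seq in self.sequences.items():
            bad = set(seq.upper()) - AA_ALPHABET
            if not seq or bad:
                raise ValueError(
                    f"proteome {self.strain_id!r}, gene {gene!r}: "
                    + ("empty sequence" if not seq else f"non-amino-acid characters {sorted(bad)}")
                )

    def __len__(self):
        return len(self.sequences)


@dataclass(frozen=True)
class HitRecord:
    query_gene: str
    subject_gene: str
    percent_identity: float
    query_coverage: float
    subject_coverage: float
    score: float


@dataclass
class OrthologMap:
    """Reference gene -> strain gene, one-to-one, with per-pair hit records."""

    strain_id: str
    pairs: Dict[str, str] = field(default_factory=dict)
    records: Dict[str, HitRecord] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.pairs.values())) != len(self.pairs):
            raise ValueError("ortholog map is not one-to-one")

    def __len__(self):
        return len(self.pairs)

    def inverse(self) -> Dict[str, str]:
        return {s: r for r, s in self.pairs.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "reference_gene": r,
                "strain_gene": s,
                "percent_identity": self.records[r].percent_identity,
                "query_coverage": self.records[r].query_coverage,
                "subject_coverage": self.records[r].subject_coverage,
                "score": self.records[r].score,
            }
            for r, s in sorted(self.pairs.items())
        ]
        return pd.DataFrame(rows, columns=[
            "reference_gene", "strain_gene", "percent_identity",
            "query_coverage", "subject_coverage", "score",
        ])


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def align_pair(a: str, b: str, query_gene: str = "query", subject_gene: str = "subject") -> HitRecord:
    """Globally align two amino-acid sequences.

    Identity = matches / aligned columns x 100, computed over the region
    between the first and last column where both sequences have a residue
    (terminal gap overhangs do not count as aligned columns). Coverage of
    each protein = its residues inside that region / its length x 100.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    a, b = a.upper(), b.upper()
    aln = _ALIGNER.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    both = [i for i in range(len(row_a)) if row_a[i] != "-" and row_b[i] != "-"]
    if not both:
        return HitRecord(query_gene, subject_gene, 0.0, 0.0, 0.0, float(aln.score))
    lo, hi = both[0], both[-1] + 1
    cols = hi - lo
    matches = sum(1 for i in range(lo, hi) if row_a[i] == row_b[i] and row_a[i] != "-")
    res_a = sum(1 for i in range(lo, hi) if row_a[i] != "-")
    res_b = sum(1 for i in range(lo, hi) if row_b[i] != "-")
    return HitRecord(
        query_gene,
        subject_gene,
        percent_identity=100.0 * matches / cols,
        query_coverage=100.0 * res_a / len(a),
        subject_coverage=100.0 * res_b / len(b),
        score=float(aln.score),
    )


def _prescreen_passes(a: str, b: str, min_identity: float) -> bool:
    """Fast upper bound on achievable identity from the edit distance; the
    margin keeps the screen conservative."""
    d = edlib.align(a, b)["editDistance"]
    longest = max(len(a), len(b))
    upper = 100.0 * (longest - d) / longest
    return upper >= min_identity - _PRESCREEN_MARGIN


def _passes(hit: HitRecord, min_identity: float, min_coverage: float) -> bool:
    return (
        hit.percent_identity >= min_identity
        and hit.query_coverage >= min_coverage
        and hit.subject_coverage >= min_coverage
    )


def _hit_table(
    query: Proteome,
    subject: Proteome,
    min_identity: float,
    min_coverage: float,
    prescreen: bool,
) -> Dict[str, List[HitRecord]]:
    """All query-subject hits passing both cutoffs, per query gene."""
    table: Dict[str, List[HitRecord]] = {}
    for qg, qseq in query.sequences.items():
        for sg, sseq in subject.sequences.items():
            if prescreen and not _prescreen_passes(qseq, sseq, min_identity):
                continue
            hit = align_pair(qseq, sseq, qg, sg)
            if _passes(hit, min_identity, min_coverage):
                table.setdefault(qg, []).append(hit)
    return table


def _best(hits: Sequence[HitRecord]) -> HitRecord:
    # highest score; ties broken by lexicographically smallest subject id
    return min(hits, key=lambda h: (-h.score, h.subject_gene))


def best_hits(
    query: Proteome,
    subject: Proteome,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    prescreen: bool = True,
) -> Dict[str, HitRecord]:
    """Best passing hit in `subject` for each query gene (queries with no
    passing hit are omitted)."""
    table = _hit_table(query, subject, min_identity, min_coverage, prescreen)
    return {qg: _best(hits) for qg, hits in table.items()}


def bidirectional_best_hits(
    ref: Proteome,
    strain: Proteome,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    prescreen: bool = True,
) -> OrthologMap:
    """Ortholog pairs (r, s): s is r's best hit and r is s's best hit.

    The result is a bijection on its domain/range by construction.
    """
    fwd = best_hits(ref, strain, min_identity, min_coverage, prescreen)
    rev = best_hits(strain, ref, min_identity, min_coverage, prescreen)
    pairs: Dict[str, str] = {}
    records: Dict[str, HitRecord] = {}
    for r, hit in fwd.items():
        s = hit.subject_gene
        back = rev.get(s)
        if back is not None and back.subject_gene == r:
            pairs[r] = s
            records[r] = hit
    return OrthologMap(strain_id=strain.strain_id, pairs=pairs, records=records)


def cluster_gene_families(
    proteomes: Iterable[Proteome],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    prescreen: bool = True,
) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Gene families as connected components of the all-pairs BBH graph.

    Returns ``(matrix, representatives)``: a strains x families binary
    presence DataFrame (families named F000001... in order of their
    lexicographically smallest member) and per-family representative
    sequences (that smallest member's sequence). Output is independent of
    the order the proteomes are supplied in.
    """
    prots = sorted(proteomes, key=lambda p: p.strain_id)
    if not prots:
        raise ValueError("need at least one proteome")
    if len({p.strain_id for p in prots}) != len(prots):
        raise ValueError("duplicate strain ids")
    graph = nx.Graph()
    seqs: Dict[Tuple[str, str], str] = {}
    for p in prots:
        for g, s in p.sequences.items():
            graph.add_node((p.strain_id, g))
            seqs[(p.strain_id, g)] = s
    for i in range(len(prots)):
        for j in range(i + 1, len(prots)):
            omap = bidirectional_best_hits(
                prots[i], prots[j], min_identity, min_coverage, prescreen
            )
            for r, s in omap.pairs.items():
                graph.add_edge((prots[i].strain_id, r), (prots[j].strain_id, s))
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(graph)),
        key=lambda members: members[0],
    )
    strains = [p.strain_id for p in prots]
    fam_ids = [f"F{k + 1:06d}" for k in range(len(components))]
    matrix = pd.DataFrame(0, index=strains, columns=fam_ids, dtype=int)
    reps: Dict[str, str] = {}
    for fid, members in zip(fam_ids, components):
        reps[fid] = seqs[members[0]]
        for strain_id, _gene in members:
            matrix.loc[strain_id, fid] = 1
    matrix.index.name = "strain"
    return matrix, reps


# -- FASTA I/O -------------------------------------------------------------

def read_fasta_proteome(path, strain_id: Optional[str] = None) -> Proteome:
    from pathlib import Path

    path = Path(path)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return Proteome(strain_id=strain_id or path.stem, sequences=seqs)


def write_fasta_proteome(proteome: Proteome, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(proteome.sequences):
            fh.write(f">{gene}\n{proteome.sequences[gene]}\n")
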