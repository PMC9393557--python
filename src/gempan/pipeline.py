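"""End-to-end pipeline: reconstruct -> screen -> pan analytics -> statistics.

Stages communicate through plain files (model JSON, TSV matrices) so any
stage can be rerun from upstream serialized outputs; a manifest records
the configuration, package version, seeds and input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .fba import GROWTH_EPSILON
from .media import m9_base
from .model import Model, read_model, write_model
from .orthology import (
    DEFAULT_MIN_COVERAGE,
    DEFAULT_MIN_IDENTITY,
    Proteome,
    cluster_gene_families,
    read_fasta_proteome,
)
from .pan import (
    accumulation_curves,
    core_pan,
    reaction_presence_matrix,
    subsystem_conservation,
)
from .reconstruction import reconstruct_all
from .screen import GrowthMatrix, read_conditions_tsv, screen, growth_support_summary
from .stats import (
    gene_reaction_correlation,
    hierarchical_cluster,
    jaccard_distance,
    pca_project,
)

__all__ = ["PipelineConfig", "run_all", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run. Defaults are the standard
    protocol constants: 70/70 BBH cutoffs, growth threshold 1e-6 h^-1,
    10 random orderings for accumulation curves, average linkage."""

    reference_model: str = ""
    universal_db: str = ""
    reference_proteome: str = ""
    proteome_dir: str = ""
    conditions: str = ""
    outdir: str = "gempan_out"
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_coverage: float = DEFAULT_MIN_COVERAGE
    epsilon: float = GROWTH_EPSILON
    n_orders: int = 10
    seed: int = 0
    linkage: str = "average"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_proteomes(proteome_dir: Path, reference_name: str = "reference") -> List[Proteome]:
    paths = sorted(p for p in proteome_dir.glob("*.faa") if p.stem != reference_name)
    if not paths:
        raise FileNotFoundError(f"no strain proteomes (*.faa) in {proteome_dir}")
    return [read_fasta_proteome(p) for p in paths]


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {},
        "stages": {},
    }
    for key in ("reference_model", "universal_db", "reference_proteome", "conditions"):
        p = Path(getattr(config, key))
        if p.is_file():
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    # -- stage: reconstruct ------------------------------------------------
    try:
        reference = read_model(config.reference_model)
        universal = read_model(config.universal_db)
        ref_prot = read_fasta_proteome(config.reference_proteome)
        proteomes = _load_proteomes(Path(config.proteome_dir))
        media = m9_base(reference)
        models, provenance = reconstruct_all(
            reference,
            universal,
            proteomes,
            media,
            reference_proteome=ref_prot,
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
            min_growth=config.epsilon,
        )
        failed = provenance[provenance["error"] != ""]
        models_dir = outdir / "models"
        models_dir.mkdir(exist_ok=True)
        for sid, model in models.items():
            write_model(model, models_dir / f"{sid}.json")
        provenance.to_csv(outdir / "provenance.tsv", sep="\t", index=False)
        manifest["stages"]["reconstruct"] = {
            "n_strains": len(proteomes),
            "n_models": len(models),
            "n_failed": int(len(failed)),
        }
        if len(failed) == len(proteomes):
            raise PipelineError("reconstruct", "every strain failed; see provenance.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("reconstruct", str(exc)) from exc

    # -- stage: screen -----------------------------------------------------
    try:
        conditions = read_conditions_tsv(config.conditions)
        growth = screen(models, conditions, epsilon=config.epsilon)
        growth.calls.to_csv(outdir / "growth_calls.tsv", sep="\t")
        growth.rates.to_csv(outdir / "growth_rates.tsv", sep="\t")
        summary = growth_support_summary(growth)
        summary.to_csv(outdir / "growth_summary.tsv", sep="\t")
        manifest["stages"]["screen"] = {
            "n_conditions": len(conditions),
            "n_supported": int((summary["fraction_growing"] > 0).sum()),
            "n_universal": int((summary["classification"] == "universal").sum()),
        }
    except Exception as exc:
        raise PipelineError("screen", str(exc)) from exc

    # -- stage: pan --------------------------------------------------------
    try:
        fam_matrix, _reps = cluster_gene_families(
            proteomes, config.min_identity, config.min_coverage
        )
        fam_matrix.to_csv(outdir / "gene_families.tsv", sep="\t")
        rxn_matrix = reaction_presence_matrix(models)
        rxn_matrix.to_csv(outdir / "reaction_presence.tsv", sep="\t")
        gene_part = core_pan(fam_matrix)
        rxn_part = core_pan(rxn_matrix)
        conservation = subsystem_conservation(models, rxn_part)
        conservation.to_csv(outdir / "subsystem_conservation.tsv", sep="\t")
        curves = accumulation_curves(
            fam_matrix, n_orders=config.n_orders, seed=config.seed
        )
        curves.to_frame().to_csv(outdir / "gene_accumulation.tsv", sep="\t", index=False)
        rxn_curves = accumulation_curves(
            rxn_matrix, n_orders=config.n_orders, seed=config.seed
        )
        rxn_curves.to_frame().to_csv(
            outdir / "reaction_accumulation.tsv", sep="\t", index=False
        )
        partition_rows = [
            {"matrix": "gene_families", "core": len(gene_part.core),
             "accessory": len(gene_part.accessory), "pan": len(gene_part.pan)},
            {"matrix": "reactions", "core": len(rxn_part.core),
             "accessory": len(rxn_part.accessory), "pan": len(rxn_part.pan)},
        ]
        pd.DataFrame(partition_rows).to_csv(
            outdir / "core_pan_partition.tsv", sep="\t", index=False
        )
        manifest["stages"]["pan"] = {
            "gene_families": len(gene_part.pan),
            "core_gene_families": len(gene_part.core),
            "pan_reactions": len(rxn_part.pan),
            "core_reactions": len(rxn_part.core),
        }
    except Exception as exc:
        raise PipelineError("pan", str(exc)) from exc

    # -- stage: stats ------------------------------------------------------
    try:
        dist = jaccard_distance(growth.calls)
        dist.to_csv(outdir / "jaccard_distance.tsv", sep="\t")
        dendro = hierarchical_cluster(dist, linkage=config.linkage)
        (outdir / "strain_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        ordered = growth.calls.loc[dendro.leaf_order()]
        ordered.to_csv(outdir / "growth_calls_clustered.tsv", sep="\t")
        pca = pca_project(growth.calls, n_components=2)
        pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        try:
            slope, intercept, r = gene_reaction_correlation(models)
        except ValueError:  # degenerate variance on tiny collections
            slope = intercept = r = float("nan")
        pd.DataFrame(
            [{"slope": slope, "intercept": intercept, "pearson_r": r}]
        ).to_csv(outdir / "gene_reaction_fit.tsv", sep="\t", index=False)
        manifest["stages"]["stats"] = {
            "pca_explained_variance": [float(v) for v in pca.explained_variance_ratio],
            "gene_reaction_pearson_r": r,
        }
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
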