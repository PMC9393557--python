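"""Self-contained synthetic strain collections with planted ground truth.

The generator builds a toy universal metabolic network: a viable core
(glucose uptake, an abstracted glycolysis/respiration energy axis, N/P/S
assimilation, biomass) plus independent catabolic modules, each a short
pathway that converts one candidate nutrient into a core intermediate and
is gated by module-specific genes with mixed AND/OR rules. Strains are
mutated copies of the reference proteome with clade-structured module gain
and loss, so orthology calling, reconstruction, gap-filling and the
sole-source growth screen all have exact, machine-readable expected
outcomes.

Sequences are generated, not biological: uniform random amino-acid strings
with controlled point substitutions targeting a chosen percent identity.
Insertions and deletions are excluded so alignment coverage stays 100% and
identity is the only thresholded axis. One nutrient per module and one
module per nutrient keeps genotype <-> phenotype bijective.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gpr import Gpr
from .media import M9_ION_EXCHANGES
from .model import Metabolite, Model, Reaction, read_model, write_model
from .orthology import Proteome, read_fasta_proteome, write_fasta_proteome
from .screen import NutrientCondition, read_conditions_tsv, write_conditions_tsv

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "ModuleSpec",
    "build_universal_toy",
    "spawn_strains",
    "emit_study",
    "load_study",
]

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

ELEMENT_CYCLE = ("carbon", "nitrogen", "phosphorus", "sulfur")
_MODULE_SUBSYSTEM = {
    "carbon": "Alternate carbon metabolism",
    "nitrogen": "Nitrogen metabolism",
    "phosphorus": "Phosphorus metabolism",
    "sulfur": "Sulfur metabolism",
}

BIOMASS_ID = "BIOMASS"
ORPHAN_EXCHANGE = "EX_orph_e"
AUXOTROPHY_GENE = "gcore_sassim"  # sulfate assimilation: the planted auxotrophy target


@dataclass(frozen=True)
class ModuleSpec:
    """One catabolic module: the nutrient it unlocks and its gating genes."""

    name: str
    element_class: str
    nutrient_exchange: str
    reaction_ids: Tuple[str, ...]
    genes: Tuple[str, ...]


@dataclass
class SyntheticDesign:
    """Study conditions for a synthetic strain collection.

    ``carriage_probs`` is a (n_clades x n_modules) matrix of per-clade
    module carriage probabilities; the default is the noiseless pattern in
    which clade c lacks exactly the modules m with m % n_clades == c, giving
    every clade a distinct module complement and every module a 75% carrier
    fraction (at 4 clades).
    """

    n_strains: int = 24
    n_clades: int = 4
    n_modules: int = 8
    carriage_probs: Optional[np.ndarray] = None
    target_identity: float = 88.0
    n_private_genes: int = 2
    auxotroph_strains: Tuple[int, ...] = (0, 7)
    auxotrophy_gene: str = AUXOTROPHY_GENE
    seed: int = 0
    bbh_identity_cutoff: float = 70.0

    def __post_init__(self):
        if self.carriage_probs is None:
            probs = np.ones((self.n_clades, self.n_modules))
            for c in range(self.n_clades):
                for m in range(self.n_modules):
                    if m % self.n_clades == c:
                        probs[c, m] = 0.0
            self.carriage_probs = probs
        self.carriage_probs = np.asarray(self.carriage_probs, dtype=float)
        if self.carriage_probs.shape != (self.n_clades, self.n_modules):
            raise ValueError("carriage_probs must be (n_clades, n_modules)")
        if ((self.carriage_probs < 0) | (self.carriage_probs > 1)).any():
            raise ValueError("carriage probabilities must lie in [0, 1]")
        if not 0 < self.target_identity <= 100:
            raise ValueError("target identity must be in (0, 100]")

    def clade_of(self, strain_index: int) -> int:
        return strain_index * self.n_clades // self.n_strains

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["carriage_probs"] = self.carriage_probs.tolist()
        d["auxotroph_strains"] = list(self.auxotroph_strains)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticDesign":
        d = dict(d)
        d["carriage_probs"] = np.asarray(d["carriage_probs"], dtype=float)
        d["auxotroph_strains"] = tuple(d["auxotroph_strains"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator decided, for downstream recovery checks."""

    carriage: pd.DataFrame  # strains x modules, 0/1
    expected_growth: pd.DataFrame  # strains x condition ids, 0/1
    clades: pd.Series  # strain -> clade index
    deleted_genes: Dict[str, List[str]]
    modules: List[ModuleSpec]
    conditions: List[NutrientCondition]


# -- universal toy network -------------------------------------------------

def _core_reactions() -> List[Reaction]:
    def rxn(rid, stoich, lb, ub, gpr="", subsystem="", name=""):
        return Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            gpr=Gpr.parse(gpr), subsystem=subsystem, name=name,
        )

    core = [
        rxn("GLCt", {"glc__D_e": -1, "glc__D_c": 1}, 0, 1000, "gcore_glct",
            "Transport", "glucose transport"),
        rxn("GLYC", {"glc__D_c": -1, "cint_c": 2, "nrg_c": 2}, 0, 1000, "gcore_glyc",
            "Glycolysis/gluconeogenesis", "glycolysis (lumped)"),
        rxn("O2t", {"o2_e": -1, "o2_c": 1}, 0, 1000, "", "Transport", "O2 diffusion"),
        rxn("RESP", {"cint_c": -1, "o2_c": -1, "nrg_c": 3, "co2_c": 1}, 0, 1000,
            "gcore_resp", "Oxidative phosphorylation", "respiration (lumped)"),
        rxn("CO2t", {"co2_c": -1, "co2_e": 1}, 0, 1000, "", "Transport", "CO2 venting"),
        rxn("NH4t", {"nh4_e": -1, "nh4_c": 1}, 0, 1000, "gcore_nh4t", "Transport"),
        rxn("NASSIM", {"nh4_c": -1, "cint_c": -1, "nrg_c": -1, "nint_c": 1}, 0, 1000,
            "gcore_nassim", "Nitrogen assimilation"),
        rxn("PIt", {"pi_e": -1, "pi_c": 1}, 0, 1000, "gcore_pit", "Transport"),
        rxn("PASSIM", {"pi_c": -1, "nrg_c": -1, "pint_c": 1}, 0, 1000,
            "gcore_passim", "Phosphorus assimilation"),
        rxn("SO4t", {"so4_e": -1, "so4_c": 1}, 0, 1000, "gcore_so4t", "Transport"),
        rxn("SASSIM", {"so4_c": -1, "cint_c": -1, "nrg_c": -2, "sint_c": 1}, 0, 1000,
            "gcore_sassim", "Sulfur assimilation", "sulfate reduction (lumped)"),
        rxn("CBLt", {"cbl1_e": -1, "cbl1_c": 1}, 0, 1000, "", "Transport",
            "cobalamin uptake"),
        rxn(BIOMASS_ID,
            {"cint_c": -1.0, "nint_c": -0.6, "pint_c": -0.2, "sint_c": -0.1,
             "nrg_c": -2.0, "cbl1_c": -0.0001},
            0, 1000, "", "Biomass", "biomass objective"),
    ]
    return core


def _exchange(met_e: str) -> Reaction:
    return Reaction(
        id=f"EX_{met_e}",
        stoichiometry={met_e: -1},
        lower_bound=-1000.0,
        upper_bound=1000.0,
        gpr=Gpr.empty(),
        subsystem="Exchange",
    )


def _module_reactions(i: int) -> Tuple[ModuleSpec, List[Reaction]]:
    """Module i (0-based): transport + 1-2 catabolic steps feeding the core."""
    element = ELEMENT_CYCLE[i % len(ELEMENT_CYCLE)]
    sub = _MODULE_SUBSYSTEM[element]
    name = f"mod{i + 1}"
    nut_e, nut_c = f"nut{i + 1}_e", f"nut{i + 1}_c"
    ga, gb = f"g_{name}_a", f"g_{name}_b"
    product = {
        "carbon": {"cint_c": 2},
        "nitrogen": {"nh4_c": 1},
        "phosphorus": {"pi_c": 1},
        "sulfur": {"so4_c": 1},
    }[element]
    rxns = [
        Reaction(
            id=f"{name.upper()}t", stoichiometry={nut_e: -1, nut_c: 1},
            lower_bound=0, upper_bound=1000, gpr=Gpr.parse(ga), subsystem=sub,
        )
    ]
    if i % 2 == 0:
        mid = f"mid{i + 1}_c"
        rxns.append(
            Reaction(
                id=f"{name.upper()}cat1", stoichiometry={nut_c: -1, mid: 1},
                lower_bound=0, upper_bound=1000,
                gpr=Gpr.parse(f"{ga} and {gb}"), subsystem=sub,
            )
        )
        rxns.append(
            Reaction(
                id=f"{name.upper()}cat2", stoichiometry={mid: -1, **product},
                lower_bound=0, upper_bound=1000, gpr=Gpr.parse(gb), subsystem=sub,
            )
        )
    else:
        rxns.append(
            Reaction(
                id=f"{name.upper()}cat", stoichiometry={nut_c: -1, **product},
                lower_bound=0, upper_bound=1000,
                gpr=Gpr.parse(f"{ga} or {gb}"), subsystem=sub,
            )
        )
    spec = ModuleSpec(
        name=name,
        element_class=element,
        nutrient_exchange=f"EX_{nut_e}",
        reaction_ids=tuple(r.id for r in rxns),
        genes=(ga, gb),
    )
    return spec, rxns


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA20, size=length))


def build_universal_toy(
    n_modules: int = 8, seed: int = 0
) -> Tuple[Model, Model, Proteome, List[ModuleSpec]]:
    """Universal reaction database, reference model, reference proteome and
    the module catalogue.

    The reference strain carries every module, so universal and reference
    share reaction content; they differ only in identity. Metabolite ids for
    M9 ions are included as exchange-only species so media construction is
    exercised in full.
    """
    if n_modules < 1:
        raise ValueError("need at least one module")
    reactions = _core_reactions()
    modules: List[ModuleSpec] = []
    for i in range(n_modules):
        spec, rxns = _module_reactions(i)
        modules.append(spec)
        reactions.extend(rxns)

    exchanged = ["glc__D_e", "o2_e", "nh4_e", "pi_e", "so4_e", "cbl1_e", "co2_e"]
    exchanged += [f"nut{i + 1}_e" for i in range(n_modules)]
    exchanged += ["orph_e"]  # nutrient with no catabolic route anywhere
    ion_mets = [ex[len("EX_"):] for ex in M9_ION_EXCHANGES]
    exchanged += [m for m in ion_mets if m not in exchanged]
    reactions += [_exchange(m) for m in dict.fromkeys(exchanged)]

    mets = []
    seen = set()
    for r in reactions:
        for mid in r.stoichiometry:
            if mid not in seen:
                seen.add(mid)
                mets.append(Metabolite(id=mid, compartment=mid.rsplit("_", 1)[-1]))

    reference = Model(
        "reference", reactions, mets,
        objective=BIOMASS_ID, biomass_reaction_id=BIOMASS_ID,
    )
    universal = Model(
        "universal", reactions, mets,
        objective=BIOMASS_ID, biomass_reaction_id=BIOMASS_ID,
    )
    # child stream keyed by purpose so other seed-derived streams never
    # replay the same draws (identical substrings would alias gene families)
    rng = np.random.default_rng([seed, 1])
    sequences = {
        gene: _random_protein(rng, int(rng.integers(120, 401)))
        for gene in sorted(reference.genes)
    }
    proteome = Proteome(strain_id="reference", sequences=sequences)
    return universal, reference, proteome, modules


# -- strain spawning -------------------------------------------------------

def _mutate(seq: str, target_identity: float, rng: np.random.Generator) -> str:
    """Point-substitute to the target percent identity (no indels)."""
    n_sub = int(round(len(seq) * (1.0 - target_identity / 100.0)))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        choices = AA20[AA20 != out[pos]]
        out[pos] = rng.choice(choices)
    return "".join(out)


def default_conditions(modules: Sequence[ModuleSpec]) -> List[NutrientCondition]:
    """Glucose control, one condition per module nutrient, and the orphan
    nutrient (exchange present, no catabolic route: a structural all-zero
    column)."""
    conds = [NutrientCondition(element_class="carbon", exchange_id="EX_glc__D_e")]
    conds += [
        NutrientCondition(element_class=m.element_class, exchange_id=m.nutrient_exchange)
        for m in modules
    ]
    conds.append(NutrientCondition(element_class="carbon", exchange_id=ORPHAN_EXCHANGE))
    return conds


def spawn_strains(
    design: SyntheticDesign,
    reference: Model,
    reference_proteome: Proteome,
    modules: Sequence[ModuleSpec],
    allow_low_identity: bool = False,
) -> Tuple[List[Proteome], GroundTruth]:
    """Mutated strain proteomes plus the ground truth of every decision.

    Kept orthologs are mutated to ``design.target_identity``; genes of
    non-carried modules (and planted auxotrophy genes) are removed
    entirely. A target identity at or below the BBH cutoff would break
    planted recovery and is rejected unless ``allow_low_identity`` is set
    (used to study degradation deliberately).
    """
    if design.target_identity <= design.bbh_identity_cutoff and not allow_low_identity:
        raise ValueError(
            f"target identity {design.target_identity} is at or below the BBH cutoff "
            f"{design.bbh_identity_cutoff}; kept orthologs would be missed"
        )
    if design.n_modules != len(modules):
        raise ValueError("design.n_modules does not match the module catalogue")
    rng = np.random.default_rng([design.seed, 2])
    strain_ids = [f"S{j:02d}" for j in range(design.n_strains)]
    module_names = [m.name for m in modules]
    carriage = pd.DataFrame(0, index=strain_ids, columns=module_names, dtype=int)
    clades = pd.Series(
        {sid: design.clade_of(j) for j, sid in enumerate(strain_ids)}, name="clade"
    )
    deleted: Dict[str, List[str]] = {}
    proteomes: List[Proteome] = []
    module_gene_owner = {g: m.name for m in modules for g in m.genes}

    for j, sid in enumerate(strain_ids):
        clade = design.clade_of(j)
        carried = {
            m.name
            for k, m in enumerate(modules)
            if rng.random() < design.carriage_probs[clade, k]
        }
        carriage.loc[sid, sorted(carried)] = 1
        drop_genes = set()
        if j in design.auxotroph_strains:
            drop_genes.add(design.auxotrophy_gene)
        seqs: Dict[str, str] = {}
        for gene in sorted(reference_proteome.sequences):
            owner = module_gene_owner.get(gene)
            if owner is not None and owner not in carried:
                continue
            if gene in drop_genes:
                continue
            seqs[f"{sid}_{gene}"] = _mutate(
                reference_proteome.sequences[gene], design.target_identity, rng
            )
        for k in range(design.n_private_genes):
            seqs[f"{sid}_priv{k + 1}"] = _random_protein(
                rng, int(rng.integers(120, 401))
            )
        deleted[sid] = sorted(drop_genes)
        proteomes.append(Proteome(strain_id=sid, sequences=seqs))

    conditions = default_conditions(modules)
    expected = pd.DataFrame(
        0, index=strain_ids, columns=[c.condition_id for c in conditions], dtype=int
    )
    by_exchange = {m.nutrient_exchange: m.name for m in modules}
    for cond in conditions:
        if cond.exchange_id == "EX_glc__D_e":
            expected[cond.condition_id] = 1  # gap-fill guarantees glucose growth
        elif cond.exchange_id == ORPHAN_EXCHANGE:
            expected[cond.condition_id] = 0
        else:
            expected[cond.condition_id] = carriage[by_exchange[cond.exchange_id]]
    expected.index.name = carriage.index.name = "strain"
    truth = GroundTruth(
        carriage=carriage,
        expected_growth=expected,
        clades=clades,
        deleted_genes=deleted,
        modules=list(modules),
        conditions=conditions,
    )
    return proteomes, truth


# -- study emission --------------------------------------------------------

def emit_study(design: SyntheticDesign, outdir) -> Dict[str, Path]:
    """Write a complete pipeline input set: models, proteomes, condition
    list and ground-truth tables. Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "proteomes").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    universal, reference, ref_prot, modules = build_universal_toy(
        design.n_modules, seed=design.seed
    )
    proteomes, truth = spawn_strains(design, reference, ref_prot, modules)

    paths: Dict[str, Path] = {}

    def _p(key, rel):
        paths[key] = outdir / rel
        return paths[key]

    write_model(universal, _p("universal", "universal.json"))
    write_model(reference, _p("reference", "reference.json"))
    write_fasta_proteome(ref_prot, _p("reference_proteome", "proteomes/reference.faa"))
    for prot in proteomes:
        write_fasta_proteome(prot, outdir / "proteomes" / f"{prot.strain_id}.faa")
    paths["proteome_dir"] = outdir / "proteomes"
    write_conditions_tsv(truth.conditions, _p("conditions", "conditions.tsv"))
    truth.carriage.to_csv(_p("carriage", "truth/carriage.tsv"), sep="\t")
    truth.expected_growth.to_csv(
        _p("expected_growth", "truth/expected_growth.tsv"), sep="\t"
    )
    truth.clades.rename_axis("strain").to_frame().to_csv(
        _p("clades", "truth/clades.tsv"), sep="\t"
    )
    with open(_p("deleted_genes", "truth/deleted_genes.tsv"), "w") as fh:
        fh.write("strain\tdeleted_genes\n")
        for sid in sorted(truth.deleted_genes):
            fh.write(f"{sid}\t{';'.join(truth.deleted_genes[sid])}\n")
    with open(_p("design", "design.json"), "w") as fh:
        json.dump(design.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def load_study(outdir):
    """Re-read an emitted study into in-memory objects.

    Returns (design, universal, reference, reference_proteome, strain
    proteomes, conditions, truth tables dict).
    """
    outdir = Path(outdir)
    with open(outdir / "design.json") as fh:
        design = SyntheticDesign.from_dict(json.load(fh))
    universal = read_model(outdir / "universal.json")
    reference = read_model(outdir / "reference.json")
    ref_prot = read_fasta_proteome(outdir / "proteomes" / "reference.faa")
    proteomes = [
        read_fasta_proteome(p)
        for p in sorted((outdir / "proteomes").glob("S*.faa"))
    ]
    conditions = read_conditions_tsv(outdir / "conditions.tsv")
    truth = {
        "carriage": pd.read_csv(outdir / "truth/carriage.tsv", sep="\t", index_col=0),
        "expected_growth": pd.read_csv(
            outdir / "truth/expected_growth.tsv", sep="\t", index_col=0
        ),
        "clades": pd.read_csv(outdir / "truth/clades.tsv", sep="\t", index_col=0)["clade"],
    }
    return design, universal, reference, ref_prot, proteomes, conditions, truth
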