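# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `gempan`, in the order the pipeline runs them.

## Constraint-based model and FBA

A model is a set of reactions with stoichiometries, flux bounds
(mmol·gDW⁻¹·h⁻¹), boolean GPR rules and subsystem labels. The
stoichiometric matrix S (metabolites × reactions) is derived on demand;
flux balance analysis maximizes the objective (biomass) flux subject to
S·v = 0 and per-reaction bounds. Conventions:

- **Exchanges** are single-metabolite boundary pseudo-reactions written
  `met_e →` with coefficient −1, so negative flux is uptake. A medium is a
  map exchange → lower bound; exchanges absent from the medium get lower
  bound 0 (no uptake). Media never touch upper bounds, so secretion stays
  open.
- **Default bounds** when a file omits them: reversible (−1000, 1000),
  irreversible (0, 1000).
- **Growth threshold** ε = 10⁻⁶ h⁻¹. "Growth above zero" is not usable at
  floating point; ε is far above LP solver noise (HiGHS default
  tolerances, ~10⁻⁹) and far below any real optimum in the toy network
  (~10¹).
- **Solver**: scipy's HiGHS via a minimal `solve_lp(c, A_eq, b_eq, bounds)`
  contract. No solver-specific features are used, so the backend can be
  swapped behind that one function. An unbounded objective raises
  an error advising a bound audit rather than returning infinity.
- Empty GPR ⇒ reaction always active (spontaneous reactions, exchanges and
  biomass need no gene product).

Correctness of the LP layer is checked against an independent brute-force
oracle that enumerates every basic feasible solution (vertex) of the flux
polytope on networks of ≤ 8 reactions with finite bounds.

Model I/O is a BiGG-style model JSON dialect (top-level `reactions`,
`metabolites`, `genes`; reaction fields `id`, `name`, `metabolites`,
`lower_bound`, `upper_bound`, `gene_reaction_rule`, `subsystem`,
`objective_coefficient`). Writing is canonicalized (sorted keys, fixed
indentation) so read → write → read is bit-stable. The files load directly
into COBRApy, which the test suite uses as an independent FBA cross-check.
SBML import is not implemented; model JSON is the single interchange
format.

## Orthology

Ortholog calling follows the bidirectional-best-hit protocol: gene pairs
that are each other's best-scoring hit with percent identity ≥ 70 and
coverage ≥ 70% of the protein length. Choices that the protocol leaves
open, fixed here:

- **Aligner**: deterministic global Needleman–Wunsch (Biopython
  `PairwiseAligner`, BLOSUM62, affine gaps −11/−1). At the scale this
  package targets, exact alignment is affordable and removes heuristic
  search variance. Identity = matches / aligned columns × 100 over the
  region between the first and last column where both sequences have a
  residue; coverage of each protein = its residues in that region / its
  length × 100.
- **Coverage is enforced symmetrically** on both query and subject — the
  stricter of the two possible readings of "70% of the protein length".
- **Tie-break**: equal-scoring hits resolve to the lexicographically
  smallest subject id, for reproducibility.
- **Prescreen**: an edlib edit-distance bound skips pairs whose identity
  cannot plausibly reach the cutoff, applied with a 10-point safety margin
  (a pair is skipped only if even the most generous identity estimate is
  10 points below the threshold). This is a speed filter, never a scorer;
  all reported numbers come from the full aligner.

Gene families are the connected components (single linkage) of the
all-pairs BBH graph. This is a deliberately simple stand-in for dedicated
pan-genome family pipelines; it behaves exactly when paralogy is limited,
as in the synthetic studies, and is not a re-implementation of any
published family pipeline. Family naming and the presence matrix are
invariant to the order in which proteomes are supplied.

## Reconstruction and gap-filling

A strain draft inherits every reference reaction whose GPR evaluates true
over the ortholog-mapped gene set, plus all empty-GPR reactions. Mapped
gene leaves are rewritten to strain gene ids; unmapped leaves are
substituted false and simplified away (an OR drops the false branch, an
AND becomes false and the reaction is dropped). This keeps the model
invariant that every GPR gene exists in the model's gene set, while
producing exactly the same retained-reaction set as leaving unmapped genes
in place as permanently-false leaves. Losing the biomass reaction is an
error: the objective must remain resolvable.

Gap-filling restores growth on a stated medium (M9 + glucose in the
standard pipeline) from a universal reaction database:

1. If the draft already grows (≥ ε), return the empty set.
2. If even draft + full universal cannot grow, fail explicitly, naming the
   medium.
3. Solve an LP relaxation: minimize total absolute flux through candidate
   reactions subject to steady state, bounds, and objective flux ≥ ε. The
   support (candidates carrying flux) is the working pool.
4. If the pool has ≤ 12 members, run an exact cardinality-ascending
   search (all 1-subsets, then 2-subsets, …, in sorted-id order) and
   return the first growing subset — guaranteed minimal cardinality and
   therefore irreducible. For larger pools, greedily prune the support
   (smallest relaxation flux first) until no member can be removed without
   losing growth — guaranteed irreducible, not guaranteed minimal.
5. Added reactions carry no gene association (there is no strain gene
   evidence for them).

The exact/greedy split keeps the algorithm solver-independent (no MILP)
while making minimality a real guarantee on the small universals where it
can be checked; tests compare against an exhaustive subset-enumeration
oracle. Determinism: no randomness anywhere in reconstruction; identical
inputs give identical models.

**Auxotrophy masking.** Gap-filling to a growth guarantee hides real
biosynthetic lesions: a strain missing an assimilation gene gets the
reaction restored without gene support. The synthetic generator plants
such deletions deliberately and the suite asserts the masking happens and
is visible in the provenance log — the caveat is demonstrated, not just
documented.

## M9 medium and the nutrient screen

The M9 base opens 24 exchanges: 18 trace ions at −1000 (Ca²⁺, Cl⁻, CO₂,
Co²⁺, Cu²⁺, Fe²⁺, Fe³⁺, H⁺, H₂O, K⁺, Mg²⁺, Mn²⁺, molybdate, Na⁺, Ni²⁺,
selenate, selenite, Zn²⁺), cob(I)alamin at −0.01, O₂ at −20 (aerobic;
anaerobic screening is out of scope), and the four element-class defaults:
glucose −20 (carbon), NH₄⁺ −1000 (nitrogen), phosphate −1000 (phosphorus),
sulfate −1000 (sulfur). Ions a model does not exchange are warned about
and skipped.

A sole-source condition zeroes exactly one class default and opens the
candidate exchange at the class bound — carbon −20, N/P/S −1000,
mirroring the magnitude of the replaced default. The candidate bound is
configurable per condition (TSV column `bound`); element-class membership
is declared in the condition list, never inferred from formulas, so a
multi-element compound can be tested separately as, say, both a carbon and
a nitrogen source. Only the one default is removed (the literal reading of
the protocol); cobalamin and O₂ stay open in every condition.

The screen records raw growth rates, binary calls (rate > ε) and a
per-cell status; solver failures and missing exchanges are flagged
no-growth, never dropped. The per-condition summary classifies conditions
as universal (all strains grow), variable, rare (≤ 10% grow — a declared
convenience threshold), or none.

## Pan analytics

Core = features carried by all strains; pan = by at least one; accessory =
pan minus core. Accumulation curves add strains in uniformly random order
(sampling without replacement — permutations, not bootstrap), replicated
`n_orders = 10` times from a seeded generator; the 95% band is mean ±
1.96·sd across replicates, with percentile bands as an option. Subsystem
conservation reports per-subsystem core/total counts with percentages
rounded to the nearest integer; unlabelled reactions bucket as
"unassigned".

## Statistics

- **Jaccard distance** d = 1 − |x∧y|/|x∨y| on binary rows; the 0/0 case
  (two all-zero strains) is defined as distance 0. Metric axioms are
  property-tested.
- **Hierarchical clustering** is an explicit agglomeration (average
  linkage by default; single/complete available) with a fully specified
  tie-break: equidistant cluster pairs merge in lexicographic order of
  their leaf-sorted labels. scipy's nn-chain implementation has its own
  internal tie order, which is why the agglomeration is written out here —
  dendrograms are reproducible across platforms and checkable against a
  naive step-by-step oracle. Exports: Newick (branch length = merge-height
  difference), scipy linkage matrix, leaf order for heatmaps. Heatmap
  rendering itself is out of contract: the cluster-ordered matrix export
  is the interface to any plotting layer.
- **PCA** is column-centred SVD; component signs are fixed by making each
  component's largest-magnitude loading positive. Variance fractions are
  cross-checked against covariance eigenvalues in the tests.
- **Gene–reaction correlation** is an ordinary least-squares line plus
  Pearson r between per-strain gene and reaction counts. Constant gene
  counts make the correlation undefined (explicit error); constant
  reaction counts return r = 0 with slope 0.

## Synthetic studies

The generator emulates the structure of a real strain panel at toy scale:

- **Universal toy network**: a viable core — glucose uptake and transport,
  lumped glycolysis (glc → 2 carbon units + 2 energy units), lumped
  respiration (carbon unit + O₂ → 3 energy units), N/P/S uptake and
  assimilation, cobalamin uptake, and a biomass reaction consuming all
  four element pools, energy, and a trace of cobalamin (so the −0.01
  cobalamin bound is exercised without ever limiting growth). All 18 M9
  ion exchanges are present so media construction is fully exercised. Each
  of `n_modules` catabolic modules converts one dedicated nutrient into a
  core species (carbon modules → carbon units; N/P/S modules → NH₄⁺ /
  phosphate / sulfate) through 2–3 reactions gated by two module genes
  with alternating AND/OR rules. One "orphan" nutrient has an exchange but
  no route anywhere, giving a structurally all-zero screen column.
- **Strains** are mutated copies of the reference proteome. Kept orthologs
  receive point substitutions to a target identity (default 88%, chosen so
  strain–reference and strain–strain identities stay safely above the 70%
  cutoff; a target at or below the cutoff is rejected unless explicitly
  allowed for degradation experiments). No indels, so coverage is always
  100% and identity is the only thresholded axis. Genes of non-carried
  modules are removed outright. Each strain also gets 2 private random
  genes (singleton families).
- **Clade structure**: strains split into `n_clades` contiguous blocks;
  the default carriage pattern is noiseless — clade c lacks exactly the
  modules m with m mod n_clades = c — giving distinct per-clade phenotype
  profiles (so clustering recovers clades with adjusted Rand index 1) and
  75% carriage per module at the default 4 clades. Carriage probabilities
  are a free (clades × modules) matrix for noisy designs.
- **Auxotrophy plants**: two strains lose the sulfate-assimilation gene,
  creating drafts that cannot grow on M9 until gap-filled.
- **Determinism**: one seed fixes everything; independent child streams
  (seeded `[seed, k]`) keep the reference-sequence draws and the
  strain-mutation draws from ever replaying the same underlying stream,
  which would create spurious sequence identity between unrelated genes.

Default study size — 24 strains, 4 clades, 8 modules — runs the full
pipeline (including all-pairs gene-family clustering, the most expensive
step) in well under a minute on one CPU.

**What passing on synthetic data does and does not show.** The generator
gives exact ground truth for orthology, reconstruction, gap-filling,
screening and clustering, so tests can demand perfect recovery. It does
not emulate real proteomes (no indels, no domain structure, no paralog
families beyond what mutation creates), real metabolic networks (toy
stoichiometry, no cofactor balancing, no alternate routes between
modules), or annotation noise. Passing therefore validates the pipeline's
logic and numerics, not the biological fidelity of any particular strain
panel.

## Known limitations

- No flux variability analysis, parsimonious FBA, thermodynamic or
  kinetic constraints.
- Gene families by single-linkage BBH components will over-merge in the
  presence of extensive paralogy or promiscuous domains.
- Gap-fill minimality is guaranteed only when the LP-relaxation support is
  small (≤ 12 candidates); larger repairs are irreducible but possibly
  not minimum-cardinality.
- Single-default removal in sole-source conditions means a candidate
  containing several elements is only ever tested for the class it is
  declared under.
- SBML I/O is not provided; convert to model JSON first.
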