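import itertools

import numpy as np
import pytest

from gempan.fba import solve_fba
from gempan.media import m9_base
from gempan.orthology import bidirectional_best_hits
from gempan.screen import sole_source_media
from gempan.synthetic import (
    SyntheticDesign,
    build_universal_toy,
    emit_study,
    load_study,
    spawn_strains,
)


def test_reference_viable_on_glucose_m9():
    _u, ref, _p, _m = build_universal_toy(8, seed=0)
    res = solve_fba(ref, m9_base(ref))
    assert res.grows


def test_module_genes_irrelevant_on_glucose():
    _u, ref, _p, mods = build_universal_toy(4, seed=0)
    drop = [rid for m in mods for rid in m.reaction_ids]
    stripped = ref.delete_reactions(drop)
    full = solve_fba(ref, m9_base(ref)).objective_value
    bare = solve_fba(stripped, m9_base(stripped)).objective_value
    assert bare == pytest.approx(full, rel=1e-9)


@pytest.mark.parametrize("n_modules", [2, 4])
def test_nutrient_supports_growth_iff_module_intact(n_modules):
    """FBA over every on/off combination of the modules: each module's
    nutrient supports growth exactly when its reactions are present."""
    _u, ref, _p, mods = build_universal_toy(n_modules, seed=1)
    base = m9_base(ref)
    for keep in itertools.product([0, 1], repeat=n_modules):
        drop = [rid for k, m in zip(keep, mods) if not k for rid in m.reaction_ids]
        model = ref.delete_reactions(drop) if drop else ref
        media_base = m9_base(model)
        for k, mod in zip(keep, mods):
            from gempan.screen import NutrientCondition

            cond = NutrientCondition(element_class=mod.element_class,
                                     exchange_id=mod.nutrient_exchange)
            media = sole_source_media(media_base, cond)
            res = solve_fba(model, media)
            assert res.grows == bool(k), (keep, mod.name)


def test_same_seed_reproduces_bytes(tmp_path):
    design = SyntheticDesign(n_strains=6, n_clades=2, n_modules=4,
                             auxotroph_strains=(0,), seed=123)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    p1 = emit_study(design, d1)
    p2 = emit_study(design, d2)
    for key in p1:
        if p1[key].is_file():
            assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_different_seed_differs(tmp_path):
    a = emit_study(SyntheticDesign(n_strains=4, n_clades=2, n_modules=4,
                                   auxotroph_strains=(), seed=1), tmp_path / "a")
    b = emit_study(SyntheticDesign(n_strains=4, n_clades=2, n_modules=4,
                                   auxotroph_strains=(), seed=2), tmp_path / "b")
    assert a["reference_proteome"].read_bytes() != b["reference_proteome"].read_bytes()


def test_emitted_study_round_trips(tmp_path):
    design = SyntheticDesign(n_strains=6, n_clades=2, n_modules=4,
                             auxotroph_strains=(0,), seed=7)
    emit_study(design, tmp_path)
    loaded_design, universal, reference, ref_prot, proteomes, conditions, truth = (
        load_study(tmp_path)
    )
    assert loaded_design.to_dict() == design.to_dict()
    _u2, ref2, prot2, mods = build_universal_toy(design.n_modules, seed=design.seed)
    assert reference.content_equal(ref2)
    assert ref_prot.sequences == prot2.sequences
    prots2, truth2 = spawn_strains(design, ref2, prot2, mods)
    assert {p.strain_id: p.sequences for p in proteomes} == {
        p.strain_id: p.sequences for p in prots2
    }
    assert truth["expected_growth"].equals(truth2.expected_growth)
    assert conditions == truth2.conditions


def test_mutation_rate_zero_identity_proteomes():
    _u, ref, prot, mods = build_universal_toy(2, seed=0)
    design = SyntheticDesign(n_strains=4, n_clades=2, n_modules=2,
                             target_identity=100.0, n_private_genes=0,
                             auxotroph_strains=(), seed=0,
                             carriage_probs=np.ones((2, 2)))
    prots, truth = spawn_strains(design, ref, prot, mods)
    for p in prots:
        assert {g.split("_", 1)[1] for g in p.sequences} == set(prot.sequences)
        for g, seq in p.sequences.items():
            assert seq == prot.sequences[g.split("_", 1)[1]]
    assert (truth.carriage == 1).all().all()
    assert (truth.expected_growth.drop(columns=["C:EX_orph_e"]) == 1).all().all()


def test_zero_probability_blocks_module_block():
    _u, ref, prot, mods = build_universal_toy(2, seed=0)
    probs = np.ones((2, 2))
    probs[0, 1] = 0.0  # clade 0 never carries module 2
    design = SyntheticDesign(n_strains=6, n_clades=2, n_modules=2,
                             carriage_probs=probs, auxotroph_strains=(), seed=3)
    prots, truth = spawn_strains(design, ref, prot, mods)
    clade0 = truth.clades[truth.clades == 0].index
    assert (truth.carriage.loc[clade0, "mod2"] == 0).all()


def test_low_target_identity_rejected():
    _u, ref, prot, mods = build_universal_toy(2, seed=0)
    design = SyntheticDesign(n_strains=2, n_clades=1, n_modules=2,
                             target_identity=65.0, auxotroph_strains=(), seed=0,
                             carriage_probs=np.ones((1, 2)))
    with pytest.raises(ValueError, match="cutoff"):
        spawn_strains(design, ref, prot, mods)


def test_degradation_below_cutoff_causes_bbh_misses():
    """Pushing kept-ortholog identity well below 70% makes BBH drop pairs;
    every strain is affected in the noiseless design."""
    _u, ref, prot, mods = build_universal_toy(2, seed=0)
    design = SyntheticDesign(n_strains=3, n_clades=1, n_modules=2,
                             target_identity=50.0, n_private_genes=0,
                             auxotroph_strains=(), seed=0,
                             carriage_probs=np.ones((1, 2)))
    prots, _ = spawn_strains(design, ref, prot, mods, allow_low_identity=True)
    for p in prots:
        omap = bidirectional_best_hits(prot, p)
        assert len(omap) < len(p.sequences)
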