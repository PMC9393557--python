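import numpy as np
import pytest

from gempan.fba import GROWTH_EPSILON, solve_fba
from gempan.gpr import Gpr
from gempan.media import m9_base
from gempan.model import Model, Reaction
from gempan.orthology import OrthologMap
from gempan.reconstruction import (
    GapfillError,
    derive_strain_model,
    gapfill,
    is_irreducible,
    reconstruct_all,
)
from gempan.synthetic import build_universal_toy

from .oracles import gapfill_oracle


def identity_map(model: Model, strain_id: str) -> OrthologMap:
    return OrthologMap(strain_id=strain_id, pairs={g: f"{strain_id}_{g}" for g in model.genes})


def test_full_ortholog_map_reproduces_reference():
    _u, ref, _p, _m = build_universal_toy(4, seed=2)
    strain = derive_strain_model(ref, identity_map(ref, "sX"), "sX")
    assert set(strain.reactions) == set(ref.reactions)
    assert strain.genes == {f"sX_{g}" for g in ref.genes}
    for rid, rxn in ref.reactions.items():
        assert strain.reactions[rid].stoichiometry == rxn.stoichiometry
        assert strain.reactions[rid].lower_bound == rxn.lower_bound


def test_unmapped_single_gene_drops_reaction():
    _u, ref, _p, _m = build_universal_toy(4, seed=2)
    omap = identity_map(ref, "sY")
    del omap.pairs["gcore_glyc"]
    strain = derive_strain_model(ref, omap, "sY")
    assert "GLYC" not in strain.reactions
    # empty-GPR reactions (exchanges, biomass) always inherited
    assert "BIOMASS" in strain.reactions
    assert all(r.id in strain.reactions for r in ref.exchanges)


def test_or_rule_retained_with_one_mapped_gene():
    _u, ref, _p, _m = build_universal_toy(4, seed=2)
    # MOD2cat has rule "g_mod2_a or g_mod2_b"
    omap = identity_map(ref, "sZ")
    del omap.pairs["g_mod2_b"]
    strain = derive_strain_model(ref, omap, "sZ")
    assert "MOD2cat" in strain.reactions
    assert strain.reactions["MOD2cat"].gpr.genes() == {"sZ_g_mod2_a"}
    # AND rule loses its reaction when one member is unmapped
    omap2 = identity_map(ref, "sW")
    del omap2.pairs["g_mod1_b"]
    strain2 = derive_strain_model(ref, omap2, "sW")
    assert "MOD1cat1" not in strain2.reactions


def test_unknown_ortholog_domain_rejected():
    _u, ref, _p, _m = build_universal_toy(2, seed=2)
    bad = OrthologMap(strain_id="s", pairs={"not_a_gene": "s_g"})
    with pytest.raises(ValueError, match="absent from the reference"):
        derive_strain_model(ref, bad, "s")


def test_gapfill_restores_single_missing_transport():
    _u, ref, _p, _m = build_universal_toy(2, seed=0)
    media = m9_base(ref)
    draft = ref.delete_reactions(["GLCt"])
    assert not solve_fba(draft, media).grows
    result = gapfill(draft, ref, media)
    assert result.added_reaction_ids == ["GLCt"]
    assert result.post_fill_growth > GROWTH_EPSILON
    assert is_irreducible(draft, ref, result.added_reaction_ids, media)


def test_gapfill_noop_when_draft_grows():
    _u, ref, _p, _m = build_universal_toy(2, seed=0)
    media = m9_base(ref)
    result = gapfill(ref, ref, media)
    assert result.added_reaction_ids == []
    assert result.post_fill_growth > GROWTH_EPSILON


def test_gapfill_prefers_one_reaction_repair():
    # universal offers a 2-reaction detour and a 1-reaction direct repair
    reactions = [
        Reaction(id="EX_s_e", stoichiometry={"s_e": -1}, lower_bound=-10, upper_bound=1000),
        Reaction(id="OBJ", stoichiometry={"p_c": -1}, lower_bound=0, upper_bound=1000),
    ]
    draft = Model("draft", reactions, objective="OBJ", biomass_reaction_id="OBJ")
    uni_rxns = reactions + [
        Reaction(id="DIRECT", stoichiometry={"s_e": -1, "p_c": 1}, lower_bound=0,
                 upper_bound=1000),
        Reaction(id="STEP1", stoichiometry={"s_e": -1, "i_c": 1}, lower_bound=0,
                 upper_bound=1000),
        Reaction(id="STEP2", stoichiometry={"i_c": -1, "p_c": 1}, lower_bound=0,
                 upper_bound=1000),
    ]
    universal = Model("uni", uni_rxns, objective="OBJ", biomass_reaction_id="OBJ")
    media = {"EX_s_e": -10.0}
    result = gapfill(draft, universal, media)
    assert result.added_reaction_ids == ["DIRECT"]
    assert gapfill_oracle(draft, universal, media, GROWTH_EPSILON) == 1


def test_unfillable_names_medium():
    reactions = [
        Reaction(id="EX_s_e", stoichiometry={"s_e": -1}, lower_bound=-10, upper_bound=1000),
        Reaction(id="OBJ", stoichiometry={"p_c": -1}, lower_bound=0, upper_bound=1000),
    ]
    draft = Model("draft", reactions, objective="OBJ", biomass_reaction_id="OBJ")
    with pytest.raises(GapfillError, match="unfillable"):
        gapfill(draft, draft, {"EX_s_e": -10.0})


def test_gapfill_matches_exhaustive_oracle_on_random_instances():
    rng = np.random.default_rng(11)
    _u, ref, _p, _m = build_universal_toy(4, seed=5)
    media = m9_base(ref)
    deletable = [
        rid for rid in ref.reactions
        if rid not in ("BIOMASS",) and not ref.reactions[rid].is_exchange
    ]
    for _ in range(8):
        k = int(rng.integers(1, 4))
        drop = list(rng.choice(deletable, size=k, replace=False))
        draft = ref.delete_reactions(drop)
        oracle_k = gapfill_oracle(draft, ref, media, GROWTH_EPSILON)
        if oracle_k is None:
            with pytest.raises(GapfillError):
                gapfill(draft, ref, media)
            continue
        result = gapfill(draft, ref, media)
        assert len(result.added_reaction_ids) == oracle_k
        assert result.post_fill_growth > GROWTH_EPSILON
        assert is_irreducible(draft, ref, result.added_reaction_ids, media)


def test_reconstruct_all_reference_round_trip(toy_study):
    ref = toy_study["reference"]
    media = m9_base(ref)
    models, prov = reconstruct_all(
        ref, toy_study["universal"], [toy_study["reference_proteome"]], media,
        reference_proteome=toy_study["reference_proteome"],
    )
    model = models["reference"]
    assert set(model.reactions) == set(ref.reactions)
    assert prov.loc[0, "n_gapfilled"] == 0


def test_strain_models_match_planted_modules(toy_study, reconstructed):
    truth = toy_study["truth"]
    modules = {m.name: m for m in toy_study["modules"]}
    for sid, model in reconstructed["models"].items():
        for name, mod in modules.items():
            carried = bool(truth.carriage.loc[sid, name])
            present = all(rid in model.reactions for rid in mod.reaction_ids)
            absent = all(rid not in model.reactions for rid in mod.reaction_ids)
            assert present if carried else absent, (sid, name)


def test_auxotroph_masked_by_gapfill(toy_study, reconstructed):
    """A strain with a deleted biosynthetic gene still grows on M9 after
    gap-filling; the repair is visible in the provenance log."""
    prov = reconstructed["provenance"].set_index("strain")
    truth = toy_study["truth"]
    auxotrophs = [s for s, genes in truth.deleted_genes.items() if genes]
    assert auxotrophs
    for sid in auxotrophs:
        assert prov.loc[sid, "n_gapfilled"] >= 1
        assert "SASSIM" in prov.loc[sid, "gapfilled_reactions"]
        res = solve_fba(reconstructed["models"][sid], reconstructed["media"])
        assert res.grows
    # non-auxotrophs needed no repair on glucose
    for sid in truth.carriage.index:
        if sid not in auxotrophs:
            assert prov.loc[sid, "n_gapfilled"] == 0


def test_reconstruction_deterministic(toy_study):
    ref = toy_study["reference"]
    media = m9_base(ref)
    prots = toy_study["proteomes"][:3]
    m1, p1 = reconstruct_all(ref, toy_study["universal"], prots, media,
                             reference_proteome=toy_study["reference_proteome"])
    m2, p2 = reconstruct_all(ref, toy_study["universal"], prots, media,
                             reference_proteome=toy_study["reference_proteome"])
    assert p1.equals(p2)
    for sid in m1:
        assert m1[sid].content_equal(m2[sid])
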