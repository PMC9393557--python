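from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from gempan.fba import solve_fba
from gempan.gpr import Gpr
from gempan.media import m9_base
from gempan.model import Metabolite, Model, Reaction
from gempan.reconstruction import reconstruct_all
from gempan.screen import screen
from gempan.synthetic import SyntheticDesign, build_universal_toy, spawn_strains

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_chain_model(uptake: float = -20.0) -> Model:
    """EX_A (lb -20) -> transport A_e->A_c -> biomass consuming 1 A_c."""
    reactions = [
        Reaction(id="EX_A_e", stoichiometry={"A_e": -1}, lower_bound=uptake,
                 upper_bound=1000),
        Reaction(id="At", stoichiometry={"A_e": -1, "A_c": 1}, lower_bound=0,
                 upper_bound=1000, gpr=Gpr.parse("gAt")),
        Reaction(id="GROWTH", stoichiometry={"A_c": -1}, lower_bound=0,
                 upper_bound=1000),
    ]
    return Model("chain", reactions, objective="GROWTH", biomass_reaction_id="GROWTH")


@pytest.fixture
def chain_model() -> Model:
    return make_chain_model()


@pytest.fixture(scope="session")
def toy_study():
    """The default synthetic study: universal DB, reference model+proteome,
    module catalogue, strain proteomes and planted ground truth."""
    universal, reference, ref_prot, modules = build_universal_toy(8, seed=0)
    design = SyntheticDesign()
    proteomes, truth = spawn_strains(design, reference, ref_prot, modules)
    return {
        "design": design,
        "universal": universal,
        "reference": reference,
        "reference_proteome": ref_prot,
        "modules": modules,
        "proteomes": proteomes,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def reconstructed(toy_study):
    """Strain models and provenance for the default study (M9 + glucose)."""
    media = m9_base(toy_study["reference"])
    models, provenance = reconstruct_all(
        toy_study["reference"],
        toy_study["universal"],
        toy_study["proteomes"],
        media,
        reference_proteome=toy_study["reference_proteome"],
    )
    return {"models": models, "provenance": provenance, "media": media}


@pytest.fixture(scope="session")
def growth_matrix(toy_study, reconstructed):
    return screen(reconstructed["models"], toy_study["truth"].conditions)
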