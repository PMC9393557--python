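import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gempan.stats import (
    gene_reaction_correlation,
    hierarchical_cluster,
    jaccard_distance,
    pca_project,
)

from .oracles import agglomeration_oracle


def binary_frame(rows):
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])


def test_jaccard_examples():
    d = jaccard_distance(binary_frame([[1, 1, 0, 0], [0, 1, 1, 0]]))
    assert d.iloc[0, 1] == pytest.approx(1 - 1 / 3)
    d2 = jaccard_distance(binary_frame([[1, 1], [1, 1]]))
    assert d2.iloc[0, 1] == 0.0
    d3 = jaccard_distance(binary_frame([[1, 0], [0, 1]]))
    assert d3.iloc[0, 1] == 1.0
    # all-zero pair defined as distance 0
    d4 = jaccard_distance(binary_frame([[0, 0], [0, 0]]))
    assert d4.iloc[0, 1] == 0.0


def test_jaccard_rejects_non_binary():
    with pytest.raises(ValueError):
        jaccard_distance(binary_frame([[0.5, 1]]))


@given(st.integers(0, 10_000))
@settings(max_examples=50)
def test_jaccard_metric_axioms(seed):
    rng = np.random.default_rng(seed)
    m = binary_frame(rng.integers(0, 2, size=(4, 10)))
    d = jaccard_distance(m).to_numpy()
    assert (np.diag(d) == 0).all()
    assert np.allclose(d, d.T)
    assert ((d >= 0) & (d <= 1)).all()
    for i in range(4):
        for j in range(4):
            for k in range(4):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def test_identical_strains_merge_first():
    m = binary_frame([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
    dend = hierarchical_cluster(jaccard_distance(m))
    assert dend.merges[0].height == 0.0
    assert set(dend.merges[0].left + dend.merges[0].right) == {"s0", "s1"}


def test_clear_pair_merges_first():
    d = pd.DataFrame(
        [[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]],
        index=list("abc"), columns=list("abc"),
    )
    dend = hierarchical_cluster(d)
    assert set(dend.merges[0].left + dend.merges[0].right) == {"a", "b"}
    # average linkage to c: (0.9 + 0.8)/2
    assert dend.merges[1].height == pytest.approx(0.85)


@pytest.mark.parametrize("linkage", ["average", "single", "complete"])
def test_merge_order_matches_brute_force_oracle(linkage):
    rng = np.random.default_rng(17)
    labels = list("abcde")
    for _ in range(20):
        raw = rng.integers(0, 2, size=(5, 12))
        d = jaccard_distance(pd.DataFrame(raw, index=labels))
        dend = hierarchical_cluster(d, linkage=linkage)
        expected = agglomeration_oracle(labels, d.to_numpy(), method=linkage)
        got = [(m.left, m.right, m.height) for m in dend.merges]
        exp = [(a, b, h) for a, b, h in expected]
        assert [(set(a + b), pytest.approx(h)) for a, b, h in exp] == [
            (set(l + r), pytest.approx(h)) for l, r, h in got
        ]
        # identical tie-break: exact pair identity, not just membership
        assert [(a, b) for a, b, _ in exp] == [(m.left, m.right) for m in dend.merges]


def test_heights_monotone_and_newick_wellformed():
    rng = np.random.default_rng(3)
    m = binary_frame(rng.integers(0, 2, size=(6, 15)))
    dend = hierarchical_cluster(jaccard_distance(m))
    heights = [mg.height for mg in dend.merges]
    assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))
    nwk = dend.to_newick()
    assert nwk.endswith(";") and nwk.count("(") == len(dend.merges)
    import io

    from Bio import Phylo

    tree = Phylo.read(io.StringIO(nwk), "newick")
    assert {t.name for t in tree.get_terminals()} == set(dend.leaves)


def test_relabeling_invariance():
    rng = np.random.default_rng(4)
    raw = rng.integers(0, 2, size=(5, 10))
    d1 = jaccard_distance(pd.DataFrame(raw, index=list("abcde")))
    d2 = jaccard_distance(pd.DataFrame(raw, index=list("vwxyz")))
    m1 = hierarchical_cluster(d1).merges
    m2 = hierarchical_cluster(d2).merges
    trans = dict(zip("abcde", "vwxyz"))
    for a, b in zip(m1, m2):
        assert {tuple(sorted(trans[x] for x in a.left)),
                tuple(sorted(trans[x] for x in a.right))} == {b.left, b.right}
        assert a.height == pytest.approx(b.height)


def test_asymmetric_distance_rejected():
    d = pd.DataFrame([[0, 0.5], [0.4, 0]], index=["a", "b"], columns=["a", "b"])
    with pytest.raises(ValueError):
        hierarchical_cluster(d)


def test_pca_one_dimensional_gradient():
    m = pd.DataFrame({"f1": [0, 1, 2, 3], "f2": [0, 2, 4, 6]})
    res = pca_project(m, n_components=2)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)


def test_pca_orthonormal_components_and_reconstruction():
    rng = np.random.default_rng(5)
    m = pd.DataFrame(rng.integers(0, 2, size=(10, 6)).astype(float))
    res = pca_project(m, n_components=6)
    V = res.loadings.to_numpy()
    assert np.allclose(V @ V.T, np.eye(V.shape[0]), atol=1e-10)
    Xc = m.to_numpy() - m.to_numpy().mean(axis=0)
    assert np.allclose(res.scores.to_numpy() @ V, Xc, atol=1e-8)
    # variance fractions match covariance eigenvalues computed independently
    eig = np.linalg.eigvalsh(np.cov(Xc.T))[::-1]
    frac = eig / eig.sum()
    assert np.allclose(res.explained_variance_ratio[: len(frac)], frac[:6], atol=1e-8)


def test_pca_sign_convention_deterministic():
    rng = np.random.default_rng(6)
    m = pd.DataFrame(rng.normal(size=(8, 4)))
    r1, r2 = pca_project(m), pca_project(m)
    assert np.allclose(r1.scores, r2.scores)
    for i in range(2):
        row = r1.loadings.to_numpy()[i]
        assert row[np.argmax(np.abs(row))] > 0


def test_pca_needs_two_strains():
    with pytest.raises(ValueError):
        pca_project(pd.DataFrame([[1, 0]]))


def test_gene_reaction_correlation_linear_and_degenerate():
    from gempan.gpr import Gpr
    from gempan.model import Model, Reaction

    def fake_model(mid, n_genes, n_rxns):
        rxns = [
            Reaction(id=f"R{i}", stoichiometry={f"m{i}_c": -1}, lower_bound=0,
                     upper_bound=1)
            for i in range(n_rxns)
        ]
        return Model(mid, rxns, genes={f"g{k}" for k in range(n_genes)},
                     objective="R0", biomass_reaction_id="R0")

    linear = {f"s{i}": fake_model(f"s{i}", 10 + i, 20 + 2 * i) for i in range(5)}
    slope, intercept, r = gene_reaction_correlation(linear)
    assert r == pytest.approx(1.0)
    assert slope == pytest.approx(2.0)
    assert intercept == pytest.approx(0.0, abs=1e-9)

    flat = {f"s{i}": fake_model(f"s{i}", 10 + i, 30) for i in range(4)}
    slope, intercept, r = gene_reaction_correlation(flat)
    assert (slope, r) == (0.0, 0.0)

    degenerate = {f"s{i}": fake_model(f"s{i}", 10, 20 + i) for i in range(4)}
    with pytest.raises(ValueError, match="undefined"):
        gene_reaction_correlation(degenerate)


def test_correlation_recovers_planted_slope():
    from gempan.model import Model, Reaction

    rng = np.random.default_rng(8)
    models = {}
    for i in range(30):
        n_genes = int(rng.integers(50, 150))
        n_rxns = int(round(0.5 * n_genes + 40 + rng.normal(0, 2)))
        rxns = [
            Reaction(id=f"R{k}", stoichiometry={f"m{k}_c": -1}, lower_bound=0,
                     upper_bound=1)
            for k in range(n_rxns)
        ]
        models[f"s{i}"] = Model(f"s{i}", rxns,
                                genes={f"g{k}" for k in range(n_genes)},
                                objective="R0", biomass_reaction_id="R0")
    slope, intercept, r = gene_reaction_correlation(models)
    assert slope == pytest.approx(0.5, abs=0.05)
    assert r > 0.95
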