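"""Nei distance, UPGMA, AMOVA, pairwise Fst, cluster diversity, delta-K."""

import math

import numpy as np
import pytest

from ssrmine import datasets
from ssrmine import synthetic_data as sd
from ssrmine.genotype_stats import panel_summary
from ssrmine.population_structure import (
    DistanceMatrix,
    amova,
    evanno_delta_k,
    grouped_diversity,
    nei_distance,
    nei_distance_matrix,
    pairwise_fst,
    upgma,
)

# ---------------------------------------------------------------------------
# Nei distance
# ---------------------------------------------------------------------------

def test_nei_identical_sets_is_zero():
    f = {"L1": {1: 0.3, 2: 0.7}, "L2": {1: 1.0}}
    assert nei_distance(f, f) == 0.0


def test_nei_closed_form_single_locus():
    d = nei_distance({"L": {1: 1.0, 2: 0.0}}, {"L": {1: 0.5, 2: 0.5}})
    assert d == pytest.approx(-math.log(0.5 / math.sqrt(0.5)), abs=1e-9)
    assert d == pytest.approx(0.3466, abs=2e-4)


def test_nei_disjoint_alleles_flagged():
    a = {"L": {1: 1.0}}
    b = {"L": {2: 1.0}}
    assert math.isinf(nei_distance(a, b))
    assert nei_distance(a, b, zero_identity=10.0) == 10.0


def test_nei_symmetry(rng):
    for _ in range(10):
        a = {"L": dict(enumerate(rng.dirichlet(np.ones(4))))}
        b = {"L": dict(enumerate(rng.dirichlet(np.ones(4))))}
        assert nei_distance(a, b) == pytest.approx(nei_distance(b, a))


def test_nei_requires_matching_loci():
    with pytest.raises(ValueError):
        nei_distance({"L1": {1: 1.0}}, {"L2": {1: 1.0}})


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def test_upgma_three_taxon_hand_agglomeration():
    dm = DistanceMatrix(["A", "B", "C"],
                        np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float))
    tree = upgma(dm)
    assert tree.newick() == "((A:1,B:1):2,C:3);"
    assert tree.is_ultrametric()


def test_upgma_two_taxon_cherry():
    dm = DistanceMatrix(["X", "Y"], np.array([[0, 3], [3, 0]], float))
    tree = upgma(dm)
    assert tree.newick() == "((X:1.5,Y:1.5));" or tree.newick() == "(X:1.5,Y:1.5);"
    depths = tree.leaf_depths()
    assert depths["X"] == depths["Y"] == 1.5


def test_upgma_rejects_nan():
    with pytest.raises(ValueError):
        upgma(DistanceMatrix(["A", "B"], np.array([[0, np.nan], [np.nan, 0]])))


def _random_distance_matrix(rng, n):
    x = rng.random((n, 5))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([f"t{i}" for i in range(n)], d)


def test_upgma_always_ultrametric(rng):
    for n in (4, 7, 12):
        tree = upgma(_random_distance_matrix(rng, n))
        assert tree.is_ultrametric(tol=1e-9)
        assert sorted(l.name for l in tree.leaves()) == sorted(
            f"t{i}" for i in range(n)
        )


def test_upgma_matches_scipy_cophenetic(rng):
    """Cross-check against scipy's average-linkage cophenetic distances."""
    from scipy.cluster.hierarchy import cophenet, linkage
    from scipy.spatial.distance import squareform

    dm = _random_distance_matrix(rng, 8)
    tree = upgma(dm)

    # pairwise cophenetic distances from our tree: 2 x merge height
    def pair_heights(node, out):
        if node.is_leaf:
            return [node.name]
        sides = [pair_heights(c, out) for c in node.children]
        for a in sides[0]:
            for b in sides[1]:
                out[frozenset((a, b))] = 2.0 * node.height
        return sides[0] + sides[1]

    ours: dict = {}
    pair_heights(tree, ours)
    z = linkage(squareform(dm.values), method="average")
    coph = squareform(cophenet(z))
    for i in range(8):
        for j in range(i + 1, 8):
            key = frozenset((f"t{i}", f"t{j}"))
            assert ours[key] == pytest.approx(coph[i, j], abs=1e-9)


def test_upgma_invariant_under_label_permutation(rng):
    dm = _random_distance_matrix(rng, 6)
    perm = rng.permutation(6)
    dm_p = DistanceMatrix([dm.labels[i] for i in perm],
                          dm.values[np.ix_(perm, perm)])
    t1 = upgma(dm)
    t2 = upgma(dm_p)
    assert t1.leaf_depths() == pytest.approx(t2.leaf_depths())

    def clades(node, acc):
        if node.is_leaf:
            return frozenset([node.name])
        s = frozenset().union(*(clades(c, acc) for c in node.children))
        acc.add(s)
        return s

    c1, c2 = set(), set()
    clades(t1, c1)
    clades(t2, c2)
    assert c1 == c2


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _three_pop_matrix(seed=31, n=90, div=0.10, loci=12):
    cfg = sd.SimulationConfig(seed=seed, n_accessions=n, n_subpops=3,
                              divergence=div, n_loci=loci, missing_rate=0.0)
    return sd.simulate_genotype_matrix(cfg)


def test_amova_degrees_of_freedom_identity():
    m, truth = _three_pop_matrix(n=149)
    vc = amova(m, truth.assignments)
    assert list(vc.table["df"][:3]) == [2, 146, 149]
    assert vc.table.loc["total", "df"] == 297  # 2N - 1


def test_amova_percents_sum_to_100():
    m, truth = _three_pop_matrix()
    vc = amova(m, truth.assignments)
    assert sum(vc.percents.values()) == pytest.approx(100.0, abs=1e-9)
    assert all(v >= 0 for v in vc.percents.values())


def test_amova_published_components_give_84_percent_within():
    comp = datasets.AMOVA_COMPONENTS
    total = sum(comp.values())
    pct = 100.0 * comp["within_individuals"] / total
    assert round(pct) == 84


def test_amova_panmictic_split_has_no_among_share():
    cfg = sd.SimulationConfig(seed=41, n_accessions=500, n_subpops=1,
                              divergence=0.0, n_loci=20, missing_rate=0.0)
    m, _ = sd.simulate_genotype_matrix(cfg)
    arbitrary = {a: ("left" if i < 250 else "right")
                 for i, a in enumerate(m.accession_ids)}
    vc = amova(m, arbitrary)
    assert vc.percents["among_populations"] < 2.0


def test_amova_requires_two_populations_of_two():
    m, truth = _three_pop_matrix(n=12)
    with pytest.raises(ValueError):
        amova(m, {a: "one" for a in m.accession_ids})
    lone = dict(truth.assignments)
    lone[m.accession_ids[0]] = "loner"
    with pytest.raises(ValueError):
        amova(m, lone)


# ---------------------------------------------------------------------------
# pairwise Fst
# ---------------------------------------------------------------------------

def test_fst_identical_pools_is_zero(rng):
    cfg = sd.SimulationConfig(seed=43, n_accessions=200, n_subpops=1,
                              divergence=0.0, n_loci=15, missing_rate=0.0)
    m, _ = sd.simulate_genotype_matrix(cfg)
    grouping = {a: ("A" if i % 2 else "B") for i, a in enumerate(m.accession_ids)}
    fst = pairwise_fst(m, grouping)
    assert fst.values[0, 1] < 0.02
    assert fst.values[0, 0] == 0.0 and fst.values[1, 1] == 0.0


def test_fst_matrix_shape_and_bounds():
    m, truth = _three_pop_matrix()
    fst = pairwise_fst(m, truth.assignments)
    assert fst.values.shape == (3, 3)
    assert np.all(fst.values >= 0) and np.all(fst.values <= 1)
    assert np.allclose(fst.values, fst.values.T)
    assert np.all(np.diag(fst.values) == 0)


def test_fst_recovers_balding_nichols_parameter():
    """Mean pairwise Fst within +-0.03 of the 0.10 divergence target
    (50 loci, 200 individuals per population)."""
    cfg = sd.SimulationConfig(seed=47, n_accessions=400, n_subpops=2,
                              divergence=0.10, n_loci=50, missing_rate=0.0)
    m, truth = sd.simulate_genotype_matrix(cfg)
    fst = pairwise_fst(m, truth.assignments)
    assert fst.values[0, 1] == pytest.approx(0.10, abs=0.03)


def test_fst_monotone_in_divergence():
    est = []
    for div in (0.02, 0.05, 0.15):
        cfg = sd.SimulationConfig(seed=53, n_accessions=200, n_subpops=2,
                                  divergence=div, n_loci=30, missing_rate=0.0)
        m, truth = sd.simulate_genotype_matrix(cfg)
        est.append(pairwise_fst(m, truth.assignments).values[0, 1])
    assert est[0] < est[1] < est[2]


# ---------------------------------------------------------------------------
# grouped diversity
# ---------------------------------------------------------------------------

def test_cluster_mean_shannon_matches_published_table():
    assert datasets.CLUSTER_DIVERSITY["I"].mean() == pytest.approx(0.975, abs=5e-4)


def test_single_population_equals_panel_summary():
    m, _ = _three_pop_matrix(n=40)
    grouping = {a: "all" for a in m.accession_ids}
    gd = grouped_diversity(m, grouping)
    ps = panel_summary(m).loc["Mean"]
    for col in ("N", "Na", "Ne", "I", "Ho", "He", "F"):
        assert gd.loc["all", col] == pytest.approx(ps[col])


def test_grouped_diversity_bounds():
    m, truth = _three_pop_matrix()
    gd = grouped_diversity(m, truth.assignments)
    assert ((gd["Ho"] >= 0) & (gd["Ho"] <= 1)).all()
    assert "Mean" in gd.index


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def test_delta_k_direct_formula():
    runs = {
        1: [-1000.0, -1000.0, -1000.0],
        2: [-510.0, -500.0, -490.0],   # mean -500, sample sd 10
        3: [-401.0, -400.0, -399.0],
        4: [-301.0, -300.0, -299.0],   # linear beyond the knee
    }
    out = evanno_delta_k(runs)
    assert out.table.loc[2, "sd_l"] == pytest.approx(10.0)
    # |mean L(3) - 2 mean L(2) + mean L(1)| / sd(2) = |-400 + 1000 - 1000| / 10
    assert out.table.loc[2, "delta_k"] == pytest.approx(40.0)
    assert out.table.loc[3, "delta_k"] == pytest.approx(0.0)
    assert out.optimal_k == 2


def test_delta_k_zero_for_linear_means():
    # symmetric replicate spread around exactly linear means
    runs = {k: [-1000.0 + 100.0 * k + d for d in (-1.0, 0.0, 1.0)]
            for k in range(1, 6)}
    out = evanno_delta_k(runs)
    inner = out.table["delta_k"].dropna()
    assert (inner.abs() < 1e-9).all()


def test_delta_k_zero_sd_excluded_from_argmax():
    runs = {
        1: [-1000.0, -1000.0],
        2: [-500.0, -500.0],      # sd 0 -> undefined
        3: [-460.0, -440.0],
        4: [-445.0, -425.0],
    }
    out = evanno_delta_k(runs)
    assert math.isnan(out.table.loc[2, "delta_k"])
    assert out.optimal_k == 3


def test_delta_k_input_validation():
    with pytest.raises(ValueError):
        evanno_delta_k({1: [-10.0, -9.0], 2: [-8.0, -7.0]})  # only 2 K values
    with pytest.raises(ValueError):
        evanno_delta_k({1: [-10.0], 2: [-8.0], 3: [-7.0]})  # 1 replicate
    with pytest.raises(ValueError):
        evanno_delta_k({1: [-1.0, -1.0], 3: [-1.0, -1.0], 4: [-1.0, -1.0]})


def test_delta_k_recovers_planted_knee(rng):
    hits = 0
    for _ in range(30):
        planted = int(rng.integers(2, 7))
        runs = sd.simulate_delta_k_table(rng, planted_k=planted)
        if evanno_delta_k(runs).optimal_k == planted:
            hits += 1
    assert hits == 30


# ---------------------------------------------------------------------------
# distance matrix plumbing
# ---------------------------------------------------------------------------

def test_population_distance_matrix_is_valid():
    m, truth = _three_pop_matrix()
    dm = nei_distance_matrix(m, truth.assignments)
    assert sorted(dm.labels) == ["pop1", "pop2", "pop3"]
    assert np.all(dm.values >= 0)


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[1.0, 0.0], [0.0, 0.0]]))
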