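import numpy as np
import pytest

from epitree.core_data import (
    FeatureAnnotation,
    FeatureMatrix,
    PhenotypeVector,
    ValidationError,
)
from epitree.irf_screen import (
    CandidateInteraction,
    PathSet,
    ScreenParams,
    expand_pairwise_top,
    extract_class1_paths,
    filter_cross_chromosome,
    fit_weighted_forest,
    gini_importance,
    merge_candidates,
    random_intersection_trees,
    run_irf,
    stability_scores,
    two_step_screen,
)
from epitree.tree_models import Interaction
from tests.conftest import make_genotypes


def _separable(n=600, p=5, seed=0):
    r = np.random.default_rng(seed)
    X = r.normal(size=(n, p))
    y = (X[:, 0] > 0).astype(int)
    return X, y


# ---------------------------------------------------------------------------
# forests
# ---------------------------------------------------------------------------

def test_uniform_weights_act_like_plain_rf():
    from sklearn.metrics import roc_auc_score

    X, y = _separable()
    forest = fit_weighted_forest(X, y, n_trees=30, seed=1)
    auc = roc_auc_score(y, forest.predict_proba(X))
    assert auc >= 0.95


def test_degenerate_weight_forces_single_feature():
    X, y = _separable(p=4, seed=2)
    w = np.array([0.0, 0.0, 1.0, 0.0])
    forest = fit_weighted_forest(X, y, feature_weights=w, n_trees=10, seed=3)
    for tree in forest.trees:
        assert tree.features_used() <= {"x2"}
    with pytest.raises(ValidationError):
        fit_weighted_forest(X, y, feature_weights=np.zeros(4))


def test_forest_determinism():
    X, y = _separable(seed=4)
    f1 = fit_weighted_forest(X, y, n_trees=1, seed=11)
    f2 = fit_weighted_forest(X, y, n_trees=1, seed=11)
    t1, t2 = f1.trees[0], f2.trees[0]
    np.testing.assert_array_equal(t1.feature, t2.feature)
    np.testing.assert_array_equal(t1.threshold, t2.threshold)
    np.testing.assert_array_equal(t1.value, t2.value)


def test_forest_respects_min_leaf_and_depth():
    X, y = _separable(n=500, seed=5)
    forest = fit_weighted_forest(X, y, n_trees=5, min_leaf=40, max_depth=3,
                                 seed=0)
    for t in forest.trees:
        leaves = t.leaf_ids()
        assert t.n_samples[leaves].min() >= 40
        # depth bound: no path can have more than 3 splits
        depth = np.zeros(t.n_nodes, dtype=int)
        for node in range(t.n_nodes):
            if t.feature[node] >= 0:
                depth[t.left[node]] = depth[node] + 1
                depth[t.right[node]] = depth[node] + 1
        assert depth.max() <= 3


def test_gini_importance_concentrates_and_ignores_unused():
    X, y = _separable(p=4, seed=6)
    w = np.array([0.0, 0.0, 1.0, 0.0])
    forest = fit_weighted_forest(X, y, feature_weights=w, n_trees=10, seed=1)
    imp = gini_importance(forest)
    assert imp[2] == pytest.approx(1.0)
    assert imp[0] == imp[1] == imp[3] == 0.0
    assert imp.sum() == pytest.approx(1.0)


def test_gini_importance_roughly_uniform_on_noise():
    r = np.random.default_rng(7)
    X = r.normal(size=(2000, 100))
    y = r.integers(0, 2, 2000)
    forest = fit_weighted_forest(X, y, n_trees=300, min_leaf=50, seed=2)
    imp = gini_importance(forest)
    assert imp.max() / max(imp.min(), 1e-12) < 5


# ---------------------------------------------------------------------------
# iRF iterations
# ---------------------------------------------------------------------------

def test_irf_single_iteration_is_plain_rf():
    X, y = _separable(seed=8)
    f_plain = fit_weighted_forest(X, y, n_trees=5, seed=21)
    f_irf, imp = run_irf(X, y, n_iter=1, forest_params={"n_trees": 5}, seed=21)
    np.testing.assert_array_equal(f_plain.trees[0].feature,
                                  f_irf.trees[0].feature)
    assert imp.sum() == pytest.approx(1.0)


def test_irf_iterations_concentrate_on_planted_pair():
    hits = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        n, p = 800, 100
        X = r.binomial(2, 0.3, size=(n, p)).astype(float)
        active = (X[:, 0] >= 1) & (X[:, 1] >= 1)
        y = (r.random(n) < np.where(active, 0.85, 0.25)).astype(int)
        _, imp1 = run_irf(X, y, n_iter=1, forest_params={"n_trees": 25},
                          seed=seed)
        _, imp3 = run_irf(X, y, n_iter=3, forest_params={"n_trees": 25},
                          seed=seed)
        hits += imp3[:2].sum() > imp1[:2].sum()
    assert hits >= 9


# ---------------------------------------------------------------------------
# path extraction
# ---------------------------------------------------------------------------

def _brute_force_paths(tree):
    """Independent recursive traversal oracle."""
    out = []

    def rec(node, feats):
        f = tree.feature[node]
        if f < 0:
            if tree.value[node] > 0.5 and feats and tree.n_pos[node] > 0:
                out.append((frozenset(feats), int(tree.n_pos[node])))
            return
        rec(tree.left[node], feats | {tree.feature_ids[f]})
        rec(tree.right[node], feats | {tree.feature_ids[f]})

    rec(0, frozenset())
    return sorted(out, key=lambda t: (sorted(t[0]), t[1]))


def test_path_extraction_matches_traversal_oracle():
    for seed in range(10):
        r = np.random.default_rng(seed)
        X = r.normal(size=(300, 4))
        y = (X[:, 0] * X[:, 1] > 0).astype(int)
        forest = fit_weighted_forest(X, y, n_trees=3, min_leaf=20, seed=seed)
        got = sorted(
            [(p.features, int(p.weight)) for p in extract_class1_paths(forest)],
            key=lambda t: (sorted(t[0]), t[1]),
        )
        expected = sorted(
            [pp for t in forest.trees for pp in _brute_force_paths(t)],
            key=lambda t: (sorted(t[0]), t[1]),
        )
        assert got == expected


def test_all_control_forest_yields_no_paths():
    r = np.random.default_rng(3)
    X = r.normal(size=(100, 2))
    forest = fit_weighted_forest(X, np.zeros(100, dtype=int), n_trees=3, seed=0)
    assert extract_class1_paths(forest) == []


# ---------------------------------------------------------------------------
# random intersection trees
# ---------------------------------------------------------------------------

def test_rit_identical_paths_single_candidate():
    paths = [PathSet(frozenset({"A", "B"}), 3.0)] * 20
    cands = random_intersection_trees(paths, n_rit=50, seed=0)
    assert len(cands) == 1
    assert cands[0].interaction.key == ("A", "B")
    assert cands[0].prevalence == pytest.approx(1.0)


def test_rit_threshold_above_one_empties_output():
    paths = [PathSet(frozenset({"A", "B"}), 1.0)] * 5
    assert random_intersection_trees(paths, min_prevalence=1.01, seed=0) == []


def test_rit_outputs_are_subsets_of_some_input_path():
    r = np.random.default_rng(9)
    universe = ["A", "B", "C", "D", "E"]
    paths = [
        PathSet(frozenset(r.choice(universe, size=r.integers(2, 5),
                                   replace=False)), float(r.integers(1, 6)))
        for _ in range(40)
    ]
    cands = random_intersection_trees(paths, n_rit=100, min_prevalence=0.0,
                                      seed=1)
    inputs = [p.features for p in paths]
    for c in cands:
        s = set(c.interaction.feature_ids)
        assert any(s <= inp for inp in inputs)


def rit_survival_oracle(path_dist, depth):
    """Exact distribution of an intersection of (depth + 1) iid path draws
    over a small feature universe, by subset dynamic programming."""
    universe = sorted({f for s in path_dist for f in s})
    bit = {f: 1 << i for i, f in enumerate(universe)}
    to_mask = lambda s: sum(bit[f] for f in s)
    m = 1 << len(universe)
    base = np.zeros(m)
    for s, prob in path_dist.items():
        base[to_mask(s)] += prob
    cur = base.copy()
    for _ in range(depth):
        nxt = np.zeros(m)
        for s in range(m):
            if cur[s] == 0:
                continue
            for p in range(m):
                if base[p] == 0:
                    continue
                nxt[s & p] += cur[s] * base[p]
        cur = nxt
    out = {}
    for mask in range(1, m):
        feats = frozenset(f for f in universe if mask & bit[f])
        out[feats] = cur[mask]
    return out


def test_rit_matches_survival_oracle_small():
    path_dist = {
        frozenset({"A", "B"}): 0.5,
        frozenset({"A", "B", "C"}): 0.3,
        frozenset({"D"}): 0.2,
    }
    depth = 2
    oracle = rit_survival_oracle(path_dist, depth)
    paths = [PathSet(s, w) for s, w in path_dist.items()]
    cands = random_intersection_trees(paths, depth=depth, n_rit=2000,
                                      min_prevalence=0.0, seed=5)
    got = {c.interaction.key: c.prevalence for c in cands}
    assert abs(got[("A", "B")] - oracle[frozenset({"A", "B"})]) < 0.05
    # {A,B,C} survives only if all depth+1 draws are the ABC path
    assert abs(got.get(("A", "B", "C"), 0.0) - 0.3 ** (depth + 1)) < 0.02


# ---------------------------------------------------------------------------
# stability, expansion, filtering
# ---------------------------------------------------------------------------

def test_stability_of_deterministic_signal_is_one():
    r = np.random.default_rng(11)
    n = 600
    X = r.binomial(2, 0.4, size=(n, 6)).astype(float)
    y = ((X[:, 0] >= 1) & (X[:, 1] >= 1)).astype(int)
    params = ScreenParams(n_iter=2, n_trees=10, n_rit=50, n_bootstrap=8)
    cands = stability_scores(X, y, params, n_bootstrap=8, seed=1)
    top = {c.interaction.key: c.stability for c in cands}
    assert top.get(("x0", "x1")) == pytest.approx(1.0)
    # superset matching can only raise stabilities
    sup = {c.interaction.key: c.stability
           for c in stability_scores(X, y, params, n_bootstrap=8, seed=1,
                                     match="superset")}
    for key, stab in top.items():
        assert sup.get(key, 0.0) >= stab
    with pytest.raises(ValueError):
        stability_scores(X, y, params, n_bootstrap=1)


def test_stability_threshold_is_strict():
    # recovered in exactly half the replicates -> excluded at threshold 0.5
    assert 25 / 50 <= 0.5  # documents the "> 0.5" convention checked below
    r = np.random.default_rng(12)
    X = r.normal(size=(200, 3))
    y = r.integers(0, 2, 200)
    params = ScreenParams(n_iter=1, n_trees=5, n_rit=30, n_bootstrap=4)
    for c in stability_scores(X, y, params, n_bootstrap=4, seed=0):
        assert c.stability > 0.5


def _annot(entries):
    return {e[0]: FeatureAnnotation(*e) for e in entries}


def test_pairwise_expansion_combinatorics():
    feats = [f"g{i}" for i in range(50)]
    annot = _annot([(f, f"chr{i + 1}", 1, 2) for i, f in enumerate(feats)])
    imp = np.linspace(1, 0.1, 50)
    pairs = expand_pairwise_top(imp, annot, feats, k=50)
    assert len(pairs) == 50 * 49 // 2  # 1225, all chromosomes distinct
    annot3 = _annot([("a", "chr16", 1, 2), ("b", "chr16", 5, 6),
                     ("c", "chr2", 1, 2)])
    pairs3 = expand_pairwise_top([0.5, 0.3, 0.2], annot3, ["a", "b", "c"], k=3)
    assert {p.interaction.key for p in pairs3} == {("a", "c"), ("b", "c")}


def test_merge_keeps_rit_prevalence_on_duplicates():
    rit = [CandidateInteraction(Interaction(("a", "b")), prevalence=0.4)]
    exp = [CandidateInteraction(Interaction(("a", "b")),
                                source="pairwise_expansion"),
           CandidateInteraction(Interaction(("a", "c")),
                                source="pairwise_expansion")]
    merged = merge_candidates(rit, exp)
    assert len(merged) == 2
    by_key = {c.interaction.key: c for c in merged}
    assert by_key[("a", "b")].source == "rit"
    assert by_key[("a", "b")].prevalence == 0.4


def test_cross_chromosome_filter():
    annot = _annot([("a", "chr20", 1, 2), ("b", "chr16", 1, 2),
                    ("c", "chr16", 9, 10)])
    cands = [
        CandidateInteraction(Interaction(("a", "b"))),
        CandidateInteraction(Interaction(("a", "b", "c"))),  # two on chr16
    ]
    kept = filter_cross_chromosome(cands, annot)
    assert [c.interaction.key for c in kept] == [("a", "b")]
    assert filter_cross_chromosome([], annot) == []
    with pytest.raises(KeyError):
        filter_cross_chromosome(
            [CandidateInteraction(Interaction(("a", "zz")))], annot)


# ---------------------------------------------------------------------------
# two-step screen
# ---------------------------------------------------------------------------

class _AuditedMatrix(FeatureMatrix):
    """Records every sample id requested from it."""

    requested: list = []

    def take_samples(self, sample_ids):
        ids = [str(s) for s in sample_ids]
        _AuditedMatrix.requested.extend(ids)
        return super().take_samples(ids)


def _small_two_step_inputs(seed=0):
    from epitree.core_data import WeightMap
    from epitree.synthetic import (
        SimulationSpec, gene_annotation_from_weights, simulate_gene_weights,
        simulate_genotypes,
    )

    spec = SimulationSpec(n_samples=700, n_snps=40, n_chromosomes=4,
                          maf=0.3, seed=seed)
    geno, snp_annot = simulate_genotypes(spec)
    weights = simulate_gene_weights(snp_annot, n_genes=8, snps_per_gene=2,
                                    w_dom=0.8, seed=seed + 1)
    gene_annot = gene_annotation_from_weights(weights, snp_annot)
    from epitree.core_data import aggregate_genes

    expr, _ = aggregate_genes(geno, weights)
    g1, g2 = "G1", "G5"  # different chromosomes by construction
    assert gene_annot[g1].chromosome != gene_annot[g2].chromosome
    r = np.random.default_rng(seed + 2)
    u = expr.column(g1) > np.median(expr.column(g1))
    v = expr.column(g2) > np.median(expr.column(g2))
    y = (r.random(geno.n_samples) < np.where(u & v, 0.85, 0.2)).astype(int)
    pheno = PhenotypeVector(geno.sample_ids, y)
    annot = {**snp_annot, **gene_annot}
    return geno, pheno, annot, weights


def test_two_step_screen_never_touches_test_samples():
    from epitree.core_data import split_train_test

    geno, pheno, annot, weights = _small_two_step_inputs()
    audited = _AuditedMatrix(geno.sample_ids, geno.feature_ids, geno.values,
                             geno.feature_kind)
    _AuditedMatrix.requested = []
    split = split_train_test(geno.sample_ids, 0.3, seed=1, pheno=pheno)
    params = ScreenParams(n_iter=2, n_trees=10, n_rit=50, n_bootstrap=4,
                          top_k=4)
    result = two_step_screen(audited, pheno, annot, weights, split,
                             params=params, seed=3)
    assert set(_AuditedMatrix.requested) <= set(split.train_ids)
    assert result.status in ("ok", "no candidates", "no snp candidates")


def test_two_step_screen_recovers_planted_gene_pair():
    geno, pheno, annot, weights = _small_two_step_inputs(seed=5)
    from epitree.core_data import split_train_test

    split = split_train_test(geno.sample_ids, 0.3, seed=2, pheno=pheno)
    params = ScreenParams(n_iter=2, n_trees=15, n_rit=100, n_bootstrap=8,
                          top_k=4)
    result = two_step_screen(geno, pheno, annot, weights, split,
                             params=params, seed=4)
    keys = {c.interaction.key for c in result.gene_candidates}
    assert ("G1", "G5") in keys


def test_two_step_screen_propagates_aggregation_errors():
    from epitree.core_data import WeightMap, split_train_test

    geno, pheno, annot, _ = _small_two_step_inputs(seed=6)
    bad = WeightMap.from_entries([("absent_snp", "G1", 1.0)])
    split = split_train_test(geno.sample_ids, 0.3, seed=0, pheno=pheno)
    with pytest.raises(ValidationError, match="gene aggregation stage"):
        two_step_screen(geno, pheno, annot, bad, split)
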