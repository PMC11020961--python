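"""Interaction discovery on training data.

Pipeline: iterated feature-weighted random forests (iRF) -> class-1
decision-path extraction -> random intersection trees (RIT) -> bootstrap
stability scores -> top-k Gini pairwise expansion -> cross-chromosome /
LD filtering, composed into the two-step gene -> variant screen.

Screening only ever sees training samples; candidates are handed to
PCS inference, which evaluates them on the hold-out test set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from epitree._forest import _grow_tree
from epitree.core_data import (
    Annotation,
    FeatureMatrix,
    PhenotypeVector,
    ValidationError,
    aggregate_genes,
    align,
    ld_r2,
    select_window_snps,
)
from epitree.tree_models import Interaction, TreeModel, TuningParams, _as_array

logger = logging.getLogger("epitree")


@dataclass
class Forest:
    """Feature-weighted random forest (list of flat-array trees)."""

    trees: list
    feature_weights: np.ndarray
    feature_ids: list

    def predict_proba(self, X, feature_ids=None) -> np.ndarray:
        Xa, fids = _as_array(X, feature_ids)
        pos = {f: j for j, f in enumerate(fids)}
        cols = [pos[f] for f in self.feature_ids]
        Xa = Xa[:, cols]
        acc = np.zeros(len(Xa))
        for t in self.trees:
            acc += t.predict(Xa)
        return acc / len(self.trees)


@dataclass(frozen=True)
class PathSet:
    """Distinct features on one class-1 root-to-leaf path, with sampling
    weight equal to the leaf's class-1 training-sample count."""

    features: frozenset
    weight: float

    def __post_init__(self):
        if not self.features:
            raise ValidationError("empty path set")
        if self.weight <= 0:
            raise ValidationError("path weight must be > 0")


@dataclass
class CandidateInteraction:
    interaction: Interaction
    prevalence: float | None = None
    stability: float | None = None
    source: str = "rit"


def fit_weighted_forest(X, y, feature_weights=None, n_trees: int = 500,
                        mtry: int | None = None, min_leaf: int = 5,
                        max_depth: int = 30, seed: int = 0,
                        feature_ids=None) -> Forest:
    """RF with bootstrap-per-tree and Gini splits, except that the mtry
    candidate features at each split are drawn without replacement with
    probability proportional to ``feature_weights``.  Uniform weights give
    an ordinary random forest."""
    Xa, fids = _as_array(X, feature_ids)
    y = np.asarray(y).astype(np.int64)
    n, p = Xa.shape
    if feature_weights is None:
        feature_weights = np.full(p, 1.0 / p)
    w = np.asarray(feature_weights, dtype=float)
    if w.shape != (p,) or (w < 0).any():
        raise ValidationError("feature weights must be non-negative, length p")
    if w.sum() <= 0:
        raise ValidationError("all-zero feature weights")
    w = w / w.sum()
    if mtry is None:
        mtry = int(math.ceil(math.sqrt(p)))
    mtry = max(1, min(mtry, p))
    max_nodes = 2 * max(n // max(min_leaf, 1), 1) + 3
    rng = np.random.default_rng(seed)
    trees = []
    Xc = np.ascontiguousarray(Xa)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        Xb = Xc[boot]
        yb = y[boot]
        feat = np.empty(max_nodes, dtype=np.int64)
        thr = np.empty(max_nodes, dtype=np.float64)
        left = np.empty(max_nodes, dtype=np.int64)
        right = np.empty(max_nodes, dtype=np.int64)
        value = np.empty(max_nodes, dtype=np.float64)
        n_samples = np.empty(max_nodes, dtype=np.int64)
        n_pos = np.empty(max_nodes, dtype=np.int64)
        imp = np.zeros(p, dtype=np.float64)
        count = _grow_tree(Xb, yb, w, mtry, min_leaf, max_depth, tree_seed,
                           feat, thr, left, right, value, n_samples, n_pos,
                           imp)
        trees.append(TreeModel(
            feature=feat[:count].copy(), threshold=thr[:count].copy(),
            left=left[:count].copy(), right=right[:count].copy(),
            value=value[:count].copy(), n_samples=n_samples[:count].copy(),
            feature_ids=fids, kind="classification",
            n_pos=n_pos[:count].copy(),
            tuning=TuningParams(max_depth=max_depth, min_leaf=min_leaf),
        ))
        trees[-1]._importance = imp  # per-tree Gini impurity decrease
    return Forest(trees=trees, feature_weights=w, feature_ids=fids)


def gini_importance(forest: Forest) -> np.ndarray:
    """Mean total Gini impurity decrease per feature, normalized to sum 1.

    A forest with no splits at all falls back to uniform importance."""
    p = len(forest.feature_ids)
    acc = np.zeros(p)
    for t in forest.trees:
        acc += getattr(t, "_importance", 0.0)
    total = acc.sum()
    if total <= 0:
        logger.warning("gini_importance: no splits in forest; uniform fallback")
        return np.full(p, 1.0 / p)
    return acc / total


def run_irf(X, y, n_iter: int = 3, forest_params: dict | None = None,
            seed: int = 0, feature_ids=None):
    """Iterative RF: iteration 1 is uniform-weighted; each subsequent
    iteration reuses the previous iteration's Gini importances as split
    sampling weights.  Returns (final forest, final importance)."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    Xa, fids = _as_array(X, feature_ids)
    params = dict(forest_params or {})
    weights = None
    forest = None
    for it in range(n_iter):
        forest = fit_weighted_forest(
            Xa, y, feature_weights=weights, seed=seed + it,
            feature_ids=fids, **params,
        )
        weights = gini_importance(forest)
    return forest, weights


def extract_class1_paths(forest: Forest, X_train=None, y_train=None) -> list:
    """Feature sets of root-to-leaf paths ending in class-1 leaves
    (predicted probability > 0.5), weighted by the leaf's class-1 count.

    By default counts come from each tree's own bootstrap sample; passing
    ``X_train, y_train`` recounts leaf membership on that data instead.
    """
    paths = []
    if X_train is not None and y_train is not None:
        Xa, _ = _as_array(X_train, forest.feature_ids)
        y = np.asarray(y_train)
    for t in forest.trees:
        if X_train is not None and y_train is not None:
            leaf_of = t.apply(Xa)
            pos_count = np.bincount(
                leaf_of[y == 1], minlength=t.n_nodes
            )
        else:
            pos_count = t.n_pos
        # collect features along each root-to-leaf path
        stack = [(0, frozenset())]
        while stack:
            node, feats = stack.pop()
            f = t.feature[node]
            if f < 0:
                if t.value[node] > 0.5 and feats and pos_count[node] > 0:
                    paths.append(PathSet(feats, float(pos_count[node])))
                continue
            feats = feats | {t.feature_ids[f]}
            stack.append((t.left[node], feats))
            stack.append((t.right[node], feats))
    if not paths:
        logger.warning("extract_class1_paths: no class-1 leaves in forest")
    return paths


def random_intersection_trees(paths: Sequence[PathSet], depth: int = 5,
                              n_child: int = 2, n_rit: int = 500,
                              min_prevalence: float = 0.1,
                              seed: int = 0) -> list:
    """Random intersection trees over weighted path sets.

    Each RIT node samples one path set (probability proportional to its
    weight) and intersects it with its parent's set (the root keeps its
    own sample); the non-empty depth-``depth`` leaf sets of all ``n_rit``
    trees are candidates.  Prevalence of a set is the fraction of all RIT
    leaves producing exactly that set.  Sets of size >= 2 with prevalence
    >= ``min_prevalence`` are returned, deduplicated.
    """
    if not paths:
        raise ValidationError("empty path collection")
    rng = np.random.default_rng(seed)
    weights = np.array([p.weight for p in paths], dtype=float)
    prob = weights / weights.sum()
    nodes_per_tree = (n_child ** (depth + 1) - 1) // (n_child - 1) \
        if n_child > 1 else depth + 1
    n_leaves_per_tree = n_child ** depth
    total_leaves = n_rit * n_leaves_per_tree
    draws = rng.choice(len(paths), size=(n_rit, nodes_per_tree), p=prob)
    counts: dict = {}
    for r in range(n_rit):
        row = draws[r]
        ptr = 1
        # breadth-first: level sets start from the root's own sample
        level = [paths[row[0]].features]
        for _ in range(depth):
            nxt = []
            for s in level:
                for _c in range(n_child):
                    inter = s & paths[row[ptr]].features if s else s
                    ptr += 1
                    nxt.append(inter)
            level = nxt
        for s in level:
            if s:
                counts[s] = counts.get(s, 0) + 1
    out = []
    for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0])))):
        prevalence = c / total_leaves
        if len(s) >= 2 and prevalence >= min_prevalence:
            out.append(CandidateInteraction(
                interaction=Interaction(sorted(s)), prevalence=prevalence,
                source="rit",
            ))
    return out


@dataclass
class ScreenParams:
    """Hyperparameters of one screening pass (forest + RIT + stability)."""

    n_iter: int = 3
    n_trees: int = 500
    mtry: int | None = None
    min_leaf: int = 5
    max_depth: int = 30
    rit_depth: int = 5
    n_child: int = 2
    n_rit: int = 500
    min_prevalence: float = 0.1
    n_bootstrap: int = 50
    stability_threshold: float = 0.5
    top_k: int = 50

    def forest_params(self) -> dict:
        return {
            "n_trees": self.n_trees, "mtry": self.mtry,
            "min_leaf": self.min_leaf, "max_depth": self.max_depth,
        }


def _single_run_candidates(Xa, y, fids, params: ScreenParams, seed: int):
    forest, importance = run_irf(
        Xa, y, n_iter=params.n_iter, forest_params=params.forest_params(),
        seed=seed, feature_ids=fids,
    )
    paths = extract_class1_paths(forest)
    if not paths:
        return forest, importance, []
    cands = random_intersection_trees(
        paths, depth=params.rit_depth, n_child=params.n_child,
        n_rit=params.n_rit, min_prevalence=params.min_prevalence,
        seed=seed + 7919,
    )
    return forest, importance, cands


def stability_scores(X, y, pipeline_params: ScreenParams | None = None,
                     n_bootstrap: int = 50, threshold: float = 0.5,
                     seed: int = 0, feature_ids=None,
                     match: str = "exact") -> list:
    """Bootstrap stability of the iRF + RIT search.

    Reruns the whole search on ``n_bootstrap`` resamples (with
    replacement) of the training samples; an interaction's stability is
    the fraction of replicates recovering that feature set -- exactly by
    default, or via any superset with ``match="superset"``.  Only
    interactions with stability > ``threshold`` are returned.
    """
    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2")
    if match not in ("exact", "superset"):
        raise ValueError(f"unknown match mode {match!r}")
    params = pipeline_params or ScreenParams()
    Xa, fids = _as_array(X, feature_ids)
    y = np.asarray(y)
    n = len(y)
    rng = np.random.default_rng(seed)
    replicate_keys = []
    for b in range(n_bootstrap):
        boot = rng.integers(0, n, size=n)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        _, _, cands = _single_run_candidates(
            Xa[boot], y[boot], fids, params, rep_seed
        )
        replicate_keys.append({c.interaction.key for c in cands})
    recovered: dict = {}
    seen = sorted({k for keys in replicate_keys for k in keys})
    for key in seen:
        if match == "exact":
            cnt = sum(key in keys for keys in replicate_keys)
        else:
            kset = set(key)
            cnt = sum(
                any(kset <= set(other) for other in keys)
                for keys in replicate_keys
            )
        recovered[key] = cnt
    out = []
    for key, cnt in sorted(recovered.items(), key=lambda kv: (-kv[1], kv[0])):
        stab = cnt / n_bootstrap
        if stab > threshold:
            out.append(CandidateInteraction(
                interaction=Interaction(key), stability=stab, source="rit",
            ))
    return out


def expand_pairwise_top(importance, annot: Annotation, feature_ids,
                        k: int = 50) -> list:
    """All inter-chromosome unordered pairs among the top-k features by
    Gini importance (ties broken lexicographically)."""
    fids = [str(f) for f in feature_ids]
    annotated = [f for f in fids if f in annot]
    if len(annotated) < 2:
        return []
    imp = {f: w for f, w in zip(fids, np.asarray(importance, dtype=float))}
    top = sorted(annotated, key=lambda f: (-imp[f], f))[:k]
    out = []
    for i in range(len(top)):
        for j in range(i + 1, len(top)):
            a, b = top[i], top[j]
            if annot[a].chromosome != annot[b].chromosome:
                out.append(CandidateInteraction(
                    interaction=Interaction(sorted((a, b))),
                    source="pairwise_expansion",
                ))
    return out


def merge_candidates(rit: Sequence[CandidateInteraction],
                     expanded: Sequence[CandidateInteraction]) -> list:
    """Union by feature set; a pair already found by RIT keeps its RIT
    prevalence/stability."""
    seen = {}
    for c in rit:
        seen[c.interaction.key] = c
    for c in expanded:
        seen.setdefault(c.interaction.key, c)
    return sorted(seen.values(), key=lambda c: c.interaction.key)


def filter_cross_chromosome(cands: Sequence[CandidateInteraction],
                            annot: Annotation,
                            genotypes: FeatureMatrix | None = None) -> list:
    """Keep interactions whose features lie pairwise on distinct
    chromosomes; same-chromosome candidates are removed (linkage mimics
    epistasis) and logged with their max pairwise LD r^2 when genotype
    data is available."""
    kept = []
    for c in cands:
        feats = c.interaction.feature_ids
        for f in feats:
            if f not in annot:
                raise KeyError(f"feature {f!r} has no annotation")
        chroms = [annot[f].chromosome for f in feats]
        if len(set(chroms)) == len(chroms):
            kept.append(c)
        else:
            detail = ""
            if genotypes is not None:
                r2 = [
                    ld_r2(genotypes, a, b)
                    for i, a in enumerate(feats) for b in feats[i + 1:]
                    if a in genotypes.feature_ids and b in genotypes.feature_ids
                ]
                if r2:
                    detail = f" (max pairwise LD r2 = {max(r2):.3f})"
            logger.info("filter_cross_chromosome: removed %s%s",
                        c.interaction, detail)
    return kept


@dataclass
class ScreenResult:
    gene_candidates: list
    snp_candidates: list
    gene_importance: dict
    snp_importance: dict
    status: str = "ok"


def _screen_one_level(Xa, y, fids, annot, params: ScreenParams, seed: int,
                      genotypes=None):
    forest, importance, rit_cands = _single_run_candidates(
        Xa, y, fids, params, seed
    )
    prevalence = {c.interaction.key: c.prevalence for c in rit_cands}
    stable = stability_scores(
        Xa, y, pipeline_params=params, n_bootstrap=params.n_bootstrap,
        threshold=params.stability_threshold, seed=seed + 104729,
        feature_ids=fids,
    )
    for c in stable:
        c.prevalence = prevalence.get(c.interaction.key)
    expanded = expand_pairwise_top(importance, annot, fids, k=params.top_k)
    merged = merge_candidates(stable, expanded)
    filtered = filter_cross_chromosome(merged, annot, genotypes=genotypes)
    return filtered, dict(zip(fids, importance))


def two_step_screen(snps: FeatureMatrix, pheno: PhenotypeVector,
                    annot: Annotation, weights, split,
                    params: ScreenParams | None = None,
                    seed: int = 0) -> ScreenResult:
    """Gene-level then variant-level candidate screening (training data
    only).

    Step 1 aggregates SNPs into gene scores and screens the gene
    features; step 2 restricts to SNPs within +/- 1MB of any gene in a
    surviving gene-level interaction and rescreens at the variant level.
    """
    params = params or ScreenParams()
    train_fm = snps.take_samples(split.train_ids)
    train_fm, train_ph = align(train_fm, pheno.take_samples(split.train_ids))
    try:
        expr, _dropped = aggregate_genes(train_fm, weights)
    except ValidationError as err:
        raise ValidationError(f"gene aggregation stage: {err}") from err
    gene_cands, gene_imp = _screen_one_level(
        expr.values, train_ph.y, expr.feature_ids, annot, params, seed,
    )
    if not gene_cands:
        logger.warning("two_step_screen: no gene-level candidates")
        return ScreenResult([], [], gene_imp, {}, status="no candidates")
    genes_in_cands = sorted({
        f for c in gene_cands for f in c.interaction.feature_ids
    })
    snp_ids = select_window_snps(train_fm, annot, genes_in_cands,
                                 window_bp=1_000_000)
    if len(snp_ids) < 2:
        logger.warning("two_step_screen: fewer than 2 SNPs in windows")
        return ScreenResult(gene_cands, [], gene_imp, {},
                            status="no snp candidates")
    snp_fm = train_fm.restrict(snp_ids)
    snp_cands, snp_imp = _screen_one_level(
        snp_fm.values, train_ph.y, snp_fm.feature_ids, annot, params,
        seed + 15485863, genotypes=snp_fm,
    )
    return ScreenResult(gene_cands, snp_cands, gene_imp, snp_imp)
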