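"""Pipeline orchestration: screen -> PCS inference -> report.

Everything is driven by a :class:`PipelineConfig`; every stage derives its
RNG seed deterministically from the master seed and the stage name, so a
manifest plus the inputs fully determine the outputs.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from epitree.core_data import (
    FeatureMatrix,
    PhenotypeVector,
    ValidationError,
    aggregate_genes,
    align,
    read_annotation,
    read_feature_matrix,
    read_phenotype,
    read_weights,
    split_train_test,
)
from epitree.irf_screen import ScreenParams, run_irf, two_step_screen
from epitree.pcs_inference import (
    bonferroni,
    logistic_lrt,
    pcs_pvalue,
    pcs_pvalue_gaussian,
)
from epitree.tree_models import (
    AdditiveTreeModel,
    Interaction,
    Partition,
    TreeModel,
    best_null_partition,
    fit_additive_trees,
    fit_probability_tree,
    predict_proba,
    select_tuning,
)

logger = logging.getLogger("epitree")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    genotypes: str = ""
    genotype_format: str = "tsv"
    phenotype: str = ""
    annotation: str = ""
    weights: str = ""
    out_dir: str = "epitree_run"
    truth: str = ""                    # optional simulation ground-truth JSON
    test_fraction: float = 2.0 / 15.0
    window_bp: int = 1_000_000
    alpha: float = 0.05
    B: int = 1000
    method: str = "monte_carlo"        # or "gaussian_approx"
    depth_grid_max: int = 8
    min_leaf: int | None = None
    global_bonferroni: bool = False
    screen: ScreenParams = field(default_factory=ScreenParams)
    seed: int = 0

    def validate(self):
        if not 0 < self.test_fraction < 1:
            raise ValidationError("test_fraction outside (0,1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha outside (0,1)")
        if self.B < 1:
            raise ValidationError("B must be >= 1")
        if self.method not in ("monte_carlo", "gaussian_approx"):
            raise ValidationError(f"unknown method {self.method!r}")


def test_interaction(interaction: Interaction, train_X: FeatureMatrix,
                     train_y: PhenotypeVector, test_X: FeatureMatrix,
                     test_y: PhenotypeVector, B: int = 1000,
                     method: str = "monte_carlo", seed: int = 0,
                     depth_grid=None, min_leaf=None,
                     with_logistic: bool = True) -> dict:
    """Full epiTree test of one candidate interaction.

    Tuning (shallowest CART using all features), null-partition search for
    d >= 3 (prediction accuracy on the test data selects the bipartition),
    model fits on training data, PCS p-value on the test data, and the
    pairwise logistic comparator.  Returns a flat result record.
    """
    fids = list(interaction.feature_ids)
    Xtr = train_X.restrict(fids)
    Xte = test_X.restrict(fids)
    ytr, yte = train_y.y, test_y.y
    tuning = select_tuning(Xtr, ytr, depth_grid=depth_grid, min_leaf=min_leaf)
    if interaction.order == 2:
        part = Partition(fids[:1], fids[1:])
    else:
        part = best_null_partition(Xtr, ytr, Xte, yte, tuning,
                                   feature_ids=fids)
    alt = fit_probability_tree(Xtr, ytr, tuning)
    null = fit_additive_trees(Xtr, ytr, part, tuning)
    if method == "gaussian_approx":
        res = pcs_pvalue_gaussian(null, alt, Xte, yte,
                                  interaction=interaction)
    else:
        res = pcs_pvalue(null, alt, Xte, yte, B=B, seed=seed,
                         interaction=interaction)
    row = {
        "interaction": str(interaction),
        "order": interaction.order,
        "partition": str(part),
        "ce_null": res.ce_null_test,
        "ce_alt": res.ce_alt_test,
        "pcs_p": res.p_value,
        "screened": res.screened,
        "B": res.B,
        "method": res.method,
        "seed": seed,
        "max_depth": tuning.max_depth,
        "all_features_used": tuning.all_features_used,
        "logistic_lrt_p": np.nan,
        "logistic_ce_null": np.nan,
        "logistic_ce_alt": np.nan,
    }
    if with_logistic and interaction.order == 2:
        comp = logistic_lrt(Xtr, ytr, Xte, yte)
        row.update(
            logistic_lrt_p=comp.p_value,
            logistic_ce_null=comp.ce_null_test,
            logistic_ce_alt=comp.ce_alt_test,
        )
    return row


def _results_table(candidates, train_X, train_y, test_X, test_y,
                   config: PipelineConfig, level: str) -> pd.DataFrame:
    rows = []
    for i, cand in enumerate(candidates):
        seed = stage_seed(config.seed, f"pcs:{level}:{cand.interaction}")
        row = test_interaction(
            cand.interaction, train_X, train_y, test_X, test_y,
            B=config.B, method=config.method, seed=seed,
            depth_grid=list(range(2, config.depth_grid_max + 1)),
            min_leaf=config.min_leaf,
        )
        row["level"] = level
        row["source"] = cand.source
        row["prevalence"] = cand.prevalence
        row["stability"] = cand.stability
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["pcs_p_bonf"] = bonferroni(df["pcs_p"])
        df = df.sort_values(["pcs_p", "interaction"]).reset_index(drop=True)
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full run: two-step screen on training data, PCS
    inference per candidate on test data, per-level Bonferroni, TSV/JSON
    reports plus a manifest under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        snps = read_feature_matrix(config.genotypes, config.genotype_format)
        pheno = read_phenotype(config.phenotype)
        annot = read_annotation(config.annotation)
        weights = read_weights(config.weights)
        snps, pheno = align(snps, pheno)

        stage = "split"
        split = split_train_test(
            snps.sample_ids, config.test_fraction,
            stage_seed(config.seed, "split"), pheno=pheno,
        )

        stage = "screen"
        screen = two_step_screen(
            snps, pheno, annot, weights, split, params=config.screen,
            seed=stage_seed(config.seed, "screen"),
        )
        _write_candidates(screen, annot, out / "candidates.tsv")

        stage = "inference"
        expr_all, _ = aggregate_genes(snps, weights)
        tables = {}
        for level, cands, fm in (
            ("gene", screen.gene_candidates, expr_all),
            ("snp", screen.snp_candidates, snps),
        ):
            tr_X = fm.take_samples(split.train_ids)
            te_X = fm.take_samples(split.test_ids)
            tr_y = pheno.take_samples(split.train_ids)
            te_y = pheno.take_samples(split.test_ids)
            tables[level] = _results_table(
                cands, tr_X, tr_y, te_X, te_y, config, level
            )
        if config.global_bonferroni:
            joint = pd.concat([t for t in tables.values() if not t.empty])
            if not joint.empty:
                adj = bonferroni(joint["pcs_p"])
                for level in tables:
                    mask = joint["level"] == level
                    if not tables[level].empty:
                        tables[level]["pcs_p_bonf"] = adj[mask.to_numpy()]

        for level, df in tables.items():
            df.to_csv(out / f"results_{level}.tsv", sep="\t", index=False,
                      float_format="%.10g")

        stage = "report"
        truth_cmp = None
        if config.truth:
            truth_cmp = _truth_comparison(tables, config)
            with open(out / "truth_comparison.json", "w") as fh:
                json.dump(truth_cmp, fh, indent=1)
        manifest = {
            "config": _config_dict(config),
            "stage_seeds": {
                s: stage_seed(config.seed, s) for s in ("split", "screen")
            },
            "n_train": len(split.train_ids),
            "n_test": len(split.test_ids),
            "n_gene_candidates": len(screen.gene_candidates),
            "n_snp_candidates": len(screen.snp_candidates),
            "bonferroni_divisors": {
                lvl: int(len(df)) for lvl, df in tables.items()
            },
            "status": screen.status,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return {
            "split": split, "screen": screen, "results": tables,
            "manifest": manifest, "truth_comparison": truth_cmp,
        }
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["screen"] = asdict(config.screen)
    return d


def _write_candidates(screen, annot, path) -> None:
    rows = []
    for level, cands in (("gene", screen.gene_candidates),
                         ("snp", screen.snp_candidates)):
        for c in cands:
            chroms = ";".join(
                annot[f].chromosome if f in annot else "?"
                for f in c.interaction.feature_ids
            )
            rows.append({
                "level": level,
                "interaction": str(c.interaction),
                "order": c.interaction.order,
                "source": c.source,
                "prevalence": c.prevalence,
                "stability": c.stability,
                "chromosomes": chroms,
            })
    pd.DataFrame(
        rows, columns=["level", "interaction", "order", "source",
                       "prevalence", "stability", "chromosomes"],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _truth_comparison(tables, config: PipelineConfig) -> dict:
    with open(config.truth) as fh:
        truth = json.load(fh)
    planted = set(truth.get("interacting", []))
    out = {"planted": sorted(planted)}
    for level, df in tables.items():
        hits = []
        for _, row in df.iterrows():
            feats = set(row["interaction"].split(";"))
            if feats == planted:
                hits.append({
                    "interaction": row["interaction"],
                    "pcs_p": float(row["pcs_p"]),
                    "pcs_p_bonf": float(row["pcs_p_bonf"]),
                    "significant": bool(row["pcs_p_bonf"] < config.alpha),
                })
        out[level] = hits
    return out


def depth_sensitivity(interaction: Interaction, train_X, train_y, test_X,
                      test_y, depths=range(2, 9), B: int = 200,
                      seed: int = 0, min_leaf=None) -> pd.DataFrame:
    """PCS p-value of one interaction refit at each fixed tree depth.

    The tuning rule picks the shallowest depth using all features; this
    harness shows whether a finding would persist at deeper trees rather
    than assuming stability with respect to the tuning parameters.
    """
    rows = []
    for depth in depths:
        row = test_interaction(
            interaction, train_X, train_y, test_X, test_y, B=B, seed=seed,
            depth_grid=[depth], min_leaf=min_leaf, with_logistic=False,
        )
        rows.append({"max_depth": depth, "pcs_p": row["pcs_p"],
                     "ce_null": row["ce_null"], "ce_alt": row["ce_alt"],
                     "screened": row["screened"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Prediction-accuracy evaluation and response surfaces
# ---------------------------------------------------------------------------

def evaluate_prediction(model_spec: str, train_X, train_y, test_X, test_y,
                        n_boot_ci: int = 1000, seed: int = 0,
                        irf_params: dict | None = None) -> dict:
    """Hold-out AUROC with a percentile bootstrap CI over test resamples.

    ``model_spec``: ``irf`` (this package's iterated forest),
    ``additive_logistic_l1`` (lasso-type logistic regression) or
    ``plain_rf`` (standard random forest).
    """
    from sklearn.metrics import roc_auc_score

    Xtr = train_X.values if isinstance(train_X, FeatureMatrix) else np.asarray(train_X)
    Xte = test_X.values if isinstance(test_X, FeatureMatrix) else np.asarray(test_X)
    ytr = train_y.y if isinstance(train_y, PhenotypeVector) else np.asarray(train_y)
    yte = test_y.y if isinstance(test_y, PhenotypeVector) else np.asarray(test_y)
    if len(np.unique(yte)) < 2:
        raise ValidationError("one-class test set")
    if model_spec == "irf":
        params = {"n_trees": 100, "min_leaf": 5}
        params.update(irf_params or {})
        forest, _ = run_irf(Xtr, ytr, n_iter=3, forest_params=params,
                            seed=seed)
        score = forest.predict_proba(Xte)
    elif model_spec == "additive_logistic_l1":
        from sklearn.linear_model import LogisticRegression

        est = LogisticRegression(
            solver="liblinear", C=1.0, l1_ratio=1.0, random_state=seed
        ).fit(Xtr, ytr)
        score = est.predict_proba(Xte)[:, 1]
    elif model_spec == "plain_rf":
        from sklearn.ensemble import RandomForestClassifier

        est = RandomForestClassifier(
            n_estimators=200, random_state=seed
        ).fit(Xtr, ytr)
        score = est.predict_proba(Xte)[:, 1]
    else:
        raise ValueError(f"unknown model_spec {model_spec!r}")
    auroc = float(roc_auc_score(yte, score))
    rng = np.random.default_rng(seed + 1)
    n = len(yte)
    boots = []
    for _ in range(n_boot_ci):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(yte[idx])) < 2:
            continue
        boots.append(roc_auc_score(yte[idx], score[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
    return {"model": model_spec, "auroc": auroc,
            "ci_low": float(lo), "ci_high": float(hi)}


def export_response_surface(models: dict, feature_pair, test_X, test_y,
                            grid_size: int = 25, min_bin: int = 5):
    """Grids of predicted penetrance for each fitted model over the two
    features' observed ranges, plus hexagonal-bin empirical case rates
    (bins holding fewer than ``min_bin`` test points suppressed).

    Returns (grid DataFrame, hexbin DataFrame).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fids = [str(f) for f in feature_pair]
    if len(fids) != 2:
        raise ValidationError("response surfaces are pairwise only")
    Xte = test_X.restrict(fids).values if isinstance(test_X, FeatureMatrix) \
        else np.asarray(test_X)
    yte = test_y.y if isinstance(test_y, PhenotypeVector) else np.asarray(test_y)
    a, b = Xte[:, 0], Xte[:, 1]
    ga = np.linspace(a.min(), a.max(), grid_size)
    gb = np.linspace(b.min(), b.max(), grid_size)
    AA, BB = np.meshgrid(ga, gb)
    grid_pts = np.column_stack([AA.ravel(), BB.ravel()])
    rows = []
    for name, model in models.items():
        if isinstance(model, (TreeModel, AdditiveTreeModel)):
            p = predict_proba(model, grid_pts, feature_ids=fids)
        elif callable(model):  # e.g. a fitted logistic model's predictor
            p = np.asarray(model(grid_pts), dtype=float)
        else:
            p = np.asarray(model.predict_proba(grid_pts))
            if p.ndim == 2:
                p = p[:, 1]
        for (xa, xb), pi in zip(grid_pts, p):
            rows.append({"model": name, "x1": xa, "x2": xb, "p": float(pi)})
    grid_df = pd.DataFrame(rows)

    fig, ax = plt.subplots()
    hb_rate = ax.hexbin(a, b, C=yte.astype(float), gridsize=grid_size,
                        reduce_C_function=np.mean, mincnt=min_bin)
    hb_count = ax.hexbin(a, b, gridsize=grid_size, mincnt=min_bin)
    offsets = hb_rate.get_offsets()
    rates = hb_rate.get_array()
    counts = hb_count.get_array()
    plt.close(fig)
    hex_df = pd.DataFrame({
        "x1": offsets[:, 0], "x2": offsets[:, 1],
        "case_rate": np.asarray(rates, dtype=float),
        "n": np.asarray(counts, dtype=float).astype(int),
    })
    hex_df = hex_df[hex_df["n"] >= min_bin].reset_index(drop=True)
    return grid_df, hex_df
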