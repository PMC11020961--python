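"""Repeatable simulation studies of the epiTree test's operating
characteristics.

Each study fixes its generating conditions once (sample sizes, penetrance
gaps, MAFs) and reports empirical rates computed by running the actual
pipeline components; they back both the test suite and the results
reproduction script.  Conditions:

- Type-I error: additive-on-logit truth (no epistasis), balanced n = 4000
  split 50/50, B = 200 bootstrap draws.
- Power/ranking: Boolean-AND penetrance (p_hi = 0.8, p_lo = 0.3, dominant
  coding, MAF 0.3), n = 4000, the true pair hidden among 19 decoy pairs.
- Comparator contrast: XOR of heterozygosity indicators at MAF 0.5 with
  penetrance 0.7 vs 0.3 -- a dominance-type epistasis whose product term
  has zero projection in a dosage-linear logistic model.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from epitree.pcs_inference import bonferroni, logistic_lrt
from epitree.pipeline import test_interaction
from epitree.synthetic import SimulationSpec, simulate_dataset
from epitree.tree_models import Interaction


def _sub_seed(rng):
    return int(rng.integers(0, 2**31 - 1))


def type_one_error_study(n_reps: int = 500, n_per_class: int = 2000,
                         B: int = 200, seed: int = 0) -> dict:
    """Empirical Pr(PCS p <= alpha) when the truth is additive on the
    logit scale (both features carry main effects, no interaction)."""
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_reps):
        s = _sub_seed(rng)
        spec = SimulationSpec(
            n_samples=3 * n_per_class, n_snps=2, maf=0.3,
            model="additive_null", interacting=("rs1", "rs2"),
            beta=0.4, beta0=0.0, seed=s,
        )
        d = simulate_dataset(spec, n_per_class=n_per_class,
                             test_fraction=0.5, seed=s)
        row = test_interaction(
            Interaction(("rs1", "rs2")), d.train_X, d.train_y, d.test_X,
            d.test_y, B=B, seed=_sub_seed(rng), with_logistic=False,
        )
        pvals.append(row["pcs_p"])
    pvals = np.array(pvals)
    return {
        "p_values": pvals,
        "rate_05": float(np.mean(pvals <= 0.05)),
        "rate_01": float(np.mean(pvals <= 0.01)),
        "n_reps": n_reps,
    }


def power_ranking_study(n_reps: int = 100, n_per_class: int = 2000,
                        n_decoys: int = 19, B: int = 500,
                        seed: int = 0) -> dict:
    """Boolean-AND power with Bonferroni over (1 + n_decoys) candidates,
    and the rate at which the true pair is ranked strictly smallest."""
    rng = np.random.default_rng(seed)
    n_snps = 2 + 2 * n_decoys
    detected = 0
    top_ranked = 0
    for _ in range(n_reps):
        s = _sub_seed(rng)
        spec = SimulationSpec(
            n_samples=3 * n_per_class, n_snps=n_snps, maf=0.3,
            model="boolean_and", interacting=("rs1", "rs2"),
            threshold=0.5, p_hi=0.8, p_lo=0.3, seed=s,
        )
        d = simulate_dataset(spec, n_per_class=n_per_class,
                             test_fraction=0.5, seed=s)
        pairs = [("rs1", "rs2")] + [
            (f"rs{3 + 2 * j}", f"rs{4 + 2 * j}") for j in range(n_decoys)
        ]
        pvals = []
        for pair in pairs:
            row = test_interaction(
                Interaction(pair), d.train_X, d.train_y, d.test_X, d.test_y,
                B=B, seed=_sub_seed(rng), with_logistic=False,
            )
            pvals.append(row["pcs_p"])
        adj = bonferroni(pvals)
        detected += adj[0] < 0.05
        top_ranked += pvals[0] < min(pvals[1:])
    return {
        "power": detected / n_reps,
        "top_rank_rate": top_ranked / n_reps,
        "n_candidates": 1 + n_decoys,
        "n_reps": n_reps,
    }


def gaussian_agreement_study(n_datasets: int = 10, n_per_class: int = 800,
                             B: int = 50_000, seed: int = 0) -> dict:
    """Monte-Carlo vs closed-form p-values on fixed seeded datasets whose
    signal strengths span weak to strong evidence."""
    from epitree.pcs_inference import pcs_pvalue, pcs_pvalue_gaussian
    from epitree.tree_models import (
        Partition, fit_additive_trees, fit_probability_tree, select_tuning,
    )

    rng = np.random.default_rng(seed)
    gaps = np.linspace(0.04, 0.30, n_datasets)
    diffs, p_mc_list, p_g_list = [], [], []
    for i in range(n_datasets):
        s = _sub_seed(rng)
        spec = SimulationSpec(
            n_samples=3 * n_per_class, n_snps=2, maf=0.4,
            model="boolean_and", interacting=("rs1", "rs2"), threshold=0.5,
            p_hi=0.45 + gaps[i], p_lo=0.45, seed=s,
        )
        d = simulate_dataset(spec, n_per_class=n_per_class,
                             test_fraction=0.5, seed=s)
        Xtr = d.train_X.restrict(["rs1", "rs2"])
        Xte = d.test_X.restrict(["rs1", "rs2"])
        tuning = select_tuning(Xtr, d.train_y.y)
        alt = fit_probability_tree(Xtr, d.train_y.y, tuning)
        null = fit_additive_trees(Xtr, d.train_y.y,
                                  Partition(["rs1"], ["rs2"]), tuning)
        mc = pcs_pvalue(null, alt, Xte, d.test_y.y, B=B, seed=_sub_seed(rng))
        ga = pcs_pvalue_gaussian(null, alt, Xte, d.test_y.y)
        diffs.append(abs(mc.p_value - ga.p_value))
        p_mc_list.append(mc.p_value)
        p_g_list.append(ga.p_value)
    return {
        "max_abs_diff": float(max(diffs)),
        "p_monte_carlo": p_mc_list,
        "p_gaussian": p_g_list,
    }


def screen_recovery_study(n_runs: int = 20, n_samples: int = 3000,
                          n_snps: int = 200, n_genes: int = 20,
                          seed: int = 0, n_trees: int = 15,
                          n_bootstrap: int = 50) -> dict:
    """Recovery rate of a planted gene-pair interaction through the full
    two-step screen (bootstrap stability > 0.5 included).

    The phenotype is Boolean-AND in two gene scores (median threshold,
    penetrance 0.8 vs 0.3) whose genes sit on different chromosomes; the
    forest is run at reduced size to keep the study at desk scale.
    """
    from epitree.core_data import (
        PhenotypeVector, aggregate_genes, split_train_test,
    )
    from epitree.irf_screen import ScreenParams, two_step_screen
    from epitree.synthetic import (
        gene_annotation_from_weights, simulate_gene_weights,
        simulate_genotypes,
    )

    rng = np.random.default_rng(seed)
    params = ScreenParams(
        n_iter=2, n_trees=n_trees, n_rit=100, n_bootstrap=n_bootstrap,
        min_prevalence=0.1, top_k=5,
    )
    hits = 0
    for _ in range(n_runs):
        s = _sub_seed(rng)
        spec = SimulationSpec(n_samples=n_samples, n_snps=n_snps,
                              n_chromosomes=10, maf=0.3, seed=s)
        geno, snp_annot = simulate_genotypes(spec)
        weights = simulate_gene_weights(
            snp_annot, n_genes=n_genes, snps_per_gene=3, w_dom=0.7,
            seed=s + 1,
        )
        gene_annot = gene_annotation_from_weights(weights, snp_annot)
        expr, _ = aggregate_genes(geno, weights)
        genes = sorted(gene_annot)
        g1 = genes[0]
        g2 = next(g for g in genes[1:]
                  if gene_annot[g].chromosome != gene_annot[g1].chromosome)
        r = np.random.default_rng(s + 2)
        u = expr.column(g1) > np.median(expr.column(g1))
        v = expr.column(g2) > np.median(expr.column(g2))
        y = (r.random(n_samples) < np.where(u & v, 0.8, 0.3)).astype(int)
        pheno = PhenotypeVector(geno.sample_ids, y)
        split = split_train_test(geno.sample_ids, 0.25, seed=s + 3,
                                 pheno=pheno)
        result = two_step_screen(
            geno, pheno, {**snp_annot, **gene_annot}, weights, split,
            params=params, seed=s + 4,
        )
        keys = {c.interaction.key for c in result.gene_candidates}
        hits += tuple(sorted((g1, g2))) in keys
    return {"recovery_rate": hits / n_runs, "n_runs": n_runs}


def logistic_calibration_study(n_reps: int = 500, n: int = 5000,
                               seed: int = 0) -> dict:
    """KS distance of logistic LRT p-values from uniform when the
    interaction coefficient is zero."""
    rng = np.random.default_rng(seed)
    pvals = []
    while len(pvals) < n_reps:
        r = np.random.default_rng(_sub_seed(rng))
        a = r.binomial(2, 0.4, n).astype(float)
        b = r.binomial(2, 0.4, n).astype(float)
        logit = -0.5 + 0.3 * a + 0.3 * b
        y = (r.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        X = np.column_stack([a, b])
        half = n // 2
        rec = logistic_lrt(X[:half], y[:half], X[half:], y[half:])
        if np.isfinite(rec.p_value):
            pvals.append(rec.p_value)
    ks = stats.kstest(pvals, "uniform").statistic
    return {"ks_distance": float(ks), "p_values": np.array(pvals)}


def xor_contrast_study(n_reps: int = 50, n_per_class: int = 2000,
                       B: int = 200, seed: int = 0) -> dict:
    """Dominance-type XOR: rate at which the PCS p-value is significant
    while the multiplicative-logit LRT is not."""
    rng = np.random.default_rng(seed)
    pcs_sig = 0
    contrast = 0
    for _ in range(n_reps):
        s = _sub_seed(rng)
        spec = SimulationSpec(
            n_samples=3 * n_per_class, n_snps=2, maf=0.5,
            model="boolean_xor", interacting=("rs1", "rs2"),
            indicator="heterozygous", p_hi=0.7, p_lo=0.3, seed=s,
        )
        d = simulate_dataset(spec, n_per_class=n_per_class,
                             test_fraction=0.5, seed=s)
        row = test_interaction(
            Interaction(("rs1", "rs2")), d.train_X, d.train_y, d.test_X,
            d.test_y, B=B, seed=_sub_seed(rng),
        )
        sig = row["pcs_p"] < 0.05
        pcs_sig += sig
        contrast += sig and row["logistic_lrt_p"] > 0.05
    return {
        "pcs_detection_rate": pcs_sig / n_reps,
        "contrast_rate": contrast / n_reps,
        "n_reps": n_reps,
    }
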