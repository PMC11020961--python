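"""Synthetic genotype / gene-score / phenotype generator.

Emulates the regime the pipeline targets: balanced case-control samples,
independent common variants (dosage ~ Binomial(2, MAF), optional LD
blocks), sparse linear SNP -> gene maps with one dominant weight (so gene
scores show the stepped, multi-modal distributions imputed expression
exhibits when a single variant carries most of the weight mass), and
penetrance models spanning the interaction forms of interest:

- ``additive_null``        logit P = b0 + sum_j b_j x_j          (no epistasis)
- ``marginal_only``        a single active feature on the logit scale
- ``multiplicative_logit`` adds b_int * x_A * x_B on the logit scale
- ``boolean_and``          P = p_hi if all indicators hold, else p_lo
- ``boolean_xor``          P = p_hi iff exactly one indicator holds
- ``higher_order_and``     AND over 3-4 features

Boolean indicators are 1[x > t]; by default t = 0.5 on genotype dosages
(dominant coding) and the feature median on gene scores.  The coding
``"heterozygous"`` instead uses 1[x == 1], a dominance-type deviation.
All generators are bit-reproducible under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from epitree.core_data import (
    FeatureAnnotation,
    FeatureKind,
    FeatureMatrix,
    PhenotypeVector,
    ValidationError,
    WeightMap,
    balanced_case_control,
    split_train_test,
)

MODELS = (
    "additive_null", "marginal_only", "multiplicative_logit",
    "boolean_and", "boolean_xor", "higher_order_and",
)

_CHROM_POS_SPACING = 100_000  # bp between adjacent simulated SNPs
_CHROM_POS_START = 1_000_000


@dataclass
class SimulationSpec:
    """Study-condition container for one simulated dataset."""

    n_samples: int = 4000
    n_snps: int = 20
    n_chromosomes: int = 2
    maf_range: tuple = (0.05, 0.5)
    maf: float | None = None           # fixed MAF overriding maf_range
    model: str = "boolean_and"
    interacting: tuple = ()            # feature ids carrying the signal
    beta0: float = 0.0
    beta: float = 0.4                  # per-feature logit coefficient
    beta_int: float = 2.0              # multiplicative-logit interaction
    p_hi: float = 0.8
    p_lo: float = 0.3
    threshold: float | None = None     # Boolean indicator cut (None = default)
    indicator: str = "threshold"       # or "heterozygous"
    ld_rho: float = 0.0                # copy-left-neighbour prob inside blocks
    ld_block: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValidationError(f"unknown model {self.model!r}")
        if not (0 < self.p_lo <= self.p_hi < 1):
            raise ValidationError("need 0 < p_lo <= p_hi < 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("MAFs must lie in (0, 0.5]")
        self.interacting = tuple(str(f) for f in self.interacting)


def simulate_genotypes(spec: SimulationSpec, seed: int | None = None):
    """Independent dosages: per SNP, MAF ~ Uniform(maf_range) (or fixed),
    genotype ~ Binomial(2, MAF) across samples.  SNPs are laid out in
    chromosome blocks at increasing positions.  With ``ld_rho > 0`` each
    SNP inside a block of ``ld_block`` copies its left neighbour's
    genotype per-sample with probability rho."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, p = spec.n_samples, spec.n_snps
    if spec.maf is not None:
        mafs = np.full(p, spec.maf)
    else:
        mafs = rng.uniform(*spec.maf_range, size=p)
    X = rng.binomial(2, mafs, size=(n, p)).astype(float)
    snp_ids = [f"rs{j + 1}" for j in range(p)]
    per_chrom = int(np.ceil(p / spec.n_chromosomes))
    annot = {}
    for j, s in enumerate(snp_ids):
        chrom = f"chr{j // per_chrom + 1}"
        pos = _CHROM_POS_START + (j % per_chrom) * _CHROM_POS_SPACING
        annot[s] = FeatureAnnotation(s, chrom, pos, pos)
        if spec.ld_rho > 0 and j % per_chrom != 0 and (j % spec.ld_block) != 0:
            copy = rng.random(n) < spec.ld_rho
            X[copy, j] = X[copy, j - 1]
    fm = FeatureMatrix(
        [f"S{i + 1}" for i in range(n)], snp_ids, X, FeatureKind.genotype
    )
    return fm, annot


def simulate_gene_weights(annot, n_genes: int, snps_per_gene: int = 3,
                          w_dom: float = 0.5, seed: int = 0) -> WeightMap:
    """Sparse SNP -> gene map with a dominant-weight component.

    Genes are laid over consecutive windows of SNPs (round-robin across
    chromosomes); each draws ``snps_per_gene`` SNPs from its window.  One
    weight carries fraction ``w_dom`` of the total absolute mass, the rest
    share the remainder; signs are random and sum of |w| is 1.
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict = {}
    for a in annot.values():
        by_chrom.setdefault(a.chromosome, []).append(a)
    for lst in by_chrom.values():
        lst.sort(key=lambda a: a.start)
    chroms = sorted(by_chrom)
    # split each chromosome's SNPs into contiguous windows, one per gene
    windows = []
    quota = [n_genes // len(chroms) + (1 if i < n_genes % len(chroms) else 0)
             for i in range(len(chroms))]
    for ci, chrom in enumerate(chroms):
        snps = by_chrom[chrom]
        k = quota[ci]
        if k == 0:
            continue
        size = len(snps) // k
        if size < snps_per_gene:
            raise ValidationError(
                f"window on {chrom} has {size} SNPs < {snps_per_gene} per gene"
            )
        for g in range(k):
            windows.append(snps[g * size:(g + 1) * size])
    entries = []
    for gi, window in enumerate(windows):
        gene = f"G{gi + 1}"
        chosen = rng.choice(len(window), size=snps_per_gene, replace=False)
        raw = rng.uniform(0.2, 1.0, size=snps_per_gene)
        signs = rng.choice([-1.0, 1.0], size=snps_per_gene)
        dom = int(rng.integers(snps_per_gene))
        mags = raw / raw.sum()
        if snps_per_gene > 1:
            others = np.delete(np.arange(snps_per_gene), dom)
            mags = np.empty(snps_per_gene)
            mags[dom] = w_dom
            rest = raw[others] / raw[others].sum() * (1 - w_dom)
            mags[others] = rest
        else:
            mags = np.array([1.0])
        for ii, si in enumerate(chosen):
            entries.append((window[si].feature_id, gene,
                            float(signs[ii] * mags[ii])))
    return WeightMap.from_entries(entries)


def gene_annotation_from_weights(weights: WeightMap, snp_annot) -> dict:
    """Gene span = [min, max] position of its weighted SNPs."""
    out = {}
    for gene, grp in weights.table.groupby("gene_id"):
        anns = [snp_annot[s] for s in grp["snp_id"] if s in snp_annot]
        if not anns:
            continue
        chrom = anns[0].chromosome
        out[str(gene)] = FeatureAnnotation(
            str(gene), chrom,
            min(a.start for a in anns), max(a.end for a in anns),
        )
    return out


def _indicators(fm: FeatureMatrix, spec: SimulationSpec) -> np.ndarray:
    cols = fm.restrict(list(spec.interacting)).values
    if spec.indicator == "heterozygous":
        return (cols == 1.0).astype(float)
    if spec.threshold is not None:
        t = spec.threshold
    elif fm.feature_kind is FeatureKind.genotype:
        t = 0.5  # dominant coding: dosage >= 1
    else:
        t = None  # per-feature median
    if t is None:
        return (cols > np.median(cols, axis=0)).astype(float)
    return (cols > t).astype(float)


def simulate_phenotype(features: FeatureMatrix, spec: SimulationSpec,
                       seed: int | None = None) -> PhenotypeVector:
    """Bernoulli responses under the spec's penetrance model."""
    for f in spec.interacting:
        if f not in features.feature_ids:
            raise ValidationError(f"interacting feature {f!r} not present")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    n = features.n_samples
    model = spec.model
    if model in ("additive_null", "marginal_only", "multiplicative_logit"):
        cols = features.restrict(list(spec.interacting)).values
        active = cols[:, :1] if model == "marginal_only" else cols
        logit = spec.beta0 + spec.beta * active.sum(axis=1)
        if model == "multiplicative_logit":
            if cols.shape[1] < 2:
                raise ValidationError("multiplicative_logit needs 2 features")
            logit = logit + spec.beta_int * cols[:, 0] * cols[:, 1]
        prob = 1.0 / (1.0 + np.exp(-logit))
    elif model in ("boolean_and", "higher_order_and"):
        ind = _indicators(features, spec)
        if model == "higher_order_and" and not 3 <= ind.shape[1] <= 4:
            raise ValidationError("higher_order_and takes 3-4 features")
        prob = np.where(ind.all(axis=1), spec.p_hi, spec.p_lo)
    elif model == "boolean_xor":
        ind = _indicators(features, spec)
        if ind.shape[1] != 2:
            raise ValidationError("boolean_xor takes exactly 2 features")
        prob = np.where(ind.sum(axis=1) == 1, spec.p_hi, spec.p_lo)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValidationError(f"unknown model {model!r}")
    y = (rng.random(n) < prob).astype(np.int8)
    return PhenotypeVector(features.sample_ids, y)


def assemble_case_control(X: FeatureMatrix, y: PhenotypeVector,
                          n_per_class: int, test_fraction: float,
                          seed: int = 0):
    """Balanced case-control subset, split into stratified train/test.

    Returns (train X, train y, test X, test y), all id-consistent.
    """
    case_rate = float(np.mean(y.y))
    if case_rate < 0.001:
        raise ValidationError(
            f"case rate {case_rate:.4f} < 0.001; raise p_lo/p_hi or "
            "simulate more samples"
        )
    ids = balanced_case_control(y, n_per_class, seed)
    split = split_train_test(ids, test_fraction, seed + 1,
                             pheno=y.take_samples(ids))
    return (
        X.take_samples(split.train_ids), y.take_samples(split.train_ids),
        X.take_samples(split.test_ids), y.take_samples(split.test_ids),
    )


@dataclass
class SimulatedDataset:
    train_X: FeatureMatrix
    train_y: PhenotypeVector
    test_X: FeatureMatrix
    test_y: PhenotypeVector
    snp_annot: dict
    truth: dict


def simulate_dataset(spec: SimulationSpec, n_per_class: int,
                     test_fraction: float = 0.5,
                     seed: int | None = None) -> SimulatedDataset:
    """Simulate genotype batches until both classes reach ``n_per_class``,
    then assemble a balanced, stratified train/test bundle."""
    base_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    mats, phenos, annot = [], [], None
    n_cases = n_controls = 0
    batch = 0
    while n_cases < n_per_class or n_controls < n_per_class:
        batch += 1
        if batch > 50:
            raise ValidationError("50 simulation batches without enough cases")
        s1 = int(rng.integers(0, 2**31 - 1))
        s2 = int(rng.integers(0, 2**31 - 1))
        fm, annot = simulate_genotypes(spec, seed=s1)
        ph = simulate_phenotype(fm, spec, seed=s2)
        prefix = f"b{batch}_"
        fm = FeatureMatrix([prefix + s for s in fm.sample_ids],
                           fm.feature_ids, fm.values, fm.feature_kind)
        ph = PhenotypeVector([prefix + s for s in ph.sample_ids], ph.y)
        mats.append(fm)
        phenos.append(ph)
        n_cases += int(ph.y.sum())
        n_controls += int((1 - ph.y).sum())
    all_ids = [s for fm in mats for s in fm.sample_ids]
    values = np.vstack([fm.values for fm in mats])
    X = FeatureMatrix(all_ids, mats[0].feature_ids, values,
                      mats[0].feature_kind)
    y = PhenotypeVector(all_ids, np.concatenate([ph.y for ph in phenos]))
    tr_X, tr_y, te_X, te_y = assemble_case_control(
        X, y, n_per_class, test_fraction, seed=int(rng.integers(0, 2**31 - 1))
    )
    truth = {
        "model": spec.model,
        "interacting": list(spec.interacting),
        "p_hi": spec.p_hi, "p_lo": spec.p_lo,
        "beta": spec.beta, "beta_int": spec.beta_int,
        "seed": base_seed,
    }
    return SimulatedDataset(tr_X, tr_y, te_X, te_y, annot, truth)
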