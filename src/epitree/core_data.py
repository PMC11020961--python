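"""Domain containers, file I/O and genomic utilities.

Sample x feature matrices hold either genotype dosages (0/1/2) or
continuous imputed gene-expression scores.  All joins between matrices,
phenotypes and splits are by explicit sample id, never by position.
Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("epitree")

#: clipping constant applied to all probabilities entering a likelihood
EPS = 1e-6

_PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


class FeatureKind(str, Enum):
    genotype = "genotype"
    expression = "expression"


def _check_unique(ids: Sequence, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what} ids: {dupes}")


@dataclass
class FeatureMatrix:
    """n_samples x n_features numeric matrix with aligned id lists.

    Genotype matrices contain dosages in {0, 1, 2} (NaN marks a missing
    call); expression matrices contain finite reals.
    """

    sample_ids: list
    feature_ids: list
    values: np.ndarray
    feature_kind: FeatureKind = FeatureKind.expression

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.feature_kind = FeatureKind(self.feature_kind)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-d matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        finite = np.isfinite(self.values)
        if self.feature_kind is FeatureKind.genotype:
            vals = self.values[finite]
            if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
                bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
                raise ValidationError(f"genotype dosage outside {{0,1,2}}: {bad}")
        else:
            if not finite.all() and not np.isnan(self.values[~finite]).all():
                raise ValidationError("expression values must be finite or NaN")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def require_complete(self) -> None:
        if self.has_missing:
            raise ValidationError(
                "matrix contains missing values; re-read with impute_missing=True"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.feature_ids,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, feature_kind=None) -> "FeatureMatrix":
        values = df.to_numpy(dtype=float)
        if feature_kind is None:
            finite = values[np.isfinite(values)]
            is_geno = finite.size > 0 and np.isin(finite, (0.0, 1.0, 2.0)).all()
            feature_kind = FeatureKind.genotype if is_geno else FeatureKind.expression
        return cls(list(df.index), list(df.columns), values, feature_kind)

    # -- subsetting (always by id) ---------------------------------------
    def restrict(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        """Column subset, preserving the requested order."""
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        cols = [pos[f] for f in feature_ids]
        return FeatureMatrix(
            self.sample_ids, list(feature_ids), self.values[:, cols],
            self.feature_kind,
        )

    def take_samples(self, sample_ids: Iterable[str]) -> "FeatureMatrix":
        """Row subset by id join; unmatched requested ids are an error."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        ids = [str(s) for s in sample_ids]
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        rows = [pos[s] for s in ids]
        return FeatureMatrix(ids, self.feature_ids, self.values[rows], self.feature_kind)

    def column(self, feature_id: str) -> np.ndarray:
        return self.restrict([feature_id]).values[:, 0]


@dataclass
class PhenotypeVector:
    """Binary phenotype (1 = case) aligned to samples by id."""

    sample_ids: list
    y: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.y = np.asarray(self.y)
        if self.y.ndim != 1 or len(self.y) != len(self.sample_ids):
            raise ValidationError("phenotype length does not match sample ids")
        if not np.isin(self.y, (0, 1)).all():
            raise ValidationError("phenotype values must be 0/1")
        self.y = self.y.astype(np.int8)
        _check_unique(self.sample_ids, "sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def take_samples(self, sample_ids: Iterable[str]) -> "PhenotypeVector":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        ids = [str(s) for s in sample_ids]
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in phenotype: {missing[:5]}")
        return PhenotypeVector(ids, self.y[[pos[s] for s in ids]])


def align(fm: FeatureMatrix, pheno: PhenotypeVector):
    """Inner join of a matrix and phenotype on sample id.

    Returns (FeatureMatrix, PhenotypeVector) over the common samples in the
    matrix's order.  Unmatched samples on either side are dropped with a
    logged count -- silent positional joins are the classic genomics bug.
    """
    common = [s for s in fm.sample_ids if s in set(pheno.sample_ids)]
    dropped = (fm.n_samples - len(common)) + (pheno.n_samples - len(common))
    if dropped:
        logger.info("align: dropped %d unmatched samples", dropped)
    if not common:
        raise ValidationError("no overlapping sample ids")
    return fm.take_samples(common), pheno.take_samples(common)


@dataclass(frozen=True)
class FeatureAnnotation:
    """Genomic location of one feature (1-based inclusive coordinates)."""

    feature_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not str(self.chromosome):
            raise ValidationError(f"{self.feature_id}: empty chromosome")
        if self.start > self.end:
            raise ValidationError(
                f"{self.feature_id}: start {self.start} > end {self.end}"
            )


Annotation = Mapping[str, FeatureAnnotation]


@dataclass
class WeightMap:
    """Sparse SNP -> gene weights (PrediXcan-style linear models)."""

    table: pd.DataFrame  # columns snp_id, gene_id, weight

    def __post_init__(self) -> None:
        req = ["snp_id", "gene_id", "weight"]
        if list(self.table.columns[:3]) != req:
            self.table = self.table.rename(
                columns=dict(zip(self.table.columns[:3], req))
            )
        self.table = self.table.astype(
            {"snp_id": str, "gene_id": str, "weight": float}
        )
        if self.table.duplicated(["snp_id", "gene_id"]).any():
            raise ValidationError("duplicate (snp_id, gene_id) weight entries")
        if not np.isfinite(self.table["weight"]).all():
            raise ValidationError("non-finite weight")

    @classmethod
    def from_entries(cls, entries: Iterable[tuple]) -> "WeightMap":
        return cls(pd.DataFrame(entries, columns=["snp_id", "gene_id", "weight"]))

    @property
    def gene_ids(self) -> list:
        return sorted(self.table["gene_id"].unique())

    @property
    def snp_ids(self) -> list:
        return sorted(self.table["snp_id"].unique())


@dataclass
class DataSplit:
    train_ids: list
    test_ids: list

    def __post_init__(self) -> None:
        self.train_ids = [str(s) for s in self.train_ids]
        self.test_ids = [str(s) for s in self.test_ids]
        if not self.train_ids or not self.test_ids:
            raise ValidationError("both splits must be non-empty")
        if set(self.train_ids) & set(self.test_ids):
            raise ValidationError("train and test ids overlap")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    # distinguish genuine NA tokens from unparseable text
    for col in df.columns:
        raw = df[col].astype(str).str.strip()
        became_nan = out[col].isna() & ~raw.str.upper().isin(["NA", "NAN", ""])
        if became_nan.any():
            i = int(np.nonzero(became_nan.to_numpy())[0][0])
            raise ValidationError(
                f"{path}: non-numeric value {raw.iloc[i]!r} at row "
                f"{df.index[i]!r}, column {col!r}"
            )
    return out


def read_feature_matrix(path, format: str = "tsv", impute_missing: bool = False,
                        feature_kind=None) -> FeatureMatrix:
    """Read a sample x feature matrix.

    ``tsv``: tab-separated, header of feature ids, first column the sample
    id.  ``plink_raw``: whitespace separated with the six PLINK metadata
    columns (FID IID PAT MAT SEX PHENOTYPE) followed by ``SNP_ALLELE``
    dosage columns; IID becomes the sample id.

    Missing entries (``NA``) are kept as NaN and rejected by downstream
    model fits unless ``impute_missing`` replaces them with the per-feature
    mean at read time.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValidationError(f"{path}: expected sample_id column plus features")
        df = df.set_index(df.columns[0])
        df.index = df.index.astype(str)
    elif format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        missing_meta = [c for c in _PLINK_META_COLS if c not in df.columns]
        if missing_meta:
            raise ValidationError(
                f"{path}: malformed plink_raw header, missing column "
                f"{missing_meta[0]!r}"
            )
        df = df.set_index(df["IID"].astype(str)).drop(columns=_PLINK_META_COLS)
        if df.shape[1] == 0:
            raise ValidationError(f"{path}: no genotype columns after metadata")
    else:
        raise ValueError(f"unknown format {format!r}")
    _check_unique(list(df.index), "sample")
    _check_unique(list(df.columns), "feature")
    df = _numeric(df, path)
    values = df.to_numpy(dtype=float)
    if impute_missing and np.isnan(values).any():
        col_mean = np.nanmean(values, axis=0)
        inds = np.where(np.isnan(values))
        values[inds] = np.take(col_mean, inds[1])
        df = pd.DataFrame(values, index=df.index, columns=df.columns)
    elif np.isnan(values).any():
        logger.warning("%s: %d missing entries flagged", path,
                       int(np.isnan(values).sum()))
    if format == "plink_raw" and feature_kind is None:
        feature_kind = FeatureKind.genotype
    return FeatureMatrix.from_frame(df, feature_kind=feature_kind)


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    fm.to_frame().to_csv(path, sep="\t", na_rep="NA")


def read_phenotype(path) -> PhenotypeVector:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if "phenotype" not in df.columns or "sample_id" not in df.columns:
        raise ValidationError(f"{path}: need columns sample_id, phenotype")
    return PhenotypeVector(df["sample_id"].tolist(), df["phenotype"].to_numpy())


def write_phenotype(pheno: PhenotypeVector, path) -> None:
    pd.DataFrame({"sample_id": pheno.sample_ids, "phenotype": pheno.y}).to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "chrom": str})
    req = {"feature_id", "chrom", "start", "end"}
    if not req <= set(df.columns):
        raise ValidationError(f"{path}: need columns {sorted(req)}")
    return {
        str(r.feature_id): FeatureAnnotation(
            str(r.feature_id), str(r.chrom), int(r.start), int(r.end)
        )
        for r in df.itertuples()
    }


def write_annotation(annot: Annotation, path) -> None:
    pd.DataFrame(
        [(a.feature_id, a.chromosome, a.start, a.end) for a in annot.values()],
        columns=["feature_id", "chrom", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


def read_weights(path) -> WeightMap:
    return WeightMap(pd.read_csv(path, sep="\t"))


def write_weights(weights: WeightMap, path) -> None:
    weights.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene aggregation, sampling, windows, LD
# ---------------------------------------------------------------------------

def aggregate_genes(snps: FeatureMatrix, weights: WeightMap):
    """PrediXcan-style aggregation: gene score = sum_j w_jg * dosage_j.

    Exactly linear in the genotype matrix.  Returns the expression-kind
    matrix and the list of weight SNP ids absent from the matrix (dropped).
    """
    if snps.feature_kind is not FeatureKind.genotype:
        raise ValidationError("aggregate_genes expects a genotype matrix")
    snps.require_complete()
    present = set(snps.feature_ids)
    dropped = sorted({s for s in weights.table["snp_id"] if s not in present})
    used = weights.table[weights.table["snp_id"].isin(present)]
    if used.empty:
        raise ValidationError("empty aggregation: no weight SNPs present in matrix")
    if dropped:
        logger.info("aggregate_genes: dropped %d weight SNPs", len(dropped))
    w = used.pivot(index="snp_id", columns="gene_id", values="weight").fillna(0.0)
    w = w.reindex(index=snps.feature_ids, fill_value=0.0)
    genes = list(w.columns)
    scores = snps.values @ w.to_numpy()
    out = FeatureMatrix(snps.sample_ids, genes, scores, FeatureKind.expression)
    return out, dropped


def balanced_case_control(pheno: PhenotypeVector, n_per_class: int, seed: int) -> list:
    """Uniform sample without replacement of n cases and n controls."""
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    ids = np.array(pheno.sample_ids)
    cases = np.sort(ids[pheno.y == 1])
    controls = np.sort(ids[pheno.y == 0])
    if len(cases) < n_per_class or len(controls) < n_per_class:
        raise ValidationError(
            f"insufficient class size: {len(cases)} cases, "
            f"{len(controls)} controls, requested {n_per_class} per class"
        )
    rng = np.random.default_rng(seed)
    pick_cases = rng.choice(cases, size=n_per_class, replace=False)
    pick_controls = rng.choice(controls, size=n_per_class, replace=False)
    return [str(s) for s in np.concatenate([pick_cases, pick_controls])]


def split_train_test(ids: Sequence[str], test_fraction: float, seed: int,
                     pheno: PhenotypeVector | None = None) -> DataSplit:
    """Random train/test partition, stratified by class when a phenotype
    is supplied.  Default fraction elsewhere in the package is 2/15."""
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    ids = [str(s) for s in ids]
    _check_unique(ids, "sample")
    rng = np.random.default_rng(seed)
    if pheno is None:
        strata = [ids]
    else:
        sub = pheno.take_samples(ids)
        strata = [
            [s for s, yy in zip(ids, sub.y) if yy == 1],
            [s for s, yy in zip(ids, sub.y) if yy == 0],
        ]
    train, test = [], []
    for stratum in strata:
        stratum = np.array(stratum)
        n_test = int(round(len(stratum) * test_fraction))
        n_test = min(max(n_test, 1), len(stratum) - 1) if len(stratum) > 1 else n_test
        perm = rng.permutation(len(stratum))
        test.extend(stratum[perm[:n_test]])
        train.extend(stratum[perm[n_test:]])
    return DataSplit([str(s) for s in train], [str(s) for s in test])


def select_window_snps(snps: FeatureMatrix, annot: Annotation,
                       genes: Iterable[str], window_bp: int = 1_000_000) -> list:
    """SNPs within [gene.start - window, gene.end + window] on the gene's
    chromosome, for any listed gene (1-based inclusive arithmetic)."""
    genes = list(genes)
    for g in genes:
        if g not in annot:
            raise KeyError(f"gene {g!r} has no annotation")
    selected = []
    for s in snps.feature_ids:
        a = annot.get(s)
        if a is None:
            continue
        for g in genes:
            ga = annot[g]
            if a.chromosome == ga.chromosome and (
                ga.start - window_bp <= a.start <= ga.end + window_bp
            ):
                selected.append(s)
                break
    return selected


def ld_r2(snps: FeatureMatrix, id_a: str, id_b: str) -> float:
    """Composite (dosage-correlation) r^2 between two variants."""
    a = snps.column(id_a)
    b = snps.column(id_b)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("missing genotypes in LD computation")
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("monomorphic variant")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
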