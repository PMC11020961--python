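"""PCS epistasis p-values and the logistic-regression comparator.

The epiTree test compares the no-epistasis (additive-tree) model against
the epistasis (single CART) model on hold-out test data.  Prediction on
the test set acts as a screen: if the epistasis model's cross-entropy is
not strictly better, the p-value is 1 by construction.  Otherwise, over B
bootstrap resamples of the test set, "null perturbation" responses
Y0 ~ Bernoulli(P0) are simulated from the null model and the p-value is
the fraction of resamples in which the likelihood ratio

    T(Y) = P(Y | null model) / P(Y | epistasis model)

under the observed responses exceeds (strictly) the same statistic under
the simulated responses.  A closed-form normal approximation of the
large-B limit is provided as an alternative to Monte Carlo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from epitree.core_data import EPS, ValidationError
from epitree.tree_models import (
    Interaction,
    Partition,
    cross_entropy,
    predict_proba,
)

logger = logging.getLogger("epitree")

_CHUNK = 2_000_000  # max bootstrap cells (B * n) materialized at once


@dataclass
class BootstrapDraw:
    """One bootstrap resample of the test set (paired Y and Y0)."""

    indices: np.ndarray
    y_obs: np.ndarray
    p0: np.ndarray
    y0: np.ndarray

    def __post_init__(self):
        n = len(self.indices)
        if not (len(self.y_obs) == len(self.p0) == len(self.y0) == n):
            raise ValidationError("bootstrap draw vectors must have equal length")


@dataclass
class PCSResult:
    interaction: Interaction | None
    partition: Partition | None
    ce_null_test: float
    ce_alt_test: float
    screened: bool
    B: int
    exceed_count: int
    p_value: float
    p_bonferroni: float = np.nan
    method: str = "monte_carlo"

    def display_p(self) -> str:
        """Monte-Carlo honesty: a raw 0 is reported as '< 1/B'."""
        if self.method == "monte_carlo" and self.p_value == 0 and self.B > 0:
            return f"< {1.0 / self.B:.2g}"
        return f"{self.p_value:.3g}"


def iter_bootstrap_draws(null_model, test_X, test_y, B: int, seed: int = 0,
                         feature_ids=None):
    """Materialize the B paired bootstrap draws used by the PCS test
    (for inspection/diagnostics; the p-value path is vectorized)."""
    y = np.asarray(test_y)
    p0 = predict_proba(null_model, test_X, feature_ids=feature_ids)
    n = len(y)
    rng = np.random.default_rng(seed)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        p0_b = p0[idx]
        yield BootstrapDraw(
            indices=idx,
            y_obs=y[idx],
            p0=p0_b,
            y0=(rng.random(n) < p0_b).astype(np.int8),
        )


def log_likelihood_ratio(y, p_null, p_alt) -> float:
    """log T = sum_i [log Bern(y_i; p0_i) - log Bern(y_i; p1_i)].

    Comparisons T > T' are always performed as log T > log T'.
    """
    y = np.asarray(y, dtype=float)
    p0 = np.clip(np.asarray(p_null, dtype=float), EPS, 1 - EPS)
    p1 = np.clip(np.asarray(p_alt, dtype=float), EPS, 1 - EPS)
    if not (y.shape == p0.shape == p1.shape):
        raise ValidationError("vectors must be aligned")
    return float(
        np.sum(y * (np.log(p0) - np.log(p1))
               + (1 - y) * (np.log1p(-p0) - np.log1p(-p1)))
    )


def _pointwise_logratios(p0, p1):
    """Per-observation log Bernoulli ratios at y=1 and y=0."""
    l1 = np.log(p0) - np.log(p1)
    l0 = np.log1p(-p0) - np.log1p(-p1)
    return l1, l0


def _prepare(null_model, alt_model, test_X, test_y, feature_ids=None):
    y = np.asarray(test_y, dtype=float)
    p0 = predict_proba(null_model, test_X, feature_ids=feature_ids)
    p1 = predict_proba(alt_model, test_X, feature_ids=feature_ids)
    ce0 = cross_entropy(p0, y)
    ce1 = cross_entropy(p1, y)
    return y, p0, p1, ce0, ce1


def pcs_pvalue(null_model, alt_model, test_X, test_y, B: int = 1000,
               seed: int = 0, interaction=None, feature_ids=None) -> PCSResult:
    """Monte-Carlo PCS epistasis p-value on hold-out test data.

    Screening: if the epistasis model's test cross-entropy is >= the null
    model's, return p = 1 without bootstrapping.  Otherwise resample the
    test set with replacement B times; each resample reuses the same
    indices for the observed responses and for the simulated null
    responses (paired comparison) and contributes the indicator
    1{log T(Y|b) > log T(Y0|b)} with strict inequality (ties are
    non-exceedances, conservative).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y, p0, p1, ce0, ce1 = _prepare(null_model, alt_model, test_X, test_y,
                                   feature_ids)
    n = len(y)
    if n < 10:
        logger.warning("pcs_pvalue: test set has only %d samples", n)
    part = getattr(null_model, "partition", None)
    if ce1 >= ce0:
        return PCSResult(
            interaction=interaction, partition=part, ce_null_test=ce0,
            ce_alt_test=ce1, screened=True, B=B, exceed_count=0, p_value=1.0,
            method="monte_carlo",
        )
    l1, l0 = _pointwise_logratios(p0, p1)
    ell_obs = np.where(y == 1, l1, l0)  # log-ratio at the observed response
    rng = np.random.default_rng(seed)
    exceed = 0
    half_exceed = 0  # exceedances within the first B//2 draws (diagnostic)
    done = 0
    block = max(1, _CHUNK // max(n, 1))
    while done < B:
        b = min(block, B - done)
        idx = rng.integers(0, n, size=(b, n))
        t_obs = ell_obs[idx].sum(axis=1)
        p0_b = p0[idx]
        y0 = rng.random((b, n)) < p0_b
        t_null = np.where(y0, l1[idx], l0[idx]).sum(axis=1)
        ind = t_obs > t_null
        exceed += int(ind.sum())
        if done < B // 2:
            half_exceed += int(ind[: max(0, B // 2 - done)].sum())
        done += b
    p = exceed / B
    if B >= 20:
        p_half = half_exceed / max(B // 2, 1)
        if abs(p_half - p) > 0.01:
            logger.warning(
                "pcs_pvalue: estimate moved by %.3f between B/2 and B; "
                "consider a larger B or the Gaussian method", abs(p_half - p)
            )
    return PCSResult(
        interaction=interaction, partition=part, ce_null_test=ce0,
        ce_alt_test=ce1, screened=False, B=B, exceed_count=exceed, p_value=p,
        method="monte_carlo",
    )


def pcs_pvalue_gaussian(null_model, alt_model, test_X, test_y,
                        interaction=None, feature_ids=None) -> PCSResult:
    """Large-B normal approximation of the PCS p-value.

    Per test observation i let ell_i(y) be the pointwise log likelihood
    ratio; the bootstrap difference D_b = sum over resampled i of
    [ell_i(y_i) - ell_i(Y0_i)] is a sum of n iid draws of
    Delta = ell_I(y_I) - ell_I(Y0_I) with I uniform and Y0_I ~ Bern(p0_I).
    Both moments of Delta are available in closed form, so
    p = Pr(D > 0) ~= Phi(mu_D / sigma_D).  Screening is applied first, as
    in the Monte-Carlo version.
    """
    y, p0, p1, ce0, ce1 = _prepare(null_model, alt_model, test_X, test_y,
                                   feature_ids)
    part = getattr(null_model, "partition", None)
    if ce1 >= ce0:
        return PCSResult(
            interaction=interaction, partition=part, ce_null_test=ce0,
            ce_alt_test=ce1, screened=True, B=0, exceed_count=0, p_value=1.0,
            method="gaussian_approx",
        )
    l1, l0 = _pointwise_logratios(p0, p1)
    ell_obs = np.where(y == 1, l1, l0)
    n = len(y)
    # E[Delta] and Var[Delta] over uniform I and Y0_I ~ Bern(p0_I)
    e_null = p0 * l1 + (1 - p0) * l0
    mean_delta = float(np.mean(ell_obs - e_null))
    second = float(np.mean(
        p0 * (ell_obs - l1) ** 2 + (1 - p0) * (ell_obs - l0) ** 2
    ))
    var_delta = max(second - mean_delta ** 2, 0.0)
    mu_d = n * mean_delta
    sigma_d = np.sqrt(n * var_delta)
    if sigma_d == 0:
        p = float(mu_d > 0)
    else:
        p = float(stats.norm.cdf(mu_d / sigma_d))
    return PCSResult(
        interaction=interaction, partition=part, ce_null_test=ce0,
        ce_alt_test=ce1, screened=False, B=0, exceed_count=0, p_value=p,
        method="gaussian_approx",
    )


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """min(1, m * p) over the m tests supplied."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, len(p) * p)


@dataclass
class LogisticComparator:
    """Pairwise multiplicative-on-logit comparator record."""

    p_value: float
    ce_null_test: float
    ce_alt_test: float
    converged: bool = True


def logistic_lrt(X_train, y_train, test_X, test_y,
                 feature_ids=None) -> LogisticComparator:
    """Classical comparator for a pairwise interaction.

    Fits, on training data, logit P = b0 + b1 a + b2 b (null) and the same
    plus b3 ab (alternative); reports the chi-square(1) LRT p-value from
    the training fit and the hold-out cross-entropy of both models.
    Separation or non-convergence yields a flagged record with p = NaN,
    cross-entropies still reported where computable.
    """
    import statsmodels.api as sm

    from epitree.tree_models import _as_array

    Xa, fids = _as_array(X_train, feature_ids)
    if Xa.shape[1] != 2:
        raise ValidationError("logistic comparator is pairwise only (d = 2)")
    Xt, _ = _as_array(test_X, fids)
    y = np.asarray(y_train, dtype=float)
    yt = np.asarray(test_y, dtype=float)
    a, b = Xa[:, 0], Xa[:, 1]
    d_null = np.column_stack([np.ones_like(a), a, b])
    d_alt = np.column_stack([d_null, a * b])
    at, bt = Xt[:, 0], Xt[:, 1]
    t_null = np.column_stack([np.ones_like(at), at, bt])
    t_alt = np.column_stack([t_null, at * bt])
    try:
        with np.errstate(all="ignore"):
            m0 = sm.Logit(y, d_null).fit(disp=0, maxiter=100)
            m1 = sm.Logit(y, d_alt).fit(disp=0, maxiter=100)
        converged = bool(m0.mle_retvals["converged"] and
                         m1.mle_retvals["converged"])
        lr = 2 * (m1.llf - m0.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), df=1)) if converged else np.nan
        ce0 = cross_entropy(np.clip(m0.predict(t_null), EPS, 1 - EPS), yt)
        ce1 = cross_entropy(np.clip(m1.predict(t_alt), EPS, 1 - EPS), yt)
        if not converged:
            logger.warning("logistic_lrt: non-convergence flagged")
        return LogisticComparator(p, ce0, ce1, converged)
    except Exception as err:  # separation / singular design
        logger.warning("logistic_lrt: flagged (%s)", err)
        return LogisticComparator(np.nan, np.nan, np.nan, False)
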