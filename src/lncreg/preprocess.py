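"""Count preprocessing: CPM filtering, TMM normalization, log/z-transform,
and clinical-covariate residualization.

The pipeline mirrors standard bulk RNA-seq practice: genes with CPM > 1 in
too few samples are dropped, between-sample composition bias is corrected by
the trimmed mean of M-values (TMM), expression is log2(CPM + 1) transformed
and standardized per gene, and nuisance covariates (age, sex, ethnicity,
race) are regressed out, with residuals re-standardized so that downstream
coefficients stay on a common variance-explained scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "validate_counts",
    "cpm_filter",
    "tmm_factors",
    "normalize_log_standardize",
    "residualize_covariates",
    "covariate_design",
]

#: valid processing states, in pipeline order
STATES = ("normalized_log", "standardized", "covariate_residual", "tf_residual")


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued expression matrix with a processing state.

    In every state from ``standardized`` on, each gene row has mean 0 and
    variance 1 (re-standardization is applied after each residualization).
    """

    values: pd.DataFrame
    state: str = "standardized"
    log: list = field(default_factory=list)

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise ValueError("gene and sample ids must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def check_standardized(self, atol: float = 1e-8) -> None:
        mu = self.values.to_numpy().mean(axis=1)
        var = self.values.to_numpy().var(axis=1)
        if np.abs(mu).max(initial=0) > atol or np.abs(var - 1).max(initial=0) > atol:
            raise AssertionError("matrix is not per-gene standardized")


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples integer count matrix."""
    if not counts.index.is_unique:
        raise ValueError("duplicate gene ids in count matrix")
    if not counts.columns.is_unique:
        raise ValueError("duplicate sample ids in count matrix")
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("negative counts")
    return counts


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero)}")
    return counts * 1e6 / totals


def cpm_filter(counts: pd.DataFrame, cpm_min: float = 1.0,
               min_samples: int | None = None) -> pd.DataFrame:
    """Drop genes without CPM strictly above ``cpm_min`` in >= ``min_samples``
    samples.  CPM uses the column sums of the *input* matrix."""
    validate_counts(counts)
    if min_samples is None:
        raise ValueError("min_samples is required")
    if min_samples > counts.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    cpm = _cpm(counts)
    keep = (cpm > cpm_min).sum(axis=1) >= min_samples
    dropped = int((~keep).sum())
    if dropped:
        logger.info("cpm_filter: removed %d of %d genes", dropped, len(keep))
    return counts.loc[keep]


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.3,
                abs_trim: float = 0.05, weighted: bool = True) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean of those percentiles.  For each sample, per-gene log2 ratios to
    the reference (M) and average log2 abundances (A) are computed over genes
    expressed in both; the top and bottom ``logratio_trim`` fraction by M and
    ``abs_trim`` fraction by A are trimmed, and the factor is 2 to the
    inverse-variance-weighted mean of the surviving M values.

    ``weighted=False`` uses a plain trimmed mean.  The weighted estimator
    matches the reference TMM implementation but is only approximately
    invariant to pure sequencing-depth changes (the precision weights see
    absolute counts); the unweighted variant is exactly depth-invariant.
    """
    validate_counts(counts)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero total counts")
    uq = np.percentile(X / lib, 75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = X[:, ref_idx]
    ref_lib = lib[ref_idx]

    log_factors = np.zeros(X.shape[1])
    for s in range(X.shape[1]):
        if s == ref_idx:
            continue
        obs = X[:, s]
        ok = (obs > 0) & (ref > 0)
        if not ok.any():
            raise ValueError(
                f"sample {counts.columns[s]!r} shares no expressed genes "
                f"with reference {counts.columns[ref_idx]!r}")
        p_obs = obs[ok] / lib[s]
        p_ref = ref[ok] / ref_lib
        M = np.log2(p_obs / p_ref)
        A = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic (delta-method) variance of M
        w = (lib[s] - obs[ok]) / (lib[s] * obs[ok]) \
            + (ref_lib - ref[ok]) / (ref_lib * ref[ok])
        n = M.size
        lo_m, hi_m = np.floor(n * logratio_trim), np.ceil(n * (1 - logratio_trim))
        lo_a, hi_a = np.floor(n * abs_trim), np.ceil(n * (1 - abs_trim))
        rank_m = sps_rank(M)
        rank_a = sps_rank(A)
        keep = (rank_m >= lo_m) & (rank_m < hi_m) & (rank_a >= lo_a) & (rank_a < hi_a)
        if not keep.any():
            keep = np.ones(n, bool)
        if weighted:
            log_factors[s] = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
        else:
            log_factors[s] = M[keep].mean()

    log_factors -= log_factors.mean()  # geometric mean of 2^f is 1
    return pd.Series(2.0 ** log_factors, index=counts.columns, name="tmm_factor")


def sps_rank(x: np.ndarray) -> np.ndarray:
    """0-based average-tie rank (loose ranks suffice for trimming)."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(x.size)
    return ranks


def normalize_log_standardize(counts: pd.DataFrame,
                              factors: pd.Series) -> ExpressionMatrix:
    """log2(1 + TMM-scaled CPM), then per-gene zero-mean unit-variance."""
    validate_counts(counts)
    factors = factors.reindex(counts.columns)
    if factors.isna().any():
        raise ValueError("factors missing for some samples")
    lib = counts.sum(axis=0) * factors
    vals = np.log2(1.0 + counts * 1e6 / lib)
    sd = vals.std(axis=1, ddof=0)
    constant = sd.index[sd == 0]
    if len(constant):
        logger.warning("removing %d constant gene(s) after normalization",
                       len(constant))
        vals = vals.drop(index=constant)
        sd = sd.drop(index=constant)
    vals = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(vals, state="standardized",
                            log=[f"removed {len(constant)} constant genes"])


def covariate_design(cov: pd.DataFrame, sample_ids) -> np.ndarray:
    """Design matrix: standardized age + one-hot categoricals, no intercept.

    Missing ages are imputed to the mean, missing categories to the modal
    level; imputation counts are logged.  All-missing or constant columns are
    dropped with a warning.
    """
    cov = cov.loc[list(sample_ids)].copy()
    blocks = []
    for col in cov.columns:
        series = cov[col]
        n_missing = int(series.isna().sum())
        if n_missing == len(series):
            logger.warning("covariate %r all missing; dropped", col)
            continue
        if pd.api.types.is_numeric_dtype(series):
            if n_missing:
                logger.info("imputed %d missing values in %r to mean",
                            n_missing, col)
                series = series.fillna(series.mean())
            sd = series.std(ddof=0)
            if sd == 0:
                logger.warning("constant covariate %r dropped", col)
                continue
            blocks.append(((series - series.mean()) / sd).to_numpy()[:, None])
        else:
            if n_missing:
                logger.info("imputed %d missing values in %r to mode",
                            n_missing, col)
                series = series.fillna(series.mode().iloc[0])
            dummies = pd.get_dummies(series, drop_first=True, dtype=float)
            if dummies.shape[1] == 0:
                logger.warning("constant covariate %r dropped", col)
                continue
            blocks.append(dummies.to_numpy())
    if not blocks:
        return np.empty((len(cov), 0))
    return np.hstack(blocks)


def residualize_covariates(expr: ExpressionMatrix,
                           cov: pd.DataFrame) -> ExpressionMatrix:
    """Regress every gene on the covariate design; return re-standardized
    residuals.  Genes rendered constant (expression fully explained by the
    covariates) are removed with a warning."""
    missing = set(expr.sample_ids) - set(cov.index)
    if missing:
        raise ValueError(f"covariates missing for samples: {sorted(missing)}")
    D = covariate_design(cov, expr.sample_ids)
    Y = expr.values.to_numpy().T  # samples x genes
    ones = np.ones((Y.shape[0], 1))
    X = np.hstack([ones, D])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    resid = resid.T  # genes x samples
    sd = resid.std(axis=1)
    const = sd < 1e-12
    if const.any():
        logger.warning("%d gene(s) constant after covariate residualization; "
                       "removed", int(const.sum()))
    genes = np.asarray(expr.gene_ids)[~const]
    resid = resid[~const]
    resid = (resid - resid.mean(axis=1, keepdims=True)) / resid.std(
        axis=1, keepdims=True)
    out = pd.DataFrame(resid, index=genes, columns=expr.sample_ids)
    return ExpressionMatrix(out, state="covariate_residual",
                            log=expr.log + [f"residualized on {X.shape[1]-1} "
                                            "covariate columns"])
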