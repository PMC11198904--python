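"""Sparse-selection + OLS regression engine.

Each target gene is modeled from a candidate regulator pool in two stages:
an elastic net (mixing 0.5, geometric 100-point penalty path) picks the path
point whose support size is closest to ``k_target`` (~10), and an ordinary
least squares refit on the selected predictors supplies coefficients,
t-test p-values and R^2.  Performance is measured by 5-fold cross-validated
test R^2, with selection re-run inside every training fold so held-out
samples never inform the feature choice.  Confounding by a regulator class
(typically transcription factors) is removed by subtracting that class's
model prediction from the target and re-standardizing the residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._enet import enet_support_path

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFit",
    "CVResult",
    "select_predictors",
    "ols_fit",
    "cross_validated_r2",
    "residualize_by_model",
    "model_class",
]


@dataclass
class ModelFit:
    """OLS refit for one target: predictors, coefficients, p-values, R^2."""

    target_id: str
    predictor_ids: list[str]
    intercept: float
    coefficients: np.ndarray
    coef_pvalues: np.ndarray
    overall_r2: float
    n_samples: int

    def __post_init__(self):
        if not (len(self.predictor_ids) == len(self.coefficients)
                == len(self.coef_pvalues)):
            raise ValueError("predictor/coefficient/p-value length mismatch")
        if not -1e-9 <= self.overall_r2 <= 1 + 1e-9:
            raise ValueError(f"overall R^2 out of range: {self.overall_r2}")


@dataclass
class CVResult:
    """Cross-validation record for one target."""

    target_id: str
    fold_test_r2: list[float]
    fold_selected: list[list[str]]
    test_pcc: float

    @property
    def mean_test_r2(self) -> float:
        return float(np.mean(self.fold_test_r2))


def _as_matrix(candidates) -> tuple[np.ndarray, list[str]]:
    """Accept a DataFrame (rows = predictors) or (array, ids)."""
    if isinstance(candidates, pd.DataFrame):
        return candidates.to_numpy(dtype=float), list(candidates.index)
    raise TypeError("candidates must be a DataFrame with predictor rows")


def select_predictors(
    y,
    candidates: pd.DataFrame,
    k_target: int = 10,
    exclude: set | None = None,
    seed: int = 0,
    l1_ratio: float = 0.5,
    n_alphas: int = 100,
    eps: float = 1e-3,
) -> list[str]:
    """Pick ~``k_target`` predictors for y from candidate rows.

    With ``k_target`` or fewer candidates, all are returned (an OLS fit is
    then used directly).  Otherwise the elastic-net path point whose support
    size is closest to ``k_target`` wins, ties going to the stronger penalty;
    the returned ids are ordered by |path coefficient| descending.  ``seed``
    is accepted for interface uniformity; the path itself is deterministic.
    """
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise ValueError("zero-variance target")
    exclude = exclude or set()
    if exclude and any(i in exclude for i in candidates.index):
        cand = candidates.loc[[i for i in candidates.index if i not in exclude]]
    else:
        cand = candidates
    if cand.shape[0] == 0:
        raise ValueError("empty candidate set")
    if cand.shape[0] <= k_target:
        return list(cand.index)
    X, ids = _as_matrix(cand)
    idx = _select_idx(y, X, k_target, l1_ratio, n_alphas, eps)
    return [ids[i] for i in idx]


def _select_idx(y: np.ndarray, X: np.ndarray, k_target: int,
                l1_ratio: float = 0.5, n_alphas: int = 100,
                eps: float = 1e-3) -> list[int]:
    """Numpy core of :func:`select_predictors` (X: predictors x samples)."""
    if X.shape[0] <= k_target:
        return list(range(X.shape[0]))
    _, coefs = enet_support_path(
        X.T, y, l1_ratio=l1_ratio, n_alphas=n_alphas, eps=eps,
        support_stop=3 * k_target + 5)
    support = (coefs != 0).sum(axis=0)
    best = int(np.argmin(np.abs(support - k_target)))  # first = strongest
    w = coefs[:, best]
    idx = np.nonzero(w)[0]
    return list(idx[np.argsort(-np.abs(w[idx]), kind="stable")])


def _ols_core(y: np.ndarray, X: np.ndarray):
    """Fast OLS with intercept: returns (intercept, beta, r2, yhat)."""
    n = y.size
    Z = np.empty((n, X.shape[1] + 1))
    Z[:, 0] = 1.0
    Z[:, 1:] = X
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    yhat = Z @ beta
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return float(beta[0]), beta[1:], r2, yhat, rss, Z


def ols_fit(y, X_selected: pd.DataFrame, target_id: str = "target") -> ModelFit:
    """OLS with intercept; coefficient p-values from t-tests at n-p-1 df.

    Exact duplicate predictor rows are dropped with a warning; remaining rank
    deficiency raises an error listing the collinear ids.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X, ids = _as_matrix(X_selected)
    if X.shape[0]:
        _, uniq_idx = np.unique(X, axis=0, return_index=True)
        if uniq_idx.size < X.shape[0]:
            dropped = sorted(set(range(X.shape[0])) - set(uniq_idx))
            logger.warning("dropping exact duplicate predictors: %s",
                           [ids[i] for i in dropped])
            keep = sorted(uniq_idx)
            X, ids = X[keep], [ids[i] for i in keep]
    p = X.shape[0]
    if n <= p + 1:
        raise ValueError(f"need n > p+1 (n={n}, p={p})")
    if p == 0:
        mu = float(y.mean())
        return ModelFit(target_id, [], mu, np.empty(0), np.empty(0), 0.0, n)
    Xt = X.T  # samples x predictors
    rank = np.linalg.matrix_rank(np.hstack([np.ones((n, 1)), Xt]))
    if rank < p + 1:
        raise ValueError(f"rank-deficient design; collinear ids among {ids}")
    intercept, beta, r2, yhat, rss, Z = _ols_core(y, Xt)
    df = n - p - 1
    sigma2 = rss / df if df > 0 else np.inf
    XtX_inv = np.linalg.inv(Z.T @ Z)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv)[1:], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * sps.t.sf(np.abs(t), df)
    return ModelFit(target_id, ids, intercept, beta, np.asarray(pvals),
                    max(r2, 0.0), n)


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle split into folds as equal as possible."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def cross_validated_r2(
    y,
    candidates: pd.DataFrame,
    k_target: int = 10,
    folds: int = 5,
    seed: int = 0,
    exclude: set | None = None,
    **select_kw,
) -> CVResult:
    """K-fold CV with in-fold selection; test R^2 about the held-out mean.

    Negative fold R^2 values are preserved: a model worse than the held-out
    mean scores below zero by construction.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X, ids = _as_matrix(candidates)
    if exclude:
        keep = [i for i, g in enumerate(ids) if g not in exclude]
        X, ids = X[keep], [ids[i] for i in keep]
    if X.shape[0] == 0:
        raise ValueError("empty candidate set")
    fold_idx = _fold_indices(n, folds, seed)
    fold_r2, fold_sel = [], []
    pooled_pred = np.empty(n)
    for test in fold_idx:
        train = np.setdiff1d(np.arange(n), test)
        if y[train].std() == 0:
            raise ValueError("zero-variance target in a training fold")
        pos = _select_idx(y[train], X[:, train], k_target, **select_kw)
        fold_sel.append([ids[i] for i in pos])
        if len(train) <= len(pos) + 1:
            raise ValueError("fold too small for the selected model")
        if pos:
            intercept, beta, _, _, _, _ = _ols_core(y[train], X[pos][:, train].T)
            pred = intercept + X[pos][:, test].T @ beta
        else:
            pred = np.full(test.size, y[train].mean())
        pooled_pred[test] = pred
        ss_res = float(np.sum((y[test] - pred) ** 2))
        ss_tot = float(np.sum((y[test] - y[test].mean()) ** 2))
        fold_r2.append(1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    if np.std(pooled_pred) > 0 and np.std(y) > 0:
        pcc = float(np.corrcoef(pooled_pred, y)[0, 1])
    else:
        pcc = 0.0
    return CVResult("target", fold_r2, fold_sel, pcc)


def residualize_by_model(y, fit: ModelFit, X: pd.DataFrame
                         ) -> tuple[np.ndarray, bool]:
    """Subtract a fitted model's prediction from y; re-standardize.

    Returns (residual, is_constant).  A perfect fit leaves a constant
    residual, flagged instead of standardized.  With an empty predictor set
    the residual is y minus its mean.
    """
    y = np.asarray(y, dtype=float)
    if fit.predictor_ids:
        missing = [i for i in fit.predictor_ids if i not in X.index]
        if missing:
            raise ValueError(f"predictors absent from X: {missing}")
        Xp = X.loc[fit.predictor_ids].to_numpy(dtype=float)
        if Xp.shape[1] != y.size:
            raise ValueError("sample mismatch between y and X")
        resid = y - fit.intercept - Xp.T @ fit.coefficients
    else:
        resid = y - y.mean()
    sd = resid.std()
    if sd < 1e-12:
        return np.zeros_like(resid), True
    return (resid - resid.mean()) / sd, False


@dataclass
class ClassModelOptions:
    k_target: int = 10
    folds: int = 5
    seed: int = 0
    min_candidates: int = 1
    select_kw: dict = field(default_factory=dict)


def model_class(
    targets: list[str],
    candidate_map: dict[str, list[str]],
    expr: pd.DataFrame,
    options: ClassModelOptions | None = None,
    target_values: pd.DataFrame | None = None,
) -> tuple[dict[str, tuple[ModelFit, CVResult]], pd.DataFrame]:
    """Fit selection+OLS+CV per target over a per-target candidate list.

    ``expr`` holds predictor rows; ``target_values`` (default: ``expr``)
    holds the response rows, which may be residualized copies.  Targets with
    no candidates are skipped and recorded as unmodeled in the long-format
    results table.
    """
    options = options or ClassModelOptions()
    tv = expr if target_values is None else target_values
    results: dict[str, tuple[ModelFit, CVResult]] = {}
    rows = []
    for t, target in enumerate(targets):
        cands = [c for c in candidate_map.get(target, [])
                 if c != target and c in expr.index]
        if len(cands) < options.min_candidates:
            rows.append({"target_id": target, "predictor_id": None,
                         "status": "unmodeled"})
            continue
        y = tv.loc[target].to_numpy(dtype=float)
        cand_df = expr.loc[cands]
        seed_t = int(np.random.SeedSequence([options.seed, t]).generate_state(1)[0]
                     % 2**31)
        cv = cross_validated_r2(y, cand_df, k_target=options.k_target,
                                folds=options.folds, seed=seed_t,
                                **options.select_kw)
        cv.target_id = target
        sel = select_predictors(y, cand_df, k_target=options.k_target,
                                seed=seed_t, **options.select_kw)
        fit = ols_fit(y, cand_df.loc[sel], target_id=target)
        results[target] = (fit, cv)
        for pid, coef, pv in zip(fit.predictor_ids, fit.coefficients,
                                 fit.coef_pvalues):
            rows.append({"target_id": target, "predictor_id": pid,
                         "coefficient": float(coef), "coef_p": float(pv),
                         "overall_r2": fit.overall_r2,
                         "mean_test_r2": cv.mean_test_r2, "status": "ok"})
        if not fit.predictor_ids:
            rows.append({"target_id": target, "predictor_id": None,
                         "overall_r2": fit.overall_r2,
                         "mean_test_r2": cv.mean_test_r2,
                         "status": "intercept_only"})
    table = pd.DataFrame(rows)
    return results, table


def draw_control_pool(pool_ids: list[str], size: int, seed: int) -> list[str]:
    """Seeded draw of a control predictor pool (e.g. enzyme mRNAs) of
    matched size, without replacement."""
    if size > len(pool_ids):
        raise ValueError("control pool smaller than requested size")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool_ids), size=size, replace=False)
    return [pool_ids[i] for i in sorted(idx)]
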