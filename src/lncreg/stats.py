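"""Statistical kernel: correlation thresholds, enrichment tails, corrections.

Tail probabilities are accumulated in log space (log-gamma terms) so that
extremely significant results — e.g. a binomial tail near 1e-302 — are
reported with a meaningful ``log10_p`` instead of underflowing to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

__all__ = [
    "EnrichmentResult",
    "pearson_matrix",
    "bonferroni_pcc_threshold",
    "hypergeom_tail",
    "binomial_tail",
    "proportion_ratio",
    "ks_two_sample",
    "preranked_enrichment",
    "multiple_testing",
]


@dataclass
class EnrichmentResult:
    """A test statistic with its p-value and the parameters that produced it."""

    statistic: float
    p_value: float
    log10_p: float
    method: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _row_standardize(A: np.ndarray, label: str) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[None, :]
    mu = A.mean(axis=1, keepdims=True)
    sd = A.std(axis=1, keepdims=True)
    bad = np.where(sd.ravel() == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance row(s) in {label}: {bad.tolist()}")
    return (A - mu) / sd


def pearson_matrix(A, B=None) -> np.ndarray:
    """Pearson correlations between rows of A and rows of B (default: A)."""
    Az = _row_standardize(np.asarray(A, dtype=float), "A")
    if B is None:
        Bz = Az
    else:
        Bz = _row_standardize(np.asarray(B, dtype=float), "B")
    if Az.shape[1] != Bz.shape[1]:
        raise ValueError("A and B must have the same number of samples")
    R = Az @ Bz.T / Az.shape[1]
    return np.clip(R, -1.0, 1.0)


def bonferroni_pcc_threshold(n_samples: int, n_tests: int,
                             alpha: float = 0.05) -> tuple[float, float]:
    """Smallest |r| significant at Bonferroni-corrected level alpha.

    Inverts the two-sided correlation t-test t = r sqrt((n-2)/(1-r^2)) at
    df = n-2. Returns (raw threshold, threshold rounded to 2 decimals).
    """
    if n_samples <= 3:
        raise ValueError("need n_samples > 3")
    if n_tests < 1:
        raise ValueError("need n_tests >= 1")
    corrected = alpha / n_tests
    if corrected >= 1.0:
        warnings.warn("corrected alpha >= 1; threshold is 0")
        return 0.0, 0.0
    df = n_samples - 2
    t_crit = sps.t.isf(corrected / 2.0, df)
    r = t_crit / np.sqrt(df + t_crit**2)
    return float(r), round(float(r), 2)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n), in log space."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent hypergeometric parameters "
                         f"N={N}, K={K}, n={n}, k={k}")
    hi = min(K, n)
    j = np.arange(k, hi + 1)
    log_terms = (
        gammaln(K + 1) - gammaln(j + 1) - gammaln(K - j + 1)
        + gammaln(N - K + 1) - gammaln(n - j + 1) - gammaln(N - K - n + j + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    log_p = float(logsumexp(log_terms))
    log_p = min(log_p, 0.0)
    return EnrichmentResult(
        statistic=float(k),
        p_value=float(np.exp(log_p)),
        log10_p=log_p / np.log(10.0),
        method="hypergeometric upper tail",
        parameters={"N": N, "K": K, "n": n, "k": k},
    )


def binomial_tail(k: int, n: int, p0: float,
                  alternative: str = "greater") -> EnrichmentResult:
    """Exact binomial tail P(X >= k) (or <= k), log-space accumulation."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("need 0 < p0 < 1")
    if alternative == "greater":
        j = np.arange(k, n + 1)
    elif alternative == "less":
        j = np.arange(0, k + 1)
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    log_terms = (
        gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
        + j * np.log(p0) + (n - j) * np.log1p(-p0)
    )
    log_p = min(float(logsumexp(log_terms)), 0.0)
    return EnrichmentResult(
        statistic=float(k),
        p_value=float(np.exp(log_p)),
        log10_p=log_p / np.log(10.0),
        method=f"binomial tail ({alternative})",
        parameters={"k": k, "n": n, "p0": p0},
    )


def proportion_ratio(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """(a/b)/(c/d) with a companion two-sided Fisher exact p on the 2x2 table.

    Printed enrichment reports in this field often label this ratio of
    proportions an "odds ratio"; the formula here is the ratio of proportions.
    Returns (ratio, fisher_p); round the ratio to 2 decimals for reporting.
    """
    if b <= 0 or d <= 0 or c == 0:
        raise ValueError("denominators must be positive")
    ratio = (a / b) / (c / d)
    _, fisher_p = sps.fisher_exact([[a, b - a], [c, d - c]],
                                   alternative="two-sided")
    return float(ratio), float(fisher_p)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and asymptotic two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples must have size >= 2")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def preranked_enrichment(
    ranked_ids,
    scores,
    gene_set,
    weight_exponent: float = 1.0,
    n_perms: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Preranked enrichment score with a gene-label permutation p-value.

    The running sum increments by |score|^w (normalized over the set) at
    members and decrements by 1/(N - |set|) elsewhere; ES is the extremum.
    The p-value is the fraction of random same-size sets whose |ES| meets or
    exceeds |ES| observed.
    """
    ranked_ids = list(ranked_ids)
    scores = np.asarray(scores, dtype=float)
    if len(ranked_ids) != scores.size:
        raise ValueError("ranked_ids and scores must align")
    if np.any(np.diff(scores) > 0):
        raise ValueError("scores must be sorted descending")
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    if not gene_set <= set(ranked_ids):
        raise ValueError("gene_set must be a subset of ranked_ids")
    N = len(ranked_ids)
    m = len(gene_set)
    if m >= N:
        raise ValueError("gene_set must be a proper subset of the ranking")

    member = np.fromiter((g in gene_set for g in ranked_ids), bool, N)
    w = np.abs(scores) ** weight_exponent

    def _es(hit_mask: np.ndarray) -> float:
        hit_w = np.where(hit_mask, w, 0.0)
        denom = hit_w.sum()
        if denom == 0:  # all-zero scores in the set: fall back to flat hits
            hit = hit_mask / hit_mask.sum()
        else:
            hit = hit_w / denom
        miss = (~hit_mask) / (N - hit_mask.sum())
        run = np.cumsum(hit - miss)
        return float(run[np.argmax(np.abs(run))])

    es = _es(member)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perms):
        idx = rng.choice(N, size=m, replace=False)
        mask = np.zeros(N, bool)
        mask[idx] = True
        if abs(_es(mask)) >= abs(es):
            count += 1
    return es, count / n_perms


def multiple_testing(p_values, method: str = "bh") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(1.0, ranked)
        return out
    raise ValueError(f"unknown method: {method}")
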