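"""Statistical lncRNA x protein interaction detection.

Starting from a baseline OLS model containing the selected lncRNA and
protein (TF or RBP) main effects, every elementwise product lncRNA x protein
is a candidate term.  Forward Step-AIC admits, at each step, the candidate
giving the lowest AIC provided it improves on the current model
(AIC = n ln(RSS/n) + 2(k+1), Gaussian likelihood with constants dropped —
the same ordering as the full-likelihood criterion).  An admitted term's
raw p-value is the coefficient t-test in the model at admission, Bonferroni
corrected over the target's candidate count.

Admitted terms are then verified against a median-split contrast: samples
are grouped HH/HL/LH/LL by above/below-median expression of the lncRNA and
the protein, and a triplet is shortlisted only when the HH-HL, HH-LH and
HH-LL Welch t-tests are all significant with a common direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .regress import ModelFit, ols_fit

__all__ = [
    "InteractionTerm",
    "step_aic_interactions",
    "median_split_contrasts",
    "shortlist_triplets",
    "regulator_frequency",
]

CONTRAST_KEYS = ("HH-HL", "HH-LH", "HH-LL", "HL-LL", "LH-LL")


@dataclass
class InteractionTerm:
    target_id: str
    lncrna_id: str
    protein_id: str
    protein_class: str
    coef: float
    raw_p: float
    bonferroni_p: float
    aic_before: float
    aic_after: float
    contrasts: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.aic_after < self.aic_before:
            raise ValueError("only AIC-improving terms may be stored")


def _aic(rss: float, n: int, k: int) -> float:
    """Gaussian AIC up to a constant: n ln(RSS/n) + 2 (k+1)."""
    return n * np.log(max(rss, 1e-300) / n) + 2 * (k + 1)


def _aic_vec(rss: np.ndarray, n: int, k: int) -> np.ndarray:
    return n * np.log(np.maximum(rss, 1e-300) / n) + 2 * (k + 1)


def _rss(y: np.ndarray, Z: np.ndarray) -> tuple[float, np.ndarray]:
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    r = y - Z @ beta
    return float(r @ r), beta


def step_aic_interactions(
    y,
    lnc_predictors: pd.DataFrame,
    protein_predictors: pd.DataFrame,
    protein_class: str = "TF",
    max_terms: int = 20,
    target_id: str = "target",
    bonferroni_scope: int | None = None,
) -> tuple[list[InteractionTerm], ModelFit]:
    """Forward Step-AIC over all lncRNA x protein product candidates.

    ``y`` is typically the TF-residualized target.  ``bonferroni_scope``
    overrides the correction denominator (default: this target's candidate
    product count).  Returns the admitted terms plus the final OLS refit of
    baseline + admitted products.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    lnc_ids = list(lnc_predictors.index)
    prot_ids = list(protein_predictors.index)
    L = lnc_predictors.to_numpy(dtype=float)
    P = protein_predictors.to_numpy(dtype=float)
    base = np.vstack([L, P]).T if len(lnc_ids) + len(prot_ids) else \
        np.empty((n, 0))
    if n <= base.shape[1] + 2:
        raise ValueError("too few samples for the baseline model plus a term")

    pairs = [(i, j) for i in range(len(lnc_ids)) for j in range(len(prot_ids))]
    n_candidates = bonferroni_scope if bonferroni_scope is not None else \
        max(len(pairs), 1)
    products = np.empty((len(pairs), n))
    for k, (i, j) in enumerate(pairs):
        prod = L[i] * P[j]
        sd = prod.std()
        products[k] = (prod - prod.mean()) / sd if sd > 0 else 0.0

    ones = np.ones((n, 1))
    Z = np.hstack([ones, base])
    # orthonormal basis of the current model; adding a column k changes RSS
    # by exactly (u_k . r)^2 / (u_k . u_k) with u_k the candidate residual
    # against the basis, so each forward sweep is two matrix products.
    Q, _ = np.linalg.qr(Z)
    r = y - Q @ (Q.T @ y)
    rss = float(r @ r)
    aic = _aic(rss, n, Z.shape[1] - 1)
    admitted: list[InteractionTerm] = []
    remaining = np.arange(len(pairs))
    C = products.T.copy()  # n x m candidate block, residualized in place

    while remaining.size and len(admitted) < max_terms:
        Csub = C[:, remaining]
        U = Csub - Q @ (Q.T @ Csub)
        d = np.einsum("ij,ij->j", U, U)
        num = (U.T @ r) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            drop = np.where(d > 1e-10 * n, num / d, 0.0)
        rss_new = rss - drop
        k_next = Z.shape[1]  # predictors incl. the candidate, excl. intercept
        aic_new = _aic_vec(rss_new, n, k_next)
        best = int(np.argmin(aic_new))
        if not aic_new[best] < aic - 1e-12:
            break
        k = int(remaining[best])
        u = U[:, best]
        coef = float((u @ y) / d[best])
        rss_after = float(rss_new[best])
        df = n - (Z.shape[1] - 1) - 1 - 1
        sigma2 = rss_after / df if df > 0 else np.inf
        t = coef * np.sqrt(d[best] / sigma2) if sigma2 > 0 else np.inf
        raw_p = float(2 * sps.t.sf(abs(t), df)) if df > 0 else 0.0
        i, j = pairs[k]
        admitted.append(InteractionTerm(
            target_id=target_id, lncrna_id=lnc_ids[i], protein_id=prot_ids[j],
            protein_class=protein_class, coef=coef, raw_p=raw_p,
            bonferroni_p=min(1.0, raw_p * n_candidates),
            aic_before=aic, aic_after=float(aic_new[best])))
        q_new = u / np.sqrt(d[best])
        Q = np.hstack([Q, q_new[:, None]])
        Z = np.hstack([Z, products[k][:, None]])
        r = r - q_new * (q_new @ r)
        rss, aic = rss_after, float(aic_new[best])
        remaining = remaining[remaining != k]

    cols = lnc_ids + prot_ids + [
        f"{t.lncrna_id}*{t.protein_id}" for t in admitted]
    X_final = pd.DataFrame(
        np.vstack([base.T] + [products[pairs.index((lnc_ids.index(t.lncrna_id),
                                                    prot_ids.index(t.protein_id)))]
                              [None, :] for t in admitted])
        if admitted else base.T, index=cols, columns=range(n))
    fit = ols_fit(y, X_final, target_id=target_id)
    return admitted, fit


def median_split_contrasts(y, lnc, protein, min_group: int = 3) -> dict:
    """Welch t-tests of target expression between HH/HL/LH/LL groups.

    The first letter indexes the protein, the second the lncRNA; values at
    or below the median count as "low".  Returns per-contrast
    ``(direction, p)`` with ``direction`` the sign of the mean difference;
    ``evaluable`` is False when any group is smaller than ``min_group`` or
    a test is degenerate.
    """
    y = np.asarray(y, dtype=float)
    lnc = np.asarray(lnc, dtype=float)
    protein = np.asarray(protein, dtype=float)
    if not y.size == lnc.size == protein.size:
        raise ValueError("vectors must be sample-aligned")
    hi_l = lnc > np.median(lnc)
    hi_p = protein > np.median(protein)
    groups = {
        "HH": y[hi_p & hi_l], "HL": y[hi_p & ~hi_l],
        "LH": y[~hi_p & hi_l], "LL": y[~hi_p & ~hi_l],
    }
    out = {"groups": {k: int(v.size) for k, v in groups.items()},
           "evaluable": True, "contrasts": {}}
    if min(v.size for v in groups.values()) < min_group:
        out["evaluable"] = False
        return out
    for key in CONTRAST_KEYS:
        a, b = key.split("-")
        ga, gb = groups[a], groups[b]
        if ga.std() == 0 and gb.std() == 0:
            out["contrasts"][key] = (0, 1.0)
            continue
        t, p = sps.ttest_ind(ga, gb, equal_var=False)
        direction = int(np.sign(ga.mean() - gb.mean())) or 1
        out["contrasts"][key] = (direction, float(p))
    return out


def shortlist_triplets(
    terms: list[InteractionTerm],
    p_term: float = 0.05,
    p_contrast: float = 0.05,
) -> list[InteractionTerm]:
    """Keep terms with corrected p <= ``p_term`` whose three HH contrasts
    (HH-HL, HH-LH, HH-LL) are all significant with one common direction.
    Contrasts must already be attached to each term."""
    kept = []
    for t in terms:
        if t.bonferroni_p > p_term:
            continue
        c = t.contrasts
        if not c or not c.get("evaluable", False):
            continue
        hh = [c["contrasts"].get(k) for k in ("HH-HL", "HH-LH", "HH-LL")]
        if any(v is None for v in hh):
            continue
        dirs = {d for d, _ in hh}
        if len(dirs) == 1 and all(p < p_contrast for _, p in hh):
            kept.append(t)
    return kept


def regulator_frequency(terms: list[InteractionTerm]) -> dict[str, pd.DataFrame]:
    """Per-protein and per-lncRNA counts of distinct targets and partners,
    after deduplication on (target, lncRNA, protein)."""
    seen = {}
    for t in terms:
        seen[(t.target_id, t.lncrna_id, t.protein_id)] = t
    rows = [{"target": k[0], "lncrna": k[1], "protein": k[2]}
            for k in seen]
    df = pd.DataFrame(rows, columns=["target", "lncrna", "protein"])
    prot = df.groupby("protein").agg(
        n_targets=("target", "nunique"),
        n_partners=("lncrna", "nunique")).reset_index() \
        if len(df) else pd.DataFrame(columns=["protein", "n_targets",
                                              "n_partners"])
    lnc = df.groupby("lncrna").agg(
        n_targets=("target", "nunique"),
        n_partners=("protein", "nunique")).reset_index() \
        if len(df) else pd.DataFrame(columns=["lncrna", "n_targets",
                                              "n_partners"])
    pair = df.groupby(["lncrna", "protein"]).size().rename("n_targets") \
        .reset_index() if len(df) else pd.DataFrame(columns=["lncrna",
                                                             "protein",
                                                             "n_targets"])
    return {"protein": prot, "lncrna": lnc, "pair": pair}
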