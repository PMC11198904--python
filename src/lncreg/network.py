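"""Assembly of the lncRNA regulatory network and its summaries.

Two tiers of output: the *strong-pair table* (targets modeled well and with
a null-calibrated empirical p, paired with their most significant lncRNA
predictors, annotated by location category), and the *multi-evidence
network*, where each target is refit by OLS on only those previously
significant lncRNAs that carry at least one mechanism flag (cis location,
ceRNA, or a detected lncRNA x protein interaction), keeping targets whose
refit explains enough variance and edges whose coefficients stay
significant.  A co-expression top-k baseline, external RNA-chromatin
support annotation, degree summaries and a per-regulator sign-bias binomial
test round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as lstats
from .regress import ModelFit, ols_fit

__all__ = [
    "NetworkEdge",
    "Network",
    "strong_pairs",
    "assemble_network",
    "coexpression_baseline",
    "annotate_external_support",
    "network_summary",
    "sign_bias_test",
]

EVIDENCE_FLAGS = ("overlapping", "same_tad", "proximal", "cerna",
                  "tf_interaction", "rbp_interaction")


@dataclass
class NetworkEdge:
    lncrna_id: str
    target_id: str
    sign: int
    coef: float
    coef_p: float
    evidence: dict = field(default_factory=dict)
    external_support: bool = False

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")

    def evidence_flags(self) -> list[str]:
        return [k for k in EVIDENCE_FLAGS if self.evidence.get(k)]


@dataclass
class Network:
    edges: list[NetworkEdge]

    def __post_init__(self):
        pairs = [(e.lncrna_id, e.target_id) for e in self.edges]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (lncRNA, target) edges")

    @property
    def lncrna_ids(self) -> list[str]:
        return sorted({e.lncrna_id for e in self.edges})

    @property
    def target_ids(self) -> list[str]:
        return sorted({e.target_id for e in self.edges})

    def out_degree(self) -> pd.Series:
        return pd.Series([e.lncrna_id for e in self.edges]).value_counts()

    def in_degree(self) -> pd.Series:
        return pd.Series([e.target_id for e in self.edges]).value_counts()

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.lncrna_id, e.target_id) for e in self.edges}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.edges:
            row = {"lncrna_id": e.lncrna_id, "target_id": e.target_id,
                   "sign": e.sign, "coef": e.coef, "coef_p": e.coef_p,
                   "external_support": e.external_support}
            for f in EVIDENCE_FLAGS:
                row[f] = bool(e.evidence.get(f, False))
            rows.append(row)
        return pd.DataFrame(rows)


def strong_pairs(
    fits: dict[str, ModelFit],
    cv_r2: dict[str, float],
    empirical_p: dict[str, float],
    expr: pd.DataFrame,
    categories: pd.DataFrame,
    r2_min: float = 0.2,
    emp_p_max: float = 0.01,
    ols_p_max: float = 1e-10,
    pcc_min: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strongest lncRNA-target pairs: target passes the R^2 and empirical-p
    gates, predictor passes OLS p <= ``ols_p_max`` and |PCC| >= ``pcc_min``.

    ``categories`` is a long-format location table (from
    :func:`lncreg.genomics.category_table` or ``classify_pairs``).  Returns
    (pair table, per-category composition summary with positive counts).
    """
    cat_idx = categories.set_index(["lncrna_id", "gene_id"]) \
        if len(categories) else None
    rows = []
    for target, fit in fits.items():
        if cv_r2.get(target, -np.inf) < r2_min:
            continue
        if empirical_p.get(target, 1.0) > emp_p_max:
            continue
        y = expr.loc[target].to_numpy(dtype=float)
        for pid, coef, pv in zip(fit.predictor_ids, fit.coefficients,
                                 fit.coef_pvalues):
            if pv > ols_p_max:
                continue
            x = expr.loc[pid].to_numpy(dtype=float)
            pcc = float(np.corrcoef(x, y)[0, 1])
            if abs(pcc) < pcc_min:
                continue
            row = {"target_id": target, "lncrna_id": pid,
                   "coefficient": float(coef), "ols_p": float(pv),
                   "mean_test_r2": cv_r2[target], "pcc": pcc,
                   "positive": pcc > 0}
            if cat_idx is not None and (pid, target) in cat_idx.index:
                cat = cat_idx.loc[(pid, target)]
                for f in ("overlapping", "same_tad", "proximal",
                          "same_chrom", "cerna"):
                    row[f] = bool(cat.get(f, False))
            else:
                for f in ("overlapping", "same_tad", "proximal",
                          "same_chrom", "cerna"):
                    row[f] = False
            row["non_proximal"] = not row["proximal"]
            rows.append(row)
    table = pd.DataFrame(rows)
    summary_rows = []
    for f in ("overlapping", "same_tad", "proximal", "same_chrom", "cerna",
              "non_proximal"):
        if len(table):
            sub = table[table[f]]
            summary_rows.append({
                "category": f, "n_pairs": len(sub),
                "frac": len(sub) / len(table),
                "n_positive": int(sub["positive"].sum())})
        else:
            summary_rows.append({"category": f, "n_pairs": 0, "frac": 0.0,
                                 "n_positive": 0})
    return table, pd.DataFrame(summary_rows)


def assemble_network(
    candidate_evidence: pd.DataFrame,
    expr: pd.DataFrame,
    target_expr: pd.DataFrame | None = None,
    coef_p_max: float = 0.01,
    r2_min: float = 0.2,
) -> Network:
    """Build the multi-evidence network by per-target OLS refit.

    ``candidate_evidence`` has one row per (target_id, lncrna_id) that was
    statistically significant in the per-class models, with boolean columns
    among ``EVIDENCE_FLAGS``; only rows with at least one true flag become
    candidates.  Targets whose refit R^2 falls below ``r2_min`` are dropped;
    surviving coefficients with p <= ``coef_p_max`` become signed edges.
    """
    tv = expr if target_expr is None else target_expr
    edges: list[NetworkEdge] = []
    if not len(candidate_evidence):
        return Network([])
    flags = [f for f in EVIDENCE_FLAGS if f in candidate_evidence.columns]
    ev = candidate_evidence[candidate_evidence[flags].any(axis=1)] \
        if flags else candidate_evidence.iloc[0:0]
    for target, grp in ev.groupby("target_id"):
        cands = [c for c in dict.fromkeys(grp["lncrna_id"]) if c in expr.index]
        if not cands or target not in tv.index:
            continue
        y = tv.loc[target].to_numpy(dtype=float)
        if len(y) <= len(cands) + 1:
            continue
        fit = ols_fit(y, expr.loc[cands], target_id=target)
        if fit.overall_r2 < r2_min:
            continue
        ev_by_lnc = {r["lncrna_id"]: {f: bool(r[f]) for f in flags}
                     for _, r in grp.iterrows()}
        for pid, coef, pv in zip(fit.predictor_ids, fit.coefficients,
                                 fit.coef_pvalues):
            if pv <= coef_p_max:
                edges.append(NetworkEdge(
                    lncrna_id=pid, target_id=target,
                    sign=1 if coef > 0 else -1, coef=float(coef),
                    coef_p=float(pv), evidence=ev_by_lnc.get(pid, {})))
    return Network(edges)


def coexpression_baseline(
    expr: pd.DataFrame,
    lnc_ids: list[str],
    target_ids: list[str],
    k_edges: int,
) -> pd.DataFrame:
    """Top-``k_edges`` lncRNA-target pairs by |PCC|; deterministic
    lexicographic tie-break."""
    n_pairs = len(lnc_ids) * len(target_ids)
    if k_edges > n_pairs:
        raise ValueError(f"k_edges={k_edges} exceeds {n_pairs} pairs")
    R = lstats.pearson_matrix(expr.loc[lnc_ids].to_numpy(),
                              expr.loc[target_ids].to_numpy())
    rows = [(lnc_ids[i], target_ids[j], float(R[i, j]))
            for i in range(len(lnc_ids)) for j in range(len(target_ids))
            if lnc_ids[i] != target_ids[j]]
    rows.sort(key=lambda r: (-abs(r[2]), r[0], r[1]))
    return pd.DataFrame(rows[:k_edges],
                        columns=["lncrna_id", "target_id", "pcc"])


def annotate_external_support(
    network: Network,
    rna_dna_pairs: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int = 1_000_000,
) -> tuple[Network, dict]:
    """Flag edges whose lncRNA has an RNA-chromatin interaction site within
    ``window`` of the target gene body (inclusive).

    ``rna_dna_pairs`` columns: lncrna_id, chrom, start, end (site interval).
    Returns the annotated network and support counts for enrichment testing.
    """
    by_lnc: dict[str, list] = {}
    for r in rna_dna_pairs.itertuples(index=False):
        by_lnc.setdefault(r.lncrna_id, []).append(
            (r.chrom, int(r.start), int(r.end)))
    n_supported = 0
    for e in network.edges:
        gene = annotation.loc[e.target_id]
        supported = False
        for chrom, s, t in by_lnc.get(e.lncrna_id, []):
            if chrom != gene["chrom"]:
                continue
            gap = max(gene["start"], s) - min(gene["end"], t)
            if gap <= window:  # negative gap = overlap with the gene body
                supported = True
                break
        e.external_support = supported
        n_supported += supported
    return network, {"n_edges": len(network.edges),
                     "n_supported": n_supported}


def network_summary(network: Network, hub_fraction: float = 0.1) -> dict:
    """Edge/degree summary; hubs are lncRNAs whose out-degree exceeds
    ``hub_fraction`` of the network's target count."""
    if not network.edges:
        raise ValueError("empty network")
    out_deg = network.out_degree()
    in_deg = network.in_degree()
    n_edges = len(network.edges)
    n_lnc = len(out_deg)
    n_targets = len(in_deg)
    n_act = sum(e.sign > 0 for e in network.edges)
    hub_cut = hub_fraction * n_targets
    hubs = sorted(out_deg[out_deg > hub_cut].index)
    return {
        "n_edges": n_edges,
        "n_lncrnas": n_lnc,
        "n_targets": n_targets,
        "mean_targets_per_lncrna": round(n_edges / n_lnc, 1),
        "mean_regulators_per_target": round(n_edges / n_targets, 1),
        "n_activating": n_act,
        "n_inhibitory": n_edges - n_act,
        "hubs": hubs,
    }


def sign_bias_test(network: Network, lncrna_id: str, min_edges: int = 5
                   ) -> tuple[int, float] | None:
    """One-sided binomial test of a lncRNA's activating-edge count against
    the network-wide activating fraction, sided toward the observed
    departure.  Returns (direction, p) or ``None`` when not evaluable
    (too few edges, or a degenerate global ratio)."""
    n_act = sum(e.sign > 0 for e in network.edges)
    n_all = len(network.edges)
    if n_all == 0:
        return None
    p_global = n_act / n_all
    if p_global in (0.0, 1.0):
        return None
    mine = [e for e in network.edges if e.lncrna_id == lncrna_id]
    if len(mine) < min_edges:
        return None
    k = sum(e.sign > 0 for e in mine)
    n = len(mine)
    if k / n >= p_global:
        res = lstats.binomial_tail(k, n, p_global, alternative="greater")
        return 1, res.p_value
    res = lstats.binomial_tail(k, n, p_global, alternative="less")
    return -1, res.p_value
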