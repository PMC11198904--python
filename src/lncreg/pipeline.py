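"""End-to-end orchestration: preprocess -> TF models -> residualize ->
lncRNA models -> empirical nulls -> location/ceRNA categories ->
interaction terms -> strong pairs -> multi-evidence network.

Every stage's outputs are persisted as TSV/JSON under the run directory and
logged in a :class:`RunReport`; all randomness descends deterministically
from the single config seed via per-stage derived seeds, so re-running with
the same config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genomics, io, network as net, nulls as nulls_mod
from .interactions import median_split_contrasts, shortlist_triplets, \
    step_aic_interactions
from .preprocess import ExpressionMatrix, cpm_filter, normalize_log_standardize, \
    residualize_covariates, tmm_factors
from .regress import ClassModelOptions, model_class, residualize_by_model, \
    select_predictors
from .genomics import genes_of_class

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "RunReport", "run_pipeline", "stage_seed"]


@dataclass
class AnalysisConfig:
    """Thresholds and sizes for one analysis run."""

    k_predictors: int = 10
    folds: int = 5
    n_null_reps: int = 100
    cpm_min: float = 1.0
    min_samples_fraction: float = 0.41
    proximal_dist: int = 1_000_000
    r2_min: float = 0.2
    emp_p_max: float = 0.01
    strong_ols_p: float = 1e-10
    pcc_min: float = 0.1
    edge_coef_p: float = 0.01
    interaction_gate_tf: float = 0.05
    interaction_gate_rbp: float = 0.01
    contrast_p: float = 0.05
    cerna_emp_p_max: float = 0.0
    evaluate_cerna_null: bool = True
    run_control_null: bool = True
    max_interaction_terms: int = 20
    seed: int = 0

    def validate(self) -> "AnalysisConfig":
        if not 0 < self.min_samples_fraction <= 1:
            raise ValueError("min_samples_fraction must lie in (0, 1]")
        for name in ("emp_p_max", "strong_ols_p", "pcc_min", "edge_coef_p",
                     "interaction_gate_tf", "interaction_gate_rbp",
                     "contrast_p", "cerna_emp_p_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.folds < 2 or self.k_predictors < 1 or self.n_null_reps < 1:
            raise ValueError("invalid folds/k_predictors/n_null_reps")
        return self


@dataclass
class RunReport:
    config: dict
    seeds: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def record(self, stage: str, **kv):
        self.counts.setdefault(stage, {}).update(kv)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    return int(np.random.SeedSequence(
        [seed, zlib.crc32(stage.encode())]).generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: AnalysisConfig, inputs: dict,
                 outdir: str | Path) -> RunReport:
    """Run the full analysis on in-memory inputs.

    ``inputs`` needs: counts (DataFrame), covariates (DataFrame), annotation
    (validated DataFrame), tads (DataFrame), mirna_gene and mirna_lnc
    (DataFrames); optionally rna_dna_pairs.  Outputs and a JSON run report
    are written under ``outdir``.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))
    annotation = genomics.validate_annotation(inputs["annotation"])
    tads = genomics.validate_tads(inputs["tads"])

    # ---- stage 1: preprocessing --------------------------------------
    counts = inputs["counts"]
    min_samples = max(2, int(round(config.min_samples_fraction
                                   * counts.shape[1])))
    filtered = cpm_filter(counts, cpm_min=config.cpm_min,
                          min_samples=min_samples)
    factors = tmm_factors(filtered)
    expr0 = normalize_log_standardize(filtered, factors)
    expr = residualize_covariates(expr0, inputs["covariates"])
    report.record("preprocess", n_genes_in=counts.shape[0],
                  n_genes_filtered=filtered.shape[0],
                  n_genes_final=expr.values.shape[0],
                  n_samples=expr.values.shape[1])
    E = expr.values

    lnc_ids = [g for g in genes_of_class(annotation, "lncRNA") if g in E.index]
    tf_ids = [g for g in genes_of_class(annotation, "TF") if g in E.index]
    rbp_ids = [g for g in genes_of_class(annotation, "RBP") if g in E.index]
    enzyme_ids = [g for g in genes_of_class(annotation, "enzyme")
                  if g in E.index]
    targets = [g for g in genes_of_class(annotation, "mRNA")
               if g in E.index and g not in tf_ids]
    if not lnc_ids:
        raise ValueError("no lncRNA genes present after preprocessing")

    # ---- stage 2: TF models and residualization ----------------------
    opt = ClassModelOptions(k_target=config.k_predictors, folds=config.folds,
                            seed=stage_seed(config.seed, "tf_models"))
    tf_results, tf_table = model_class(
        targets, {t: tf_ids for t in targets}, E, opt)
    tf_table.to_csv(out / "tf_models.tsv", sep="\t", index=False)
    resid_rows, kept = [], []
    for t in targets:
        if t not in tf_results:
            continue
        fit, _ = tf_results[t]
        r, const = residualize_by_model(E.loc[t].to_numpy(), fit, E)
        if not const:
            resid_rows.append(r)
            kept.append(t)
    resid = pd.DataFrame(resid_rows, index=kept, columns=E.columns)
    report.record("tf_models", n_modeled=len(tf_results),
                  n_residualized=len(kept))

    # ---- stage 3: lncRNA models on TF residuals ----------------------
    opt_lnc = ClassModelOptions(k_target=config.k_predictors,
                                folds=config.folds,
                                seed=stage_seed(config.seed, "lnc_models"))
    lnc_results, lnc_table = model_class(
        kept, {t: lnc_ids for t in kept}, E, opt_lnc, target_values=resid)
    lnc_table.to_csv(out / "lnc_models.tsv", sep="\t", index=False)
    cv_r2 = {t: cv.mean_test_r2 for t, (_, cv) in lnc_results.items()}
    report.record("lnc_models", n_modeled=len(lnc_results))

    # ---- stage 4: enzyme-control empirical null ----------------------
    null_seed = stage_seed(config.seed, "control_null")
    emp_p, null_rows = {}, []
    pool = E.loc[enzyme_ids] if enzyme_ids else None
    pool_size = min(len(lnc_ids), len(enzyme_ids)) if enzyme_ids else 0
    for ti, t in enumerate(lnc_results):
        if pool is None or pool_size < 1 or not config.run_control_null:
            break
        pool_t = pool.drop(index=t, errors="ignore")
        en = nulls_mod.control_set_null(
            t, resid.loc[t].to_numpy(), cv_r2[t], pool_t,
            min(pool_size, len(pool_t)),
            n_reps=config.n_null_reps, seed=null_seed + ti,
            k_target=config.k_predictors, folds=config.folds)
        emp_p[t] = en.empirical_p
        null_rows += [{"target_id": t, "rep": i, "null_r2": v}
                      for i, v in enumerate(en.null_r2)]
    pd.DataFrame(null_rows).to_csv(out / "control_null.tsv", sep="\t",
                                   index=False)
    nulls_dict = {t: _null_stub(t, cv_r2[t], emp_p[t], config.n_null_reps)
                  for t in emp_p}
    summary = nulls_mod.threshold_summary(cv_r2, nulls_dict,
                                          r2_min=config.r2_min,
                                          p_max=config.emp_p_max)
    report.record("nulls", n_pass_both=summary["n_pass_both"],
                  frac_pass_both=summary["frac_pass_both"])

    # ---- stage 5: categories and ceRNA -------------------------------
    cerna_pairs = genomics.find_cerna_pairs(inputs["mirna_gene"],
                                            inputs["mirna_lnc"])
    cats = genomics.category_table(lnc_ids, kept, annotation, tads,
                                   proximal_dist=config.proximal_dist,
                                   cerna_pairs=cerna_pairs)
    cats.to_csv(out / "categories.tsv", sep="\t", index=False)
    cerna_emp_p = {}
    if config.evaluate_cerna_null and cerna_pairs:
        cseed = stage_seed(config.seed, "cerna_null")
        for ti, t in enumerate(kept):
            cands = [l for l in lnc_ids if (l, t) in cerna_pairs]
            if not cands:
                continue
            copt = ClassModelOptions(k_target=config.k_predictors,
                                     folds=config.folds, seed=cseed + ti)
            res, _ = model_class([t], {t: cands}, E, copt, target_values=resid)
            if t not in res:
                continue
            obs = res[t][1].mean_test_r2
            en = nulls_mod.control_set_null(
                t, resid.loc[t].to_numpy(), obs, E.loc[lnc_ids], len(cands),
                n_reps=config.n_null_reps, seed=cseed + ti,
                k_target=config.k_predictors, folds=config.folds)
            cerna_emp_p[t] = en.empirical_p
    report.record("categories", n_cerna_pairs=len(cerna_pairs),
                  n_cerna_targets_tested=len(cerna_emp_p))

    # ---- stage 6: interaction terms ----------------------------------
    iseed = stage_seed(config.seed, "interactions")
    all_terms = []
    for klass, prot_pool, gate in (("TF", tf_ids, config.interaction_gate_tf),
                                   ("RBP", rbp_ids,
                                    config.interaction_gate_rbp)):
        for t in kept:
            if t not in lnc_results:
                continue
            lnc_sel = lnc_results[t][0].predictor_ids
            if klass == "TF":
                prot_sel = tf_results[t][0].predictor_ids if t in tf_results \
                    else []
            elif prot_pool:
                prot_sel = select_predictors(
                    resid.loc[t].to_numpy(), E.loc[prot_pool],
                    k_target=config.k_predictors, exclude={t}, seed=iseed)
            else:
                prot_sel = []
            if not lnc_sel or not prot_sel:
                continue
            y = resid.loc[t].to_numpy()
            terms, _ = step_aic_interactions(
                y, E.loc[lnc_sel], E.loc[prot_sel], protein_class=klass,
                max_terms=config.max_interaction_terms, target_id=t)
            for term in terms:
                term.contrasts = median_split_contrasts(
                    y, E.loc[term.lncrna_id].to_numpy(),
                    E.loc[term.protein_id].to_numpy())
            all_terms += shortlist_triplets(terms, p_term=gate,
                                            p_contrast=config.contrast_p)
    _terms_frame(all_terms).to_csv(out / "interaction_terms.tsv", sep="\t",
                                   index=False)
    report.record("interactions", n_terms=len(all_terms))

    # ---- stage 7: strong pairs ---------------------------------------
    fits = {t: fr[0] for t, fr in lnc_results.items()}
    # correlation filter: residualized targets vs lncRNA expression
    pcc_expr = pd.concat([resid, E.loc[[l for l in lnc_ids
                                        if l not in resid.index]]])
    sp_table, sp_summary = net.strong_pairs(
        fits, cv_r2, emp_p, pcc_expr, cats, r2_min=config.r2_min,
        emp_p_max=config.emp_p_max, ols_p_max=config.strong_ols_p,
        pcc_min=config.pcc_min)
    sp_table.to_csv(out / "strong_pairs.tsv", sep="\t", index=False)
    sp_summary.to_csv(out / "strong_pairs_summary.tsv", sep="\t", index=False)
    report.record("strong_pairs", n_pairs=len(sp_table))

    # ---- stage 8: multi-evidence network -----------------------------
    cat_idx = cats.set_index(["lncrna_id", "gene_id"])
    inter_idx = {(t.lncrna_id, t.target_id): t.protein_class
                 for t in all_terms}
    ev_rows = []
    for t, fit in fits.items():
        for pid, pv in zip(fit.predictor_ids, fit.coef_pvalues):
            if pv > config.edge_coef_p:
                continue
            flags = {f: False for f in net.EVIDENCE_FLAGS}
            if (pid, t) in cat_idx.index:
                c = cat_idx.loc[(pid, t)]
                for f in ("overlapping", "same_tad", "proximal"):
                    flags[f] = bool(c[f])
                cerna_ok = bool(c["cerna"])
                if config.evaluate_cerna_null:
                    cerna_ok = cerna_ok and cerna_emp_p.get(t, 1.0) \
                        <= config.cerna_emp_p_max
                flags["cerna"] = cerna_ok
            pc = inter_idx.get((pid, t))
            if pc == "TF":
                flags["tf_interaction"] = True
            elif pc == "RBP":
                flags["rbp_interaction"] = True
            if any(flags.values()):
                ev_rows.append({"target_id": t, "lncrna_id": pid, **flags})
    evidence = pd.DataFrame(ev_rows)
    network = net.assemble_network(evidence, E, target_expr=resid,
                                   coef_p_max=config.edge_coef_p,
                                   r2_min=config.r2_min)
    if "rna_dna_pairs" in inputs and network.edges:
        network, support = net.annotate_external_support(
            network, inputs["rna_dna_pairs"], annotation)
        report.record("external_support", **support)
    network.to_frame().to_csv(out / "network_edges.tsv", sep="\t", index=False)
    if network.edges:
        report.record("network", **{k: v for k, v in
                                    net.network_summary(network).items()
                                    if k != "hubs"})
    else:
        report.record("network", n_edges=0)

    # ---- finalize -----------------------------------------------------
    report.seeds = {s: stage_seed(config.seed, s) for s in
                    ("tf_models", "lnc_models", "control_null", "cerna_null",
                     "interactions")}
    for f in sorted(out.glob("*.tsv")):
        report.manifest[f.name] = _sha256(f)
    io.write_json_report(asdict(report), out / "run_report.json")
    report.manifest["run_report.json"] = _sha256(out / "run_report.json")
    return report


def _null_stub(t, obs, p, n_reps):
    """Reconstruct an EmpiricalNull carrying a precomputed empirical p."""
    k = int(round(p * n_reps))
    null = [obs + 1.0] * k + [obs - 1.0] * (n_reps - k)
    return nulls_mod.EmpiricalNull(t, obs, null)


def _terms_frame(terms) -> pd.DataFrame:
    rows = []
    for t in terms:
        row = {"target_id": t.target_id, "lncrna_id": t.lncrna_id,
               "protein_id": t.protein_id, "protein_class": t.protein_class,
               "coef": t.coef, "raw_p": t.raw_p,
               "bonferroni_p": t.bonferroni_p}
        for key, val in (t.contrasts.get("contrasts", {}) or {}).items():
            row[f"{key}_dir"], row[f"{key}_p"] = val
        rows.append(row)
    return pd.DataFrame(rows)
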