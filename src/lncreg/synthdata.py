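"""Seeded synthetic genomes, regulatory ground truth, and RNA-seq counts.

The generator produces data with exactly the statistical structure the
inference pipeline assumes, so that every downstream stage is testable
without external downloads:

* a genome of several chromosomes tiled by non-overlapping TADs, with
  lncRNA-mRNA pairs planted in each location category (overlapping in both
  strand arrangements, same-TAD, proximal < 1 Mbp, distal same-chromosome,
  trans);
* a regulatory ground truth in which transcription factors drive mRNA
  targets *and* lncRNAs (the shared-TF confounding the pipeline must
  remove), lncRNAs carry direct effects biased toward cis location and
  positive sign, ceRNA triplets share a miRNA partner per cell line, and
  lncRNA x protein product terms model scaffold-type interactions;
* negative-binomial counts over a latent log-linear model, evaluated in
  topological order (the ground-truth graph must be a DAG), with per-sample
  library-size scaling and linear nuisance-covariate effects.

Effect sizes are expressed in standard deviations of the latent
log-expression of the regulator, so a single edge with effect beta against
unit latent noise yields a population regulator-target correlation of
beta / sqrt(beta^2 + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_annotation",
    "generate_truth",
    "simulate_counts",
    "simulate_bundle",
    "write_bundle",
]

CELL_LINES = ("MCF7", "MDA231", "T47D")
SEX_LEVELS = ("female", "male")
ETHNICITY_LEVELS = ("not_hispanic", "hispanic")
RACE_LEVELS = ("white", "black", "asian", "other")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 500
    n_mrna: int = 150
    n_lncrna: int = 60
    n_tf: int = 40
    n_rbp: int = 20
    n_enzyme: int = 25
    n_mirna: int = 15
    n_chrom: int = 5
    chrom_length: int = 60_000_000
    tad_size: int = 1_000_000
    frac_cis_regulators: float = 0.5
    beta_tf: float = 1.0
    beta_lnc: float = 1.0
    beta_interaction: float = 1.0
    nb_dispersion: float = 0.1
    libsize_range: tuple[float, float] = (0.7, 1.3)
    covariate_effect: float = 0.3
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        counts = [self.n_samples, self.n_mrna, self.n_lncrna, self.n_tf,
                  self.n_rbp, self.n_enzyme, self.n_mirna, self.n_chrom,
                  self.chrom_length, self.tad_size]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.frac_cis_regulators <= 1.0:
            raise ValueError("frac_cis_regulators must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ValueError("libsize_range must satisfy 0 < low <= high")
        return self

    @property
    def n_expressed(self) -> int:
        return (self.n_mrna + self.n_lncrna + self.n_tf + self.n_rbp
                + self.n_enzyme)


@dataclass
class GroundTruth:
    """Planted regulatory structure behind one simulated cohort."""

    annotation: pd.DataFrame
    tads: pd.DataFrame
    tf_edges: list  # (tf_id, target_id, beta)
    lnc_edges: list  # (lnc_id, target_id, beta, category_label)
    cerna_triplets: list  # (mirna_id, lnc_id, mrna_id, cell_line)
    interaction_triplets: list  # (lnc_id, protein_id, target_id, beta)
    covariate_betas: pd.DataFrame
    mirna_gene: pd.DataFrame = field(default_factory=pd.DataFrame)
    mirna_lnc: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> "GroundTruth":
        known = set(self.annotation.index)
        for src, tgt, *_ in self.tf_edges + [e[:2] for e in self.lnc_edges]:
            if src not in known or tgt not in known:
                raise ValueError(f"edge references unknown gene: {src}->{tgt}")
        return self

    def lnc_edge_pairs(self) -> set[tuple[str, str]]:
        return {(l, t) for l, t, *_ in self.lnc_edges}


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def generate_annotation(config: SimulationConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Place genes and TADs on the synthetic genome.

    Returns ``(annotation, tads, planted_pairs)``.  ``planted_pairs`` is the
    construction bookkeeping: one row per deliberately placed lncRNA-mRNA
    pair with its intended category label (overlapping / same_tad /
    proximal / distal / trans); downstream truth generation and test
    oracles both read it.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    per_chrom = int(np.ceil(config.n_expressed / max(config.n_chrom, 1)))
    margin = 12_000_000  # keeps planted distal/proximal placements on-chrom
    if config.chrom_length < max(per_chrom * 150_000, margin):
        raise ValueError(
            f"chromosome length {config.chrom_length} too short to place "
            f"~{per_chrom} genes per chromosome with planted pair layouts")

    # --- TADs tile each chromosome without overlap ---------------------
    tad_rows = []
    for c in range(config.n_chrom):
        pos = 0
        while pos < config.chrom_length:
            size = int(config.tad_size * rng.uniform(0.6, 1.4))
            end = min(pos + size, config.chrom_length)
            tad_rows.append({"chrom": f"chr{c + 1}", "start": pos, "end": end})
            pos = end
    tads = pd.DataFrame(tad_rows)

    # --- mRNA-class genes (mRNA / TF / RBP / enzyme) -------------------
    classes = (["mRNA"] * config.n_mrna + ["TF"] * config.n_tf
               + ["RBP"] * config.n_rbp + ["enzyme"] * config.n_enzyme)
    rows = []
    for i, cls in enumerate(classes):
        chrom = f"chr{i % config.n_chrom + 1}"
        length = int(rng.uniform(5_000, 100_000))
        # keep mRNAs away from chromosome ends so planted lncRNA layouts
        # (distal gaps up to ~4 Mbp) always fit
        start = int(rng.uniform(5_000_000,
                                config.chrom_length - length - 5_000_000))
        prefix = {"mRNA": "G", "TF": "TF", "RBP": "RBP", "enzyme": "ENZ"}[cls]
        rows.append({
            "gene_id": f"{prefix}{i:04d}", "gene_name": f"{prefix.lower()}{i}",
            "gene_class": "mRNA", "chrom": chrom, "start": start,
            "end": start + length, "strand": rng.choice(["+", "-"]),
            "is_tf": cls == "TF", "is_rbp": cls == "RBP",
            "is_enzyme": cls == "enzyme",
        })
    ann = pd.DataFrame(rows).set_index("gene_id", drop=False)
    mrna_ids = list(ann.index[~(ann["is_tf"] | ann["is_rbp"] | ann["is_enzyme"])])

    # --- planted lncRNA-mRNA pairs -------------------------------------
    n_cis = int(round(config.frac_cis_regulators * config.n_lncrna))
    cis_labels = [("overlapping", "same_tad", "proximal")[i % 3]
                  for i in range(n_cis)]
    trans_labels = [("trans", "distal")[i % 2]
                    for i in range(config.n_lncrna - n_cis)]
    labels = cis_labels + trans_labels
    partners = rng.choice(mrna_ids, size=config.n_lncrna, replace=False) \
        if config.n_lncrna <= len(mrna_ids) else \
        rng.choice(mrna_ids, size=config.n_lncrna, replace=True)

    lnc_rows, planted = [], []
    for i, label in enumerate(labels):
        gid = f"LNC{i:04d}"
        partner = ann.loc[partners[i]]
        length = int(rng.uniform(1_000, 30_000))
        strand = rng.choice(["+", "-"])
        chrom = partner["chrom"]
        if label == "overlapping":
            lo = max(0, int(partner["start"]) - length // 2)
            hi = int(partner["end"]) - 1_000
            start = int(rng.uniform(lo, max(lo + 1, hi)))
        elif label == "same_tad":
            p5 = (int(partner["start"]) if partner["strand"] == "+"
                  else int(partner["end"]) - 1)
            tad = tads[(tads["chrom"] == chrom) & (tads["start"] <= p5)
                       & (p5 < tads["end"])].iloc[0]
            # place fully inside the partner's TAD but clear of its body
            left = (int(tad["start"]), int(partner["start"]) - length - 1)
            right = (int(partner["end"]) + 1, int(tad["end"]) - length - 1)
            rooms = [r for r in (left, right) if r[1] > r[0]]
            if rooms:
                lo, hi = max(rooms, key=lambda r: r[1] - r[0])
                start = int(rng.uniform(lo, hi))
            else:  # partner fills its TAD: the pair degenerates to overlap
                start = int(partner["start"]) + 100
                label = "overlapping"
        elif label == "proximal":
            gap = int(rng.uniform(200_000, 900_000 - length))
            start = int(partner["end"]) + gap
            if start + length >= config.chrom_length:
                start = max(0, int(partner["start"]) - gap - length)
        elif label == "distal":
            gap = int(rng.uniform(2_000_000, 4_000_000))
            start = int(partner["end"]) + gap
            if start + length >= config.chrom_length:
                start = max(0, int(partner["start"]) - gap - length)
        else:  # trans
            others = [f"chr{c + 1}" for c in range(config.n_chrom)
                      if f"chr{c + 1}" != chrom]
            chrom = rng.choice(others) if others else chrom
            start = int(rng.uniform(0, config.chrom_length - length))
        start = int(np.clip(start, 0, config.chrom_length - length - 1))
        lnc_rows.append({
            "gene_id": gid, "gene_name": f"lnc{i}", "gene_class": "lncRNA",
            "chrom": chrom, "start": start, "end": start + length,
            "strand": strand, "is_tf": False, "is_rbp": False,
            "is_enzyme": False,
        })
        planted.append({"lncrna_id": gid, "gene_id": partner["gene_id"],
                        "label": label})

    mirna_rows = [{
        "gene_id": f"MIR{i:03d}", "gene_name": f"mir{i}",
        "gene_class": "miRNA", "chrom": f"chr{i % config.n_chrom + 1}",
        "start": 100 + 500 * i, "end": 200 + 500 * i,
        "strand": "+", "is_tf": False, "is_rbp": False, "is_enzyme": False,
    } for i in range(config.n_mirna)]

    parts = [ann]
    for extra in (lnc_rows, mirna_rows):
        if extra:
            parts.append(pd.DataFrame(extra).set_index("gene_id", drop=False))
    annotation = pd.concat(parts)
    return annotation, tads, pd.DataFrame(planted,
                                          columns=["lncrna_id", "gene_id",
                                                   "label"])


def generate_truth(
    annotation: pd.DataFrame,
    tads: pd.DataFrame,
    config: SimulationConfig,
    planted_pairs: pd.DataFrame | None = None,
    tf_edges_per_target: tuple[int, int] = (0, 3),
    tf_confound_prob: float = 0.4,
    cis_positive_prob: float = 0.97,
    n_decoy_interactions: int = 100,
) -> GroundTruth:
    """Plant the regulatory ground truth on an annotated genome.

    Every planted lncRNA-mRNA pair from the annotation step becomes a direct
    lncRNA edge (cis pairs with positive sign at ``cis_positive_prob``);
    half of the trans-category edges also receive ceRNA evidence (a shared
    miRNA in one cell line) and the other half a lncRNA x protein product
    term so that all planted edges carry some mechanism.  TFs additionally
    drive a fraction of lncRNAs, creating the shared-regulator confounding
    the pipeline is designed to remove.  ``beta_lnc = 0`` plants no lncRNA
    edges at all.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    if planted_pairs is None:
        planted_pairs = pd.DataFrame(columns=["lncrna_id", "gene_id", "label"])
    tf_ids = list(annotation.index[annotation["is_tf"].astype(bool)])
    rbp_ids = list(annotation.index[annotation["is_rbp"].astype(bool)])
    lnc_ids = list(annotation.index[annotation["gene_class"] == "lncRNA"])
    mirna_ids = list(annotation.index[annotation["gene_class"] == "miRNA"])
    target_ids = list(annotation.index[
        (annotation["gene_class"] == "mRNA") & ~annotation["is_tf"]])

    tf_edges = []
    if tf_ids and config.beta_tf != 0:
        lo, hi = tf_edges_per_target
        for tgt in target_ids:
            for tf in rng.choice(tf_ids, size=rng.integers(lo, hi + 1),
                                 replace=False):
                sign = 1.0 if rng.random() < 0.6 else -1.0
                tf_edges.append((tf, tgt, sign * config.beta_tf))
        for lnc in lnc_ids:  # TF-driven lncRNAs: the confounder
            if rng.random() < tf_confound_prob:
                tf = rng.choice(tf_ids)
                sign = 1.0 if rng.random() < 0.6 else -1.0
                tf_edges.append((tf, lnc, sign * config.beta_tf))

    lnc_edges, cerna, inter = [], [], []
    if config.beta_lnc != 0:
        trans_seen = 0
        for row in planted_pairs.itertuples(index=False):
            is_cis = row.label in ("overlapping", "same_tad", "proximal")
            if is_cis:
                sign = 1.0 if rng.random() < cis_positive_prob else -1.0
            elif trans_seen % 2 == 1:
                # interaction-evidenced trans edge: an activating lncRNA
                # whose effect is amplified by the protein partner -- main
                # and product effects share a positive sign so the
                # median-split contrasts are directionally consistent
                sign = 1.0
            else:
                sign = 1.0 if rng.random() < 0.5 else -1.0
            lnc_edges.append((row.lncrna_id, row.gene_id,
                              sign * config.beta_lnc, row.label))
            if not is_cis:
                if trans_seen % 2 == 0 and mirna_ids:
                    # unique (miRNA, cell line) per triplet so that shared
                    # partners never arise between different planted pairs
                    combo = trans_seen // 2
                    m = mirna_ids[combo % len(mirna_ids)]
                    cl = CELL_LINES[(combo // len(mirna_ids)) % len(CELL_LINES)]
                    if combo < len(mirna_ids) * len(CELL_LINES):
                        cerna.append((m, row.lncrna_id, row.gene_id, cl))
                else:
                    pool = rbp_ids + tf_ids
                    if pool and config.beta_interaction != 0:
                        prot = pool[trans_seen % len(pool)]
                        inter.append((row.lncrna_id, prot, row.gene_id,
                                      config.beta_interaction))
                        # give the protein partner a main effect so selection
                        # keeps it in the baseline model
                        if config.beta_tf != 0 and not any(
                                s == prot and t == row.gene_id
                                for s, t, _ in tf_edges):
                            tf_edges.append((prot, row.gene_id, config.beta_tf))
                trans_seen += 1

    # miRNA interaction tables: planted triplets plus decoys that can never
    # produce a shared (miRNA, cell line) by construction
    mg_rows = [{"mirna_id": m, "partner_id": g, "partner_class": "mRNA",
                "cell_line": cl} for m, _, g, cl in cerna]
    ml_rows = [{"mirna_id": m, "partner_id": l, "partner_class": "lncRNA",
                "cell_line": cl} for m, l, _, cl in cerna]
    for d in range(n_decoy_interactions):
        cl = f"DECOY_{d}"
        if mirna_ids and target_ids and d % 2 == 0:
            mg_rows.append({"mirna_id": rng.choice(mirna_ids),
                            "partner_id": rng.choice(target_ids),
                            "partner_class": "mRNA", "cell_line": cl})
        elif mirna_ids and lnc_ids:
            ml_rows.append({"mirna_id": rng.choice(mirna_ids),
                            "partner_id": rng.choice(lnc_ids),
                            "partner_class": "lncRNA", "cell_line": cl})

    expressed = annotation.index[annotation["gene_class"] != "miRNA"]
    cov_cols = (["age"] + [f"sex_{l}" for l in SEX_LEVELS[1:]]
                + [f"ethnicity_{l}" for l in ETHNICITY_LEVELS[1:]]
                + [f"race_{l}" for l in RACE_LEVELS[1:]])
    betas = rng.normal(0.0, config.covariate_effect,
                       size=(len(expressed), len(cov_cols))) \
        if config.covariate_effect > 0 else np.zeros((len(expressed),
                                                      len(cov_cols)))
    covariate_betas = pd.DataFrame(betas, index=expressed, columns=cov_cols)

    truth = GroundTruth(
        annotation=annotation, tads=tads, tf_edges=tf_edges,
        lnc_edges=lnc_edges, cerna_triplets=cerna,
        interaction_triplets=inter, covariate_betas=covariate_betas,
        mirna_gene=pd.DataFrame(mg_rows, columns=["mirna_id", "partner_id",
                                                  "partner_class", "cell_line"]),
        mirna_lnc=pd.DataFrame(ml_rows, columns=["mirna_id", "partner_id",
                                                 "partner_class", "cell_line"]),
    )
    return truth.validate()


def _topological_order(nodes: list[str], edges: list[tuple[str, str]]
                       ) -> list[str]:
    """Kahn's algorithm; raises on cycles."""
    children: dict[str, list[str]] = {n: [] for n in nodes}
    indeg = {n: 0 for n in nodes}
    for src, tgt in edges:
        children[src].append(tgt)
        indeg[tgt] += 1
    queue = [n for n in nodes if indeg[n] == 0]
    order = []
    while queue:
        n = queue.pop()
        order.append(n)
        for ch in children[n]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                queue.append(ch)
    if len(order) != len(nodes):
        raise ValueError("ground-truth regulatory graph contains a cycle")
    return order


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    rng = _rng(config.seed, 2)
    n = config.n_samples
    return pd.DataFrame({
        "age": rng.integers(30, 81, size=n),
        "sex": rng.choice(SEX_LEVELS, size=n, p=[0.9, 0.1]),
        "ethnicity": rng.choice(ETHNICITY_LEVELS, size=n, p=[0.85, 0.15]),
        "race": rng.choice(RACE_LEVELS, size=n, p=[0.6, 0.2, 0.12, 0.08]),
    }, index=[f"S{i:04d}" for i in range(n)])


def _covariate_design_from(cov: pd.DataFrame, betas: pd.DataFrame) -> np.ndarray:
    age = cov["age"].to_numpy(dtype=float)
    cols = {"age": (age - age.mean()) / age.std()}
    for levels, name in ((SEX_LEVELS, "sex"), (ETHNICITY_LEVELS, "ethnicity"),
                         (RACE_LEVELS, "race")):
        for level in levels[1:]:
            cols[f"{name}_{level}"] = (cov[name] == level).to_numpy(float)
    return np.column_stack([cols[c] for c in betas.columns])


def simulate_counts(
    truth: GroundTruth,
    config: SimulationConfig,
    covariates: pd.DataFrame | None = None,
    return_latent: bool = False,
):
    """Draw a negative-binomial count matrix from the planted model.

    Latent log-expression per gene = covariate effects + sum of regulator
    effects (standardized parent latents) + sum of interaction products +
    unit-variance Gaussian noise; the latent is then re-standardized, and
    counts are NB with mean ``libsize_s * base_g * exp(latent)`` and
    dispersion ``nb_dispersion`` (0 falls back to Poisson).
    """
    config.validate()
    rng = _rng(config.seed, 3)
    if covariates is None:
        covariates = simulate_covariates(config)
    n = len(covariates)
    genes = [g for g in truth.annotation.index
             if truth.annotation.loc[g, "gene_class"] != "miRNA"]
    dep_edges = [(src, tgt) for src, tgt, _ in truth.tf_edges]
    dep_edges += [(l, t) for l, t, _, _ in truth.lnc_edges]
    dep_edges += [(l, t) for l, p, t, _ in truth.interaction_triplets]
    dep_edges += [(p, t) for l, p, t, _ in truth.interaction_triplets]
    order = _topological_order(genes, dep_edges)

    parents: dict[str, list[tuple[str, float]]] = {g: [] for g in genes}
    for src, tgt, beta in truth.tf_edges:
        parents[tgt].append((src, beta))
    for lnc, tgt, beta, _ in truth.lnc_edges:
        parents[tgt].append((lnc, beta))
    prods: dict[str, list[tuple[str, str, float]]] = {g: [] for g in genes}
    for lnc, prot, tgt, beta in truth.interaction_triplets:
        prods[tgt].append((lnc, prot, beta))

    D = _covariate_design_from(covariates, truth.covariate_betas)
    latent = {}
    for g in order:
        z = rng.standard_normal(n)  # unit latent noise
        z = z + D @ truth.covariate_betas.loc[g].to_numpy()
        for src, beta in parents[g]:
            z = z + beta * latent[src]
        for lnc, prot, beta in prods[g]:
            z = z + beta * latent[lnc] * latent[prot]
        latent[g] = (z - z.mean()) / z.std()

    Z = np.vstack([latent[g] for g in genes])
    base = rng.lognormal(np.log(300.0), 0.5, size=len(genes))
    lib = rng.uniform(*config.libsize_range, size=n)
    mu = lib[None, :] * base[:, None] * np.exp(Z)
    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=genes, columns=covariates.index)
    if return_latent:
        return counts_df, covariates, pd.DataFrame(Z, index=genes,
                                                   columns=covariates.index)
    return counts_df, covariates


def simulate_bundle(config: SimulationConfig, **truth_kwargs) -> dict:
    """Full simulation: annotation, TADs, truth, counts, covariates.

    ``truth_kwargs`` forward to :func:`generate_truth` (e.g. the TF-parent
    range or confounding probability for a specific benchmark scenario).
    """
    annotation, tads, planted = generate_annotation(config)
    truth = generate_truth(annotation, tads, config, planted, **truth_kwargs)
    counts, covariates = simulate_counts(truth, config)
    return {"config": config, "annotation": annotation, "tads": tads,
            "planted_pairs": planted, "truth": truth, "counts": counts,
            "covariates": covariates}


def write_bundle(bundle: dict, outdir) -> dict[str, str]:
    """Persist a simulated bundle as plain-text tables; returns the manifest."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth: GroundTruth = bundle["truth"]
    files = {}

    def _write(name, df, **kw):
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        files[name] = str(path)

    _write("counts.tsv", bundle["counts"], index_label="gene_id")
    _write("annotation.tsv", bundle["annotation"].reset_index(drop=True),
           index=False)
    tads = bundle["tads"]
    tads.to_csv(out / "tads.bed", sep="\t", header=False, index=False)
    files["tads.bed"] = str(out / "tads.bed")
    _write("covariates.tsv", bundle["covariates"], index_label="sample_id")
    mirna = pd.concat([truth.mirna_gene, truth.mirna_lnc], ignore_index=True)
    _write("mirna_interactions.tsv", mirna, index=False)
    edges = pd.DataFrame(
        [{"source": s, "target": t, "beta": b, "kind": "TF", "label": ""}
         for s, t, b in truth.tf_edges]
        + [{"source": l, "target": t, "beta": b, "kind": "lncRNA", "label": lab}
           for l, t, b, lab in truth.lnc_edges]
        + [{"source": f"{l}*{p}", "target": t, "beta": b,
            "kind": "interaction", "label": ""}
           for l, p, t, b in truth.interaction_triplets])
    _write("truth_edges.tsv", edges, index=False)
    import json
    cfg = asdict(bundle["config"])
    cfg["libsize_range"] = list(cfg["libsize_range"])
    (out / "config.json").write_text(json.dumps(cfg, indent=2))
    files["config.json"] = str(out / "config.json")
    return files
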