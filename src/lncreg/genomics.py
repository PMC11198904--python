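"""Genomic categorization of lncRNA-gene pairs and ceRNA detection.

Coordinates are 0-based half-open (BED convention) throughout.  A pair is
*overlapping* when the two gene bodies intersect on the same chromosome,
on either strand; *proximal* when the gap between nearest gene-body edges
is strictly below 1 Mbp (overlap included); *same-TAD* when both genes'
5' ends fall inside the same topologically associating domain.  Overlap
orientation follows transcription direction: tandem (same strand),
convergent (3' ends facing) or divergent (5' ends facing).  A lncRNA is a
candidate ceRNA for an mRNA when both are targets of the same miRNA in the
same cell line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairCategory",
    "validate_annotation",
    "validate_tads",
    "classify_pair",
    "classify_pairs",
    "find_cerna_pairs",
    "candidates_for",
    "genes_of_class",
    "CATEGORIES",
    "DIST_OVERLAP",
    "DIST_DIFF_CHROM",
]

CATEGORIES = ("overlapping", "same_tad", "proximal", "same_chrom", "cerna", "all")
DIST_OVERLAP = -1          # sentinel distance for intersecting gene bodies
DIST_DIFF_CHROM = "X"      # sentinel used in serialized tables

ANNOTATION_COLUMNS = ["gene_id", "gene_name", "gene_class", "chrom",
                      "start", "end", "strand"]
FLAG_COLUMNS = ["is_tf", "is_rbp", "is_enzyme"]


@dataclass
class PairCategory:
    """Location/mechanism flags for one lncRNA-gene pair."""

    lncrna_id: str
    gene_id: str
    overlapping: bool
    same_tad: bool
    proximal: bool
    same_chrom: bool
    cerna: bool
    distance: int | None  # bp gap; DIST_OVERLAP if overlapping; None if trans
    orientation: str      # tandem | convergent | divergent | NA

    def __post_init__(self):
        if self.overlapping and not (self.same_chrom and self.proximal
                                     and self.distance == DIST_OVERLAP):
            raise ValueError("overlap implies same_chrom, proximal, dist=-1")
        if self.proximal and not self.same_chrom:
            raise ValueError("proximal implies same chromosome")
        if (self.orientation != "NA") != self.overlapping:
            raise ValueError("orientation defined exactly for overlapping pairs")

    def distance_str(self) -> str:
        return DIST_DIFF_CHROM if self.distance is None else str(self.distance)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate gene annotation; returns a copy indexed by gene_id.

    ``gene_class`` is mRNA / lncRNA / miRNA; the boolean flags is_tf, is_rbp
    and is_enzyme mark mRNA subclasses and may combine.
    """
    df = annotation.copy()
    if "gene_id" in df.columns:
        df = df.set_index("gene_id", drop=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    for c in FLAG_COLUMNS:
        if c not in df.columns:
            df[c] = False
    if not df.index.is_unique:
        raise ValueError("duplicate gene ids")
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]].tolist()
        raise ValueError(f"degenerate intervals for: {bad}")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return df


def validate_tads(tads: pd.DataFrame) -> pd.DataFrame:
    """Validate TAD intervals; overlapping TADs on a chromosome are rejected."""
    df = tads.copy()
    for c in ("chrom", "start", "end"):
        if c not in df.columns:
            raise ValueError(f"TAD table missing column {c!r}")
    if (df["start"] >= df["end"]).any():
        raise ValueError("TAD with start >= end")
    for chrom, grp in df.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping TADs on {chrom}")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _five_prime(row) -> int:
    return int(row["start"]) if row["strand"] == "+" else int(row["end"]) - 1


def _tad_of(pos: int, chrom: str, tads: pd.DataFrame) -> int | None:
    sub = tads[tads["chrom"] == chrom]
    hit = sub[(sub["start"] <= pos) & (pos < sub["end"])]
    return None if hit.empty else int(hit.index[0])


def _orientation(a, b) -> str:
    """Orientation for an overlapping pair (tandem/convergent/divergent)."""
    if a["strand"] == b["strand"]:
        return "tandem"
    plus, minus = (a, b) if a["strand"] == "+" else (b, a)
    # + gene transcribes rightward from its start; - gene leftward from its
    # end.  5' ends on the outside (+ right of -) -> divergent; otherwise the
    # two 3' ends face each other -> convergent.
    return "convergent" if plus["start"] <= minus["start"] else "divergent"


def classify_pair(
    lncrna_id: str,
    gene_id: str,
    annotation: pd.DataFrame,
    tads: pd.DataFrame,
    proximal_dist: int = 1_000_000,
    cerna_pairs: set | None = None,
) -> PairCategory:
    """Categorize one lncRNA-gene pair by relative genomic location."""
    for gid in (lncrna_id, gene_id):
        if gid not in annotation.index:
            raise KeyError(f"unknown gene id {gid!r}")
    a = annotation.loc[lncrna_id]
    b = annotation.loc[gene_id]
    cerna = bool(cerna_pairs and (lncrna_id, gene_id) in cerna_pairs)
    if a["chrom"] != b["chrom"]:
        return PairCategory(lncrna_id, gene_id, False, False, False, False,
                            cerna, None, "NA")
    overlap = a["start"] < b["end"] and b["start"] < a["end"]
    if overlap:
        dist: int | None = DIST_OVERLAP
    else:
        dist = int(max(a["start"], b["start"]) - min(a["end"], b["end"]))
    proximal = overlap or dist < proximal_dist
    tad_a = _tad_of(_five_prime(a), a["chrom"], tads)
    tad_b = _tad_of(_five_prime(b), b["chrom"], tads)
    same_tad = tad_a is not None and tad_a == tad_b
    orient = _orientation(a, b) if overlap else "NA"
    return PairCategory(lncrna_id, gene_id, bool(overlap), bool(same_tad),
                        bool(proximal), True, cerna, dist, orient)


def classify_pairs(pairs, annotation, tads, proximal_dist: int = 1_000_000,
                   cerna_pairs: set | None = None) -> pd.DataFrame:
    """Vector version of :func:`classify_pair`; one row per pair, with the
    serialized distance sentinels ('-1' overlap, 'X' different chromosome)."""
    rows = []
    for lnc, gene in pairs:
        c = classify_pair(lnc, gene, annotation, tads, proximal_dist,
                          cerna_pairs)
        rows.append({
            "lncrna_id": c.lncrna_id, "gene_id": c.gene_id,
            "overlapping": c.overlapping, "same_tad": c.same_tad,
            "proximal": c.proximal, "same_chrom": c.same_chrom,
            "cerna": c.cerna, "dist": c.distance_str(),
            "tandem": c.orientation == "tandem",
            "convergent": c.orientation == "convergent",
            "divergent": c.orientation == "divergent",
        })
    return pd.DataFrame(rows)


def find_cerna_pairs(mirna_gene: pd.DataFrame, mirna_lnc: pd.DataFrame
                     ) -> dict[tuple[str, str], list[tuple[str, str]]]:
    """ceRNA pairs: a (lncRNA, gene) is emitted iff some miRNA targets both
    in the same cell line.  Returns pair -> list of (miRNA, cell_line)
    evidence."""
    for df, name in ((mirna_gene, "mirna_gene"), (mirna_lnc, "mirna_lnc")):
        for c in ("mirna_id", "partner_id", "cell_line"):
            if c not in df.columns:
                raise ValueError(f"{name} table missing column {c!r}")
    merged = mirna_lnc.merge(mirna_gene, on=["mirna_id", "cell_line"],
                             suffixes=("_lnc", "_gene"))
    out: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for row in merged.itertuples(index=False):
        key = (row.partner_id_lnc, row.partner_id_gene)
        out.setdefault(key, []).append((row.mirna_id, row.cell_line))
    return out


def category_table(
    lnc_ids: list[str],
    gene_ids: list[str],
    annotation: pd.DataFrame,
    tads: pd.DataFrame,
    proximal_dist: int = 1_000_000,
    cerna_pairs: dict | set | None = None,
) -> pd.DataFrame:
    """All-pairs location flags, vectorized over genes per lncRNA.

    Returns a long-format frame (lncrna_id, gene_id, overlapping, same_tad,
    proximal, same_chrom, cerna) equivalent to calling
    :func:`classify_pair` on every pair, minus distances/orientations.
    """
    ids = list(dict.fromkeys(list(lnc_ids) + list(gene_ids)))
    sub = annotation.loc[ids]
    chrom = sub["chrom"].to_numpy()
    start = sub["start"].to_numpy(dtype=np.int64)
    end = sub["end"].to_numpy(dtype=np.int64)
    five = np.where(sub["strand"].to_numpy() == "+", start, end - 1)
    tad_idx = np.full(len(ids), -1, dtype=np.int64)
    for c, grp in tads.groupby("chrom"):
        on_c = np.nonzero(chrom == c)[0]
        if on_c.size == 0:
            continue
        ts = grp["start"].to_numpy()
        te = grp["end"].to_numpy()
        j = np.searchsorted(ts, five[on_c], side="right") - 1
        ok = (j >= 0) & (five[on_c] < te[np.clip(j, 0, len(te) - 1)])
        tad_idx[on_c[ok]] = grp.index.to_numpy()[j[ok]]
    pos = {g: i for i, g in enumerate(ids)}
    gi = np.array([pos[g] for g in gene_ids])
    cerna_pairs = cerna_pairs or {}
    frames = []
    for lnc in lnc_ids:
        li = pos[lnc]
        same_chrom = chrom[gi] == chrom[li]
        overlap = same_chrom & (start[li] < end[gi]) & (start[gi] < end[li])
        gap = np.maximum(start[li], start[gi]) - np.minimum(end[li], end[gi])
        proximal = same_chrom & (overlap | (gap < proximal_dist))
        same_tad = same_chrom & (tad_idx[li] >= 0) & (tad_idx[gi] == tad_idx[li])
        frames.append(pd.DataFrame({
            "lncrna_id": lnc, "gene_id": gene_ids,
            "overlapping": overlap, "same_tad": same_tad,
            "proximal": proximal, "same_chrom": same_chrom,
            "cerna": [(lnc, g) in cerna_pairs for g in gene_ids],
        }))
    return pd.concat(frames, ignore_index=True)


def genes_of_class(annotation: pd.DataFrame, gene_class: str) -> list[str]:
    """Gene ids of a biotype class; TF/RBP/enzyme resolve via the mRNA flags."""
    flag = {"TF": "is_tf", "RBP": "is_rbp", "enzyme": "is_enzyme"}.get(gene_class)
    if flag is not None:
        return list(annotation.index[annotation[flag].astype(bool)])
    if gene_class in ("mRNA", "lncRNA", "miRNA"):
        return list(annotation.index[annotation["gene_class"] == gene_class])
    raise ValueError(f"unknown gene class {gene_class!r}")


def candidates_for(
    gene_id: str,
    category: str,
    annotation: pd.DataFrame,
    tads: pd.DataFrame,
    cerna_pairs: dict | set | None = None,
    proximal_dist: int = 1_000_000,
) -> list[str]:
    """Sorted lncRNA candidate list for a gene under a location/mechanism
    category.  An empty list means the gene is unmodeled for that category."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    lncs = [g for g in genes_of_class(annotation, "lncRNA") if g != gene_id]
    if category == "all":
        return sorted(lncs)
    if category == "cerna":
        pairs = cerna_pairs or {}
        return sorted(l for l in lncs if (l, gene_id) in pairs)
    out = []
    for l in lncs:
        c = classify_pair(l, gene_id, annotation, tads, proximal_dist)
        if getattr(c, category):
            out.append(l)
    return sorted(out)
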