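"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts and expression travel as TSV (genes in rows, samples in columns) or
MatrixMarket; annotation as a TSV with BED-style 0-based half-open
coordinates or as GTF (1-based closed, converted on read); TADs as BED3;
miRNA interactions, covariates and edge tables as TSV; gene sets as GMT;
configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genomics import validate_annotation, validate_tads
from .preprocess import validate_counts

__all__ = [
    "read_counts", "write_counts", "read_annotation", "write_annotation",
    "read_gtf_genes", "read_bed3", "write_bed3", "read_covariates",
    "read_mirna_interactions", "read_gmt", "read_yaml_config",
    "write_json_report",
]


def read_counts(path) -> pd.DataFrame:
    """Counts TSV (index = gene ids) or MatrixMarket ``.mtx`` with sibling
    ``.rows``/``.cols`` id files."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread
        mat = np.asarray(mmread(str(path)).todense())
        genes = path.with_suffix(".rows").read_text().split()
        samples = path.with_suffix(".cols").read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if not df.select_dtypes(exclude="number").empty:
        raise ValueError(f"{path}: non-numeric entries in count matrix")
    return validate_counts(df.astype(np.int64))


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"gene_id": str, "chrom": str})
    return validate_annotation(df)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def read_gtf_genes(path) -> pd.DataFrame:
    """Gene lines of a GTF as annotation; coordinates converted from
    1-based closed to 0-based half-open."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            raise ValueError(f"{path}:{ln}: malformed GTF line")
        if parts[2] != "gene":
            continue
        attrs = {}
        for item in parts[8].strip().strip(";").split(";"):
            if not item.strip():
                continue
            k, _, v = item.strip().partition(" ")
            attrs[k] = v.strip().strip('"')
        biotype = attrs.get("gene_biotype", attrs.get("gene_type", ""))
        cls = "lncRNA" if "lncRNA" in biotype or biotype == "lincRNA" else \
            ("miRNA" if biotype == "miRNA" else "mRNA")
        rows.append({
            "gene_id": attrs.get("gene_id", f"line{ln}"),
            "gene_name": attrs.get("gene_name", attrs.get("gene_id", "")),
            "gene_class": cls, "chrom": parts[0],
            "start": int(parts[3]) - 1, "end": int(parts[4]),
            "strand": parts[6], "is_tf": False, "is_rbp": False,
            "is_enzyme": False,
        })
    return validate_annotation(pd.DataFrame(rows))


def read_bed3(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end"], usecols=[0, 1, 2],
                     dtype={0: str})
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"{path}: interval with start >= end at line {bad + 1}")
    return validate_tads(df)


def write_bed3(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False,
                                                index=False)


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_mirna_interactions(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a combined miRNA interaction TSV into (miRNA-gene, miRNA-lnc)."""
    df = pd.read_csv(path, sep="\t")
    for c in ("mirna_id", "partner_id", "partner_class", "cell_line"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    return (df[df["partner_class"] == "mRNA"].reset_index(drop=True),
            df[df["partner_class"] == "lncRNA"].reset_index(drop=True))


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> members..."""
    sets = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs >= 3 fields")
        sets[parts[0]] = parts[2:]
    return sets


def read_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_json_report(report: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")
    Path(path).write_text(json.dumps(report, indent=2, default=_default))
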