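"""Readers for the plain-text exchange formats the pipeline consumes:
MatrixMarket counts, TSV label tables, BED intervals, JSON ground truth."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

from .types import CRE, MultiomeDataset, TrueGRN

_BED_COLS = ["chrom", "start", "end", "name"]


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    """BED (0-based half-open) with an optional 4th name column."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = names or _BED_COLS[: df.shape[1]]
    df.columns = cols + [f"col{i}" for i in range(len(cols), df.shape[1])]
    return df


def read_tf_binding(path: str | Path) -> dict[str, list[pd.DataFrame]]:
    """BED with TF name in column 4 -> {TF: [interval set]}."""
    df = read_bed(path)
    return {tf: [sub[["chrom", "start", "end"]].reset_index(drop=True)]
            for tf, sub in df.groupby("name")}


def read_seqlets(path: str | Path) -> pd.DataFrame:
    return read_bed(path, names=["chrom", "start", "end", "family", "strand", "seq"])


def load_multiome(fixture_dir: str | Path) -> MultiomeDataset:
    """Read a fixture directory written by ``synthetic.emit_fixtures``."""
    d = Path(fixture_dir)
    expr = sp.csr_matrix(mmread(str(d / "expr.mtx")))
    acc = sp.csr_matrix(mmread(str(d / "acc.mtx")))
    genes = pd.read_csv(d / "genes.tsv", sep="\t")
    cells = pd.read_csv(d / "cells.tsv", sep="\t", keep_default_na=False)
    peaks = read_bed(d / "peaks.bed")
    ds = MultiomeDataset(expr=expr, acc=acc, cells=cells, genes=genes, peaks=peaks)
    ds.validate()
    return ds


def load_truth(path: str | Path) -> TrueGRN:
    raw = json.loads(Path(path).read_text())
    cre_table = {
        g: [CRE(distance=c["distance"], bound_tfs=c["bound_tfs"], width=c["width"]) for c in cres]
        for g, cres in raw["cre_table"].items()
    }
    def _unkey(d):
        return {tuple(k.split("|")): v for k, v in d.items()}
    return TrueGRN(
        tf_names=raw["tf_names"],
        tf_role=raw["tf_role"],
        gene_names=raw["gene_names"],
        gene_role=raw["gene_role"],
        cre_table=cre_table,
        gene_decay={g: tuple(v) for g, v in raw["gene_decay"].items()},
        link_sign=_unkey(raw["link_sign"]),
        effect_size=_unkey(raw["effect_size"]),
        window=raw["window"],
        seed=raw.get("seed"),
    )


def read_clonotypes(path: str | Path) -> pd.DataFrame:
    """TSV with cell / clonotype / fate columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"cell", "clonotype", "fate"}
    if not required <= set(df.columns):
        raise ValueError(f"clonotype table needs columns {sorted(required)}")
    return df
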