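"""Convenience wiring of the pipeline stages on in-memory datasets.

These helpers adapt a :class:`~bifurcgrn.types.MultiomeDataset` to the
frame-based interfaces of the modeling stages and run common multi-stage
recipes (RP fits for many genes, per-state GRNs, knockout delta-PS).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import perturb, rp, state_grn
from .types import BaseGRN, MultiomeDataset, RPModel, TrueGRN


def frames(ds: MultiomeDataset) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """(expr genes x cells, acc peaks x cells, libsize) as labeled frames."""
    expr = pd.DataFrame(ds.expr_dense(), index=ds.genes["name"].to_numpy(),
                        columns=ds.cells["cell"].to_numpy())
    acc = pd.DataFrame(ds.acc_dense(), index=ds.peaks["name"].to_numpy(),
                       columns=ds.cells["cell"].to_numpy())
    return expr, acc, ds.cells["libsize"].to_numpy()


def truth_binding_sets(truth: TrueGRN, ds: MultiomeDataset) -> dict[str, list[pd.DataFrame]]:
    """Per-TF binding interval sets (the planted bound cCREs)."""
    peak_by = ds.peaks.set_index("name")
    out: dict[str, list[dict]] = {tf: [] for tf in truth.tf_names}
    for g in truth.gene_names:
        for j, cre in enumerate(truth.cre_table[g]):
            name = f"{g}:cre{j}"
            if name not in peak_by.index:
                continue
            prow = peak_by.loc[name]
            for tf in cre.bound_tfs:
                out[tf].append(
                    {"chrom": prow["chrom"], "start": int(prow["start"]), "end": int(prow["end"])}
                )
    return {
        tf: [pd.DataFrame(rows, columns=["chrom", "start", "end"])]
        for tf, rows in out.items() if rows
    }


def base_grn_from_truth(truth: TrueGRN) -> BaseGRN:
    """Base-GRN containing exactly the planted edges (oracle input)."""
    links = pd.DataFrame(
        [{"tf": tf, "gene": g} for (tf, g) in truth.planted_edges()],
        columns=["tf", "gene"],
    ).assign(score=1.0, source="isd")
    return BaseGRN(links=links, tfs=list(truth.tf_names), genes=list(truth.gene_names))


def fit_rp_models(
    ds: MultiomeDataset,
    genes: list[str] | None = None,
    window: int = 100_000,
    grid: np.ndarray | None = None,
) -> tuple[rp.PeakGeneIndex, dict[str, RPModel]]:
    """Link peaks to genes and fit RP models for ``genes`` (default: all
    genes with at least one linked peak)."""
    expr, acc, lib = frames(ds)
    # TF transcript rows live on a peak-less contig; only real loci link
    tss = ds.genes.loc[
        ds.genes["chrom"].isin(set(ds.peaks["chrom"])),
        ["chrom", "tss", "strand", "name"],
    ]
    index = rp.link_peaks_to_genes(ds.peaks, tss, window=window)
    targets = genes if genes is not None else [
        g for g in ds.genes["name"] if index.peaks_for(g)
    ]
    models = {
        g: rp.fit_rp_model(g, index, acc, expr.loc[g].to_numpy(), lib, grid=grid)
        for g in targets
    }
    return index, models


def fit_state_grns(
    base: BaseGRN,
    expr_norm: pd.DataFrame,
    states: pd.Series,
    which: list[str] | None = None,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    which = which if which is not None else sorted(states.unique())
    return {st: state_grn.fit_state_grn(base, expr_norm, states, st, **kwargs) for st in which}


def ko_delta_ps(
    edges_by_state: dict[str, pd.DataFrame],
    expr_norm: pd.DataFrame,
    ds: MultiomeDataset,
    tf: str,
    k_neighbors: int = 150,
    grid_n: int = 40,
) -> perturb.PerturbationResult:
    """Knockout -> perturbation flow -> delta-PS against the pseudotime flow."""
    states = pd.Series(ds.cells["state"].to_numpy(), index=ds.cells["cell"].to_numpy())
    emb = ds.cells[["x", "y"]].to_numpy()
    dfield = perturb.differentiation_flow(emb, ds.cells["pseudotime"].to_numpy(), grid_n=grid_n)
    dx = perturb.simulate_ko(edges_by_state, expr_norm, states, tf)
    pfield = perturb.perturbation_flow(dx, expr_norm, emb, k_neighbors=k_neighbors)
    gc = (ds.cells["state"] == "GC").to_numpy()
    pb = (ds.cells["state"] == "PB").to_numpy()
    return perturb.perturbation_scores(pfield, dfield, gc, pb, tf=tf)
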