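"""In-silico TF knockouts scored against the differentiation flow.

A knockout is propagated through the state-specific weighted GRN for a
few steps (primary, secondary, tertiary targets), giving each cell a
gene-space shift dX.  The shift is embedded as a 2-D perturbation vector
per cell by comparing dX with the expression offsets of the cell's
embedding neighbors (softmax transition kernel minus a uniform-neighbor
baseline).  Each cell's perturbation score is the dot product of its
perturbation vector with the pseudotime-gradient (differentiation) vector;
net scores sum over the GC and PB fate clusters and
delta_PS = net_GC - net_PB summarizes whether the knockout skews the
bifurcation toward the GC (positive) or PB (negative) fate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.neighbors import NearestNeighbors

from .types import PerturbationResult, VectorField

logger = logging.getLogger(__name__)


def _masked_gradient(values: np.ndarray, occupied: np.ndarray, h: float, axis: int):
    """Central differences over occupied bins; one-sided at mask edges."""
    v = np.where(occupied, values, 0.0)
    occ = occupied.astype(float)
    vf = np.roll(v, -1, axis=axis)
    of = np.roll(occ, -1, axis=axis)
    vb = np.roll(v, 1, axis=axis)
    ob = np.roll(occ, 1, axis=axis)
    # roll wraps around; kill the wrapped slices
    idx_last = [slice(None)] * v.ndim
    idx_last[axis] = -1
    idx_first = [slice(None)] * v.ndim
    idx_first[axis] = 0
    of[tuple(idx_last)] = 0.0
    ob[tuple(idx_first)] = 0.0
    both = (of > 0) & (ob > 0)
    fwd = (of > 0) & ~both
    bwd = (ob > 0) & ~both
    g = np.zeros_like(v)
    g[both] = (vf[both] - vb[both]) / (2 * h)
    g[fwd] = (vf[fwd] - v[fwd]) / h
    g[bwd] = (v[bwd] - vb[bwd]) / h
    g[~occupied] = 0.0
    return g


def _smooth_masked(field: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return field
    num = gaussian_filter(np.where(mask, field, 0.0), sigma=sigma)
    den = gaussian_filter(mask.astype(float), sigma=sigma)
    out = np.zeros_like(field)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    out[~mask] = 0.0
    return out


def differentiation_flow(
    embedding: np.ndarray,
    pseudotime: np.ndarray,
    grid_n: int = 40,
    smooth: float = 1.0,
) -> VectorField:
    """Pseudotime-gradient vector field over a binned 2-D embedding."""
    emb = np.asarray(embedding, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("pseudotime must be finite")
    x0, x1 = emb[:, 0].min(), emb[:, 0].max()
    y0, y1 = emb[:, 1].min(), emb[:, 1].max()
    hx = (x1 - x0) / grid_n or 1.0
    hy = (y1 - y0) / grid_n or 1.0
    ix = np.clip(((emb[:, 0] - x0) / hx).astype(int), 0, grid_n - 1)
    iy = np.clip(((emb[:, 1] - y0) / hy).astype(int), 0, grid_n - 1)

    count = np.zeros((grid_n, grid_n))
    total = np.zeros((grid_n, grid_n))
    np.add.at(count, (ix, iy), 1.0)
    np.add.at(total, (ix, iy), t)
    occupied = count > 0
    if occupied.sum() <= 1:
        logger.warning("all cells fall in a single grid bin; zero flow field")
        zeros = np.zeros((len(emb), 2))
        grid = np.where(occupied, total / np.maximum(count, 1), np.nan)
        return VectorField(zeros, grid, np.zeros_like(count), np.zeros_like(count),
                           (x0, x1, y0, y1), kind="differentiation")
    mean_t = np.where(occupied, total / np.maximum(count, 1), np.nan)

    gx = _masked_gradient(np.nan_to_num(mean_t), occupied, hx, axis=0)
    gy = _masked_gradient(np.nan_to_num(mean_t), occupied, hy, axis=1)
    gx = _smooth_masked(gx, occupied, smooth)
    gy = _smooth_masked(gy, occupied, smooth)

    vectors = np.stack([gx[ix, iy], gy[ix, iy]], axis=1)
    return VectorField(vectors, mean_t, gx, gy, (x0, x1, y0, y1), kind="differentiation")


def simulate_ko(
    edges_by_state: dict[str, pd.DataFrame],
    expr: pd.DataFrame,
    states: pd.Series,
    tf: str,
    n_steps: int = 3,
) -> pd.DataFrame:
    """Propagate the loss of one TF through each state's weighted GRN.

    Per cell, the initial shift sets the TF coordinate to zero; each step
    multiplies the current increment's TF coordinates by the state's
    TF -> gene weight matrix, clamping simulated expression at zero and
    re-clamping the knocked-out TF to zero.  Returns the cumulative
    gene-space shift dX (genes x cells); cells in states without a fitted
    GRN keep dX = 0.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if tf not in expr.index:
        raise ValueError(f"TF {tf!r} absent from the expression matrix")
    genes = expr.index
    gidx = {g: i for i, g in enumerate(genes)}
    t_row = gidx[tf]
    X = expr.to_numpy(dtype=float)
    delta = np.zeros_like(X)

    for st, et in edges_by_state.items():
        cells_mask = (states == st).to_numpy()
        if not cells_mask.any():
            continue
        et = et.loc[et["round"] == 2] if "round" in et.columns and (et["round"] == 2).any() else et
        W = np.zeros((len(genes), len(genes)))
        for tf_name, gene, w in et[["tf", "gene", "weight"]].itertuples(index=False):
            if tf_name in gidx and gene in gidx:
                W[gidx[gene], gidx[tf_name]] += w
        Xs = X[:, cells_mask]
        inc = np.zeros_like(Xs)
        inc[t_row] = -Xs[t_row]
        cum = inc.copy()
        for _ in range(n_steps):
            raw = W @ inc
            cum_next = np.maximum(cum + raw, -Xs)  # expression clamped at 0
            cum_next[t_row] = -Xs[t_row]  # TF held at 0 throughout
            inc = cum_next - cum
            cum = cum_next
        delta[:, cells_mask] = cum
    return pd.DataFrame(delta, index=genes, columns=expr.columns)


def perturbation_flow(
    delta_x: pd.DataFrame,
    expr: pd.DataFrame,
    embedding: np.ndarray,
    k_neighbors: int = 200,
    temperature: float = 0.05,
) -> VectorField:
    """Embed the gene-space KO shift as per-cell 2-D vectors.

    Transition weights over each cell's k nearest embedding neighbors are
    the softmax (at ``temperature``) of the Pearson correlation between
    the cell's dX and each neighbor's expression offset; the vector is
    the probability-weighted mean neighbor displacement minus the
    uniform-neighbor baseline.  Cells with dX = 0 get zero vectors.
    """
    emb = np.asarray(embedding, dtype=float)
    n_cells = emb.shape[0]
    if k_neighbors >= n_cells:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    D = delta_x.to_numpy(dtype=float)
    E = expr.to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb)
    _, nbr = nn.kneighbors(emb)
    nbr = nbr[:, 1:]  # drop self

    vectors = np.zeros((n_cells, 2))
    for c in range(n_cells):
        d = D[:, c]
        if not d.any():
            continue
        diffs = E[:, nbr[c]] - E[:, c][:, None]  # genes x k
        dc = d - d.mean()
        dd = diffs - diffs.mean(axis=0, keepdims=True)
        denom = np.linalg.norm(dc) * np.linalg.norm(dd, axis=0)
        r = np.zeros(k_neighbors)
        ok = denom > 1e-12
        r[ok] = (dc @ dd[:, ok]) / denom[ok]
        w = np.exp((r - r.max()) / temperature)
        w /= w.sum()
        disp = emb[nbr[c]] - emb[c]
        vectors[c] = w @ disp - disp.mean(axis=0)
    return VectorField(vectors, np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)),
                       (emb[:, 0].min(), emb[:, 0].max(), emb[:, 1].min(), emb[:, 1].max()),
                       kind="perturbation")


def perturbation_scores(
    pfield: VectorField,
    dfield: VectorField,
    gc_cells: np.ndarray,
    pb_cells: np.ndarray,
    tf: str = "",
) -> PerturbationResult:
    """Per-cell PS = perturbation . differentiation; net sums per fate.

    ``gc_cells`` / ``pb_cells`` are boolean masks or integer indices over
    the shared cell axis; they must be disjoint.
    """
    if pfield.vectors.shape != dfield.vectors.shape:
        raise ValueError("fields do not share a cell index")
    n = pfield.vectors.shape[0]
    gc = np.zeros(n, dtype=bool)
    gc[np.asarray(gc_cells)] = True
    pb = np.zeros(n, dtype=bool)
    pb[np.asarray(pb_cells)] = True
    if (gc & pb).any():
        raise ValueError("GC and PB cell sets overlap")
    ps = np.einsum("ij,ij->i", pfield.vectors, dfield.vectors)
    return PerturbationResult(
        tf=tf, ps=ps, net_gc=float(ps[gc].sum()), net_pb=float(ps[pb].sum())
    )
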