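"""State-specific weighted GRN inference by Bayesian ridge regression.

For each cell state, every gene with incoming base-GRN candidate links is
regressed on its candidate TFs' expression within that state's cells.
Coefficients get a posterior spread (se) and a two-sided normal tail
probability p = 2 * (1 - Phi(|weight| / se)).  Selection is two-round:
round 1 fits all candidates and retains up to ``edge_cap`` edges with
p < ``p_cut`` (ranked by p, then |weight|); round 2 refits each gene on
its retained TFs only and is marked final.

The ridge hyperparameters (noise precision ``alpha``, weight precision
``lam``) are set by MacKay's evidence approximation unless fixed by the
caller; the ``lam -> 0`` limit recovers ordinary least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.cluster import KMeans

from .types import BaseGRN

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


@dataclass
class RidgeFit:
    coef: np.ndarray
    se: np.ndarray
    intercept: float
    alpha: float  # noise precision
    lam: float  # weight precision


@dataclass
class CentralityMatrix:
    """TF eigenvector centralities per state, with a per-TF scaled form."""

    raw: pd.DataFrame  # TF x state
    scaled: pd.DataFrame  # per-TF standardized across states
    node_centrality: dict[str, pd.Series] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)


def bayesian_ridge(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float | None = None,
    lam: float | None = None,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> RidgeFit:
    """Bayesian ridge with evidence-maximized hyperparameters.

    ``alpha``/``lam`` fix the noise/weight precision instead of updating
    them.  X and y are centered internally; the intercept is recovered
    from the means.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    XtX = Xc.T @ Xc
    Xty = Xc.T @ yc
    eigvals = np.linalg.eigvalsh(XtX)
    eigvals = np.clip(eigvals, 0.0, None)

    a = alpha if alpha is not None else 1.0 / max(yc.var(), 1e-12)
    l = lam if lam is not None else 1.0
    update = alpha is None or lam is None
    for _ in range(max_iter if update else 1):
        A = a * XtX + l * np.eye(p)
        m = a * np.linalg.solve(A, Xty)
        resid = yc - Xc @ m
        gamma = float(np.sum(a * eigvals / (l + a * eigvals)))
        a_new = a if alpha is not None else (n - gamma) / max(resid @ resid, 1e-12)
        l_new = l if lam is not None else gamma / max(m @ m, 1e-12)
        a_new = float(np.clip(a_new, 1e-12, 1e12))
        l_new = float(np.clip(l_new, 1e-12, 1e12))
        if abs(a_new - a) <= tol * a and abs(l_new - l) <= tol * l:
            a, l = a_new, l_new
            break
        a, l = a_new, l_new
    A = a * XtX + l * np.eye(p)
    Sigma = np.linalg.inv(A)
    m = a * Sigma @ Xty
    se = np.sqrt(np.clip(np.diag(Sigma), 1e-300, None))
    return RidgeFit(coef=m, se=se, intercept=float(ym - xm @ m), alpha=a, lam=l)


def normalize_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """log1p counts scaled to a common (median) library size per cell."""
    lib = counts.sum(axis=0).astype(float)
    target = float(np.median(lib[lib > 0])) if (lib > 0).any() else 1.0
    scaled = counts.div(lib.replace(0, np.nan), axis=1).fillna(0.0) * target
    return np.log1p(scaled)


def _edge_pvalues(coef: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = np.abs(coef) / se
    return np.clip(2.0 * norm.sf(z), _P_FLOOR, 1.0)


def _rank_edges(df: pd.DataFrame) -> pd.DataFrame:
    # ascending p, ties by descending |weight|, then lexical (tf, gene)
    return df.assign(_absw=df["weight"].abs()).sort_values(
        ["p", "_absw", "tf", "gene"], ascending=[True, False, True, True], kind="mergesort"
    ).drop(columns="_absw")


def _fit_genes(
    gene_tfs: dict[str, list[str]],
    expr: pd.DataFrame,
    cells: pd.Index,
    state: str,
    rnd: int,
    alpha: float | None,
    lam: float | None,
) -> pd.DataFrame:
    rows = []
    sub = expr.loc[:, cells]
    for gene, tfs in sorted(gene_tfs.items()):
        if gene not in sub.index:
            continue
        y = sub.loc[gene].to_numpy(dtype=float)
        if y.std() < 1e-12:
            logger.info("gene %s has zero-variance expression in state %s; edges dropped", gene, state)
            continue
        tfs = [t for t in tfs if t in sub.index and t != gene]
        tfs = [t for t in tfs if sub.loc[t].std() > 1e-12]
        if not tfs:
            continue
        X = sub.loc[tfs].to_numpy(dtype=float).T
        fit = bayesian_ridge(X, y, alpha=alpha, lam=lam)
        p = _edge_pvalues(fit.coef, fit.se)
        for t, w, s, pv in zip(tfs, fit.coef, fit.se, p):
            rows.append(
                {"state": state, "tf": t, "gene": gene, "weight": float(w),
                 "se": float(s), "p": float(pv), "round": rnd}
            )
    cols = ["state", "tf", "gene", "weight", "se", "p", "round"]
    return pd.DataFrame(rows, columns=cols)


def fit_state_grn(
    base: BaseGRN,
    expr: pd.DataFrame,
    states: pd.Series,
    state: str,
    edge_cap: int = 10_000,
    p_cut: float = 1e-3,
    min_cells: int = 20,
    alpha: float | None = None,
    lam: float | None = None,
) -> pd.DataFrame:
    """Two-round per-state edge fit over base-GRN candidates.

    Returns the concatenated round-1 (all candidates) and round-2
    (refit on retained TFs, final) edge tables.
    """
    if state not in set(states):
        raise ValueError(f"state {state!r} absent from the label vector")
    cells = states.index[states == state]
    if len(cells) < min_cells:
        raise ValueError(f"state {state!r} has {len(cells)} cells; need >= {min_cells}")

    gene_tfs: dict[str, list[str]] = {}
    for tf, gene in base.links[["tf", "gene"]].itertuples(index=False):
        gene_tfs.setdefault(gene, []).append(tf)

    round1 = _fit_genes(gene_tfs, expr, cells, state, 1, alpha, lam)
    passed = _rank_edges(round1.loc[round1["p"] < p_cut])
    retained = passed.head(edge_cap)

    gene_tfs2: dict[str, list[str]] = {}
    for tf, gene in retained[["tf", "gene"]].itertuples(index=False):
        gene_tfs2.setdefault(gene, []).append(tf)
    round2 = _fit_genes(gene_tfs2, expr, cells, state, 2, alpha, lam)
    # round 2 is a refit of the retained candidate set only
    keep = set(map(tuple, retained[["tf", "gene"]].to_numpy()))
    round2 = round2[[tuple(x) in keep for x in round2[["tf", "gene"]].to_numpy()]]
    return pd.concat([round1, round2], ignore_index=True)


def final_edges(edge_table: pd.DataFrame) -> pd.DataFrame:
    """Round-2 (final) rows of a fitted edge table."""
    return edge_table.loc[edge_table["round"] == 2].reset_index(drop=True)


def _power_iteration(A: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000) -> np.ndarray:
    n = A.shape[0]
    if not A.any():
        return np.zeros(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        # iterate on A + I: same eigenvectors, avoids the sign oscillation
        # of bipartite (TF/gene-layered) graphs
        w = A @ v + v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return np.zeros(n)
        w /= nrm
        if np.linalg.norm(w - v) < tol:
            return w
        v = w
    return v


def tf_centrality(edges_by_state: dict[str, pd.DataFrame]) -> CentralityMatrix:
    """Eigenvector centrality of each TF in each state's weighted graph.

    The graph joins TFs and genes with undirected edges of magnitude
    |weight| (final-round edges).  Centrality is the principal
    eigenvector (power iteration, tolerance 1e-10), normalized to unit
    Euclidean norm over all nodes; TF rows are reported.  The scaled
    form standardizes each TF's centralities across states.
    """
    states = sorted(edges_by_state)
    all_tfs: set[str] = set()
    node_cent: dict[str, pd.Series] = {}
    flags: dict[str, str] = {}
    for st in states:
        et = edges_by_state[st]
        et = et.loc[et["round"] == 2] if "round" in et.columns and (et["round"] == 2).any() else et
        if et.empty:
            raise ValueError(f"state {st!r} has an empty edge table")
        nodes = sorted(set(et["tf"]) | set(et["gene"]))
        idx = {n: i for i, n in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)))
        for tf, gene, w in et[["tf", "gene", "weight"]].itertuples(index=False):
            i, j = idx[tf], idx[gene]
            A[i, j] += abs(w)
            A[j, i] += abs(w)
        v = _power_iteration(A)
        if not v.any():
            flags[st] = "all-zero graph"
        v = np.abs(v)  # Perron vector of a nonnegative matrix
        node_cent[st] = pd.Series(v, index=nodes)
        all_tfs |= set(et["tf"])
    tfs = sorted(all_tfs)
    raw = pd.DataFrame(
        {st: [node_cent[st].get(tf, 0.0) for tf in tfs] for st in states}, index=tfs
    )
    mu = raw.mean(axis=1)
    sd = raw.std(axis=1, ddof=0)
    scaled = raw.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return CentralityMatrix(raw=raw, scaled=scaled, node_centrality=node_cent, flags=flags)


def centrality_clusters(
    scaled: pd.DataFrame | CentralityMatrix,
    k: int = 6,
    seed: int = 0,
    n_restarts: int = 50,
) -> pd.Series:
    """k-means cluster labels (1..k) of per-TF scaled centrality profiles."""
    mat = scaled.scaled if isinstance(scaled, CentralityMatrix) else scaled
    if k > len(mat):
        raise ValueError(f"k={k} exceeds the number of TFs ({len(mat)})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(mat.to_numpy())
    return pd.Series(labels + 1, index=mat.index, name="cluster")
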