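"""Regulatory-potential models and probabilistic in-silico deletion.

A gene's regulatory potential (RP) aggregates the accessibility of its
flanking cCREs, each weighted by an exponential decay in TSS distance:
``w_j = exp(-|d_j| / l_side)`` with separate upstream/downstream decay
lengths.  Expression counts are modeled as Poisson with a log link and a
library-size offset, ``E[y_c] = libsize_c * exp(alpha + beta * RP_c)``;
decay lengths are chosen by exhaustive grid search on the profile
log-likelihood, with (alpha, beta) refit by Newton/IRLS at every grid
point.

A TF's influence on a gene (ISD score) is the log-likelihood drop after
deleting the model peaks that overlap the TF's binding regions and
refitting (alpha, beta) with the decay lengths frozen.
"""

from __future__ import annotations

import logging
from itertools import product

import numpy as np
import pandas as pd

from .types import ISDMatrix, PeakGeneIndex, RPModel

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100_000


def default_decay_grid(n: int = 12, lo: float = 500.0, hi: float = 100_000.0) -> np.ndarray:
    """Logarithmic decay-length grid (bp), shared by both sides."""
    return np.geomspace(lo, hi, n)


# ---------------------------------------------------------------------
# peak-gene linking
# ---------------------------------------------------------------------

def link_peaks_to_genes(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> PeakGeneIndex:
    """Assign every peak within ``window`` of a TSS to that gene.

    Distance is TSS-to-nearest-peak-edge (0 if the peak spans the TSS),
    signed negative upstream of the TSS with respect to the gene's
    strand.  ``peaks`` needs chrom/start/end/name columns; ``tss`` needs
    chrom/tss (or pos)/strand/name.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    tss = tss.rename(columns={"pos": "tss", "gene": "name"})
    missing = set(tss["chrom"]) - set(peaks["chrom"])
    if missing:
        logger.warning(
            "TSS chromosomes absent from the peak table are excluded: %s",
            ", ".join(sorted(map(str, missing))),
        )
    links: dict[str, list[tuple[str, int, str]]] = {}
    by_chrom = {c: sub for c, sub in peaks.groupby("chrom")}
    for _, g in tss.iterrows():
        sub = by_chrom.get(g["chrom"])
        entries: list[tuple[str, int, str]] = []
        if sub is not None:
            pos = int(g["tss"])
            start = sub["start"].to_numpy()
            end = sub["end"].to_numpy()
            # signed genomic distance to the nearest edge; 0 if spanning
            d = np.where(pos < start, start - pos, np.where(pos >= end, end - 1 - pos, 0))
            keep = np.abs(d) <= window
            strand = g.get("strand", "+")
            for name, dj in zip(sub["name"].to_numpy()[keep], d[keep]):
                d_signed = int(dj) if strand == "+" else -int(dj)
                side = "upstream" if d_signed < 0 else "downstream"
                entries.append((str(name), d_signed, side))
        links[str(g["name"])] = entries
    return PeakGeneIndex(links=links, window=window)


# ---------------------------------------------------------------------
# Poisson fit with log link and offset (Newton / IRLS, 2 parameters)
# ---------------------------------------------------------------------

def _poisson_loglik(y: np.ndarray, log_mu: np.ndarray) -> float:
    # gammaln(y+1) term omitted: constant in the parameters, so it cancels
    # in every likelihood difference the pipeline reports
    return float(np.sum(y * log_mu - np.exp(log_mu)))


def poisson_fit(
    y: np.ndarray,
    x: np.ndarray | None,
    log_offset: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[float, float, float]:
    """Fit E[y] = exp(offset + alpha + beta*x) by Newton's method.

    Returns (alpha, beta, loglik).  With ``x=None`` fits the
    intercept-only model (closed form).  Log-likelihoods drop the
    ``log(y!)`` constant, so only differences are meaningful.
    """
    y = np.asarray(y, dtype=float)
    if x is None:
        mu0 = np.exp(log_offset)
        alpha = np.log(max(y.sum(), 1e-12) / mu0.sum())
        ll = _poisson_loglik(y, log_offset + alpha)
        return alpha, 0.0, ll
    x = np.asarray(x, dtype=float)
    xs = x.std()
    if xs < 1e-12:  # constant predictor degenerates to intercept-only
        alpha, _, ll = poisson_fit(y, None, log_offset)
        return alpha, 0.0, ll
    xc = (x - x.mean()) / xs  # standardized for conditioning
    alpha = np.log(max(y.mean(), 1e-12))
    beta = 0.0
    ll_prev = -np.inf
    for _ in range(max_iter):
        eta = log_offset + alpha + beta * xc
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        g = np.array([np.sum(y - mu), np.sum((y - mu) * xc)])
        h00 = np.sum(mu)
        h01 = np.sum(mu * xc)
        h11 = np.sum(mu * xc * xc)
        det = h00 * h11 - h01 * h01
        if det <= 1e-300:
            break
        step = np.array([h11 * g[0] - h01 * g[1], -h01 * g[0] + h00 * g[1]]) / det
        # dampen overly large Newton steps
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        alpha += step[0]
        beta += step[1]
        ll = _poisson_loglik(y, np.clip(log_offset + alpha + beta * xc, -30, 30))
        if abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
            break
        ll_prev = ll
    eta = np.clip(log_offset + alpha + beta * xc, -30, 30)
    ll = _poisson_loglik(y, eta)
    # back-transform to the raw-x scale
    beta_raw = beta / xs
    alpha_raw = alpha - beta_raw * x.mean()
    return float(alpha_raw), float(beta_raw), ll


def _weights(distances: np.ndarray, sides: list[str], l_up: float, l_down: float) -> np.ndarray:
    l = np.where(np.asarray(sides) == "upstream", l_up, l_down)
    return np.exp(-np.abs(distances) / l)


def fit_rp_model(
    gene: str,
    index: PeakGeneIndex,
    acc: pd.DataFrame,
    expr: np.ndarray,
    libsize: np.ndarray,
    grid: np.ndarray | None = None,
) -> RPModel:
    """Grid-search decay lengths maximizing the Poisson log-likelihood.

    ``acc`` is a peak x cell count frame indexed by peak name; ``expr``
    the gene's counts per cell; ``libsize`` the per-cell offset scale.
    Grid arg-max ties break toward larger decay lengths (the smoother
    model).
    """
    entries = index.peaks_for(gene)
    if not entries:
        raise ValueError(f"gene {gene!r} has no linked peaks")
    grid = default_decay_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or (grid <= 0).any():
        raise ValueError("decay grid must be non-empty and positive")
    names = [e[0] for e in entries]
    distances = np.array([e[1] for e in entries], dtype=float)
    sides = [e[2] for e in entries]
    missing = [n for n in names if n not in acc.index]
    if missing:
        raise ValueError(f"accessibility matrix lacks peak rows: {missing[:5]}")
    A = acc.loc[names].to_numpy(dtype=float)
    y = np.asarray(expr, dtype=float)
    log_off = np.log(np.asarray(libsize, dtype=float))

    alpha0, _, ll0 = poisson_fit(y, None, log_off)
    if not A.any():
        return RPModel(
            gene=gene, l_up=float(grid[0]), l_down=float(grid[0]), peak_names=names,
            distances=distances, sides=sides,
            weights=_weights(distances, sides, grid[0], grid[0]),
            alpha=alpha0, beta=0.0, loglik=ll0, null_loglik=ll0, degenerate=True,
        )

    best = None
    for l_up, l_down in product(grid, grid):
        w = _weights(distances, sides, l_up, l_down)
        rp = w @ A
        alpha, beta, ll = poisson_fit(y, rp, log_off)
        key = (ll, l_up, l_down)  # ties break toward larger decay lengths
        if best is None or key > best[0]:
            best = (key, l_up, l_down, w, alpha, beta, ll)
    _, l_up, l_down, w, alpha, beta, ll = best
    return RPModel(
        gene=gene, l_up=float(l_up), l_down=float(l_down), peak_names=names,
        distances=distances, sides=sides, weights=w,
        alpha=alpha, beta=beta, loglik=max(ll, ll0), null_loglik=ll0,
    )


def rp_scores(model: RPModel, acc: pd.DataFrame) -> np.ndarray:
    """Per-cell regulatory potential RP_c = sum_j w_j * acc_jc."""
    missing = [n for n in model.peak_names if n not in acc.index]
    if missing:
        raise ValueError(f"accessibility matrix lacks peak rows: {missing[:5]}")
    A = acc.loc[model.peak_names].to_numpy(dtype=float)
    return model.weights @ A


# ---------------------------------------------------------------------
# in-silico deletion
# ---------------------------------------------------------------------

def _overlaps(peaks: pd.DataFrame, names: list[str], tf_peaks: pd.DataFrame) -> np.ndarray:
    """Boolean mask over ``names``: >=1 bp overlap with any TF interval."""
    sub = peaks.set_index("name").loc[names]
    hit = np.zeros(len(names), dtype=bool)
    for chrom, tf_sub in tf_peaks.groupby("chrom"):
        sel = sub["chrom"] == chrom
        if not sel.any():
            continue
        s = sub.loc[sel, "start"].to_numpy()[:, None]
        e = sub.loc[sel, "end"].to_numpy()[:, None]
        ts = tf_sub["start"].to_numpy()[None, :]
        te = tf_sub["end"].to_numpy()[None, :]
        hit[np.where(sel)[0]] |= ((s < te) & (ts < e)).any(axis=1)
    return hit


def isd_score(
    model: RPModel,
    acc: pd.DataFrame,
    expr: np.ndarray,
    libsize: np.ndarray,
    tf_peaks: pd.DataFrame,
    peaks: pd.DataFrame,
) -> float:
    """Log-likelihood drop after deleting TF-overlapped model peaks.

    Decay lengths stay frozen; (alpha, beta) are refit on the reduced RP.
    Exactly 0 when no model peak overlaps the TF's binding set; reduces
    to the intercept-only refit when every peak is deleted.
    """
    if model.degenerate:
        return 0.0
    hit = _overlaps(peaks, model.peak_names, tf_peaks)
    if not hit.any():
        return 0.0
    y = np.asarray(expr, dtype=float)
    log_off = np.log(np.asarray(libsize, dtype=float))
    keep = ~hit
    if keep.any():
        A = acc.loc[[n for n, k in zip(model.peak_names, keep) if k]].to_numpy(dtype=float)
        rp = model.weights[keep] @ A
        _, _, ll_del = poisson_fit(y, rp, log_off)
    else:
        _, _, ll_del = poisson_fit(y, None, log_off)
    return float(model.loglik - ll_del)


def isd_matrix(
    models: dict[str, RPModel],
    tf_binding: dict[str, list[pd.DataFrame]],
    acc: pd.DataFrame,
    expr: pd.DataFrame,
    libsize: np.ndarray,
    peaks: pd.DataFrame,
) -> ISDMatrix:
    """TF x gene matrix of retained ISD scores.

    When a TF has several binding sets (e.g. multiple ChIP-seq datasets)
    the maximum score per TF-gene pair is retained, with the arg-max
    set's label recorded as provenance.
    """
    if not tf_binding:
        raise ValueError("empty TF binding map")
    for tf, sets in tf_binding.items():
        if not sets:
            raise ValueError(f"TF {tf!r} has no binding sets")
    tfs = sorted(tf_binding)
    genes = sorted(models)
    scores = pd.DataFrame(0.0, index=tfs, columns=genes)
    prov = pd.DataFrame("", index=tfs, columns=genes)
    for tf in tfs:
        for g in genes:
            y = expr.loc[g].to_numpy()
            per_set = [
                isd_score(models[g], acc, y, libsize, tf_peaks, peaks)
                for tf_peaks in tf_binding[tf]
            ]
            best = int(np.argmax(per_set))
            scores.at[tf, g] = per_set[best]
            prov.at[tf, g] = f"set{best}"
    return ISDMatrix(scores=scores, provenance=prov)
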