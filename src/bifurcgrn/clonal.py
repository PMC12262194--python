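"""Clonal fate composition and the Monte-Carlo fate-independence test.

Clonotypes (cells sharing a B cell receptor rearrangement) of size >=
``min_size`` are classified as PB-only, GC-only or bifurcated.  The null
hypothesis -- cell fates arise independently of clonal membership -- is
simulated either by permuting fate labels across cells (conditioning
exactly on the observed clone-size multiset and marginal fate
frequencies) or by redrawing clone sizes from Poisson fits to the
observed PB/GC clone-size distributions, assigning fates i.i.d. and
subsampling to the observed cell count.  Category deviations are scored
as z = (observed - sim mean) / sim sd with p = 2 * (1 - Phi(|z|)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import ClonalTestResult

CATEGORIES = ("PB_only", "GC_only", "bifurcated")
FATES = ("PB", "GC")


def _validate_fates(fates: pd.Series) -> None:
    bad = set(fates.unique()) - set(FATES)
    if bad:
        raise ValueError(f"unknown fate labels: {sorted(bad)}; expected PB/GC")


def _counts_from_arrays(clone_ids: np.ndarray, is_pb: np.ndarray, min_size: int) -> np.ndarray:
    """(PB_only, GC_only, bifurcated) counts for clones of size >= min_size."""
    sizes = np.bincount(clone_ids)
    pb = np.bincount(clone_ids, weights=is_pb).astype(np.int64)
    keep = sizes >= min_size
    pb_k, sz_k = pb[keep], sizes[keep]
    return np.array([
        int((pb_k == sz_k).sum()),
        int((pb_k == 0).sum()),
        int(((pb_k > 0) & (pb_k < sz_k)).sum()),
    ])


def _encode(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    codes, _ = pd.factorize(table["clonotype"])
    is_pb = (table["fate"] == "PB").to_numpy(dtype=float)
    return codes, is_pb


def classify_clonotypes(table: pd.DataFrame, min_size: int = 2) -> dict[str, int]:
    """Category counts for clonotypes with at least ``min_size`` cells."""
    _validate_fates(table["fate"])
    if table.empty:
        return dict.fromkeys(CATEGORIES, 0)
    codes, is_pb = _encode(table)
    c = _counts_from_arrays(codes, is_pb, min_size)
    return dict(zip(CATEGORIES, map(int, c)))


def clonal_null_test(
    table: pd.DataFrame,
    n_sim: int = 1_000,
    mode: str = "permutation",
    seed: int = 0,
    min_size: int = 2,
) -> ClonalTestResult:
    """Monte-Carlo test of fate independence within clones.

    ``permutation`` shuffles fate labels over cells each replicate;
    ``poisson`` redraws clone sizes from Poisson fits to the observed
    PB/GC clone-size distributions, assigns fates i.i.d. at the observed
    marginal frequency and subsamples to the observed cell count.
    Replicate RNG streams are spawned from the seed, so results are
    reproducible and independent of evaluation order.
    """
    if mode not in ("permutation", "poisson"):
        raise ValueError(f"unknown mode {mode!r}")
    _validate_fates(table["fate"])
    codes, is_pb = _encode(table)
    observed = _counts_from_arrays(codes, is_pb, min_size)
    sizes = np.bincount(codes)
    if (sizes >= min_size).sum() < 2:
        raise ValueError(f"need >= 2 clones of size >= {min_size}")
    if is_pb.all() or not is_pb.any():
        raise ValueError("both fates must be present")

    n_cells = len(codes)
    pi_pb = is_pb.mean()
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_sim)]
    sims = np.empty((n_sim, 3), dtype=np.int64)

    if mode == "permutation":
        for i, rng in enumerate(streams):
            perm = rng.permutation(is_pb)
            sims[i] = _counts_from_arrays(codes, perm, min_size)
    else:
        pb_clones = np.unique(codes[is_pb.astype(bool)])
        # clone-size Poisson fits per observed majority-fate class
        sizes_all = sizes
        clone_pb_frac = np.bincount(codes, weights=is_pb) / sizes_all
        pb_like = clone_pb_frac >= 0.5
        lam_pb = float(sizes_all[pb_like].mean()) if pb_like.any() else float(sizes_all.mean())
        lam_gc = float(sizes_all[~pb_like].mean()) if (~pb_like).any() else float(sizes_all.mean())
        frac_pb_clones = float(pb_like.mean())
        n_clones = len(sizes_all)
        for i, rng in enumerate(streams):
            cls = rng.random(n_clones) < frac_pb_clones
            lam = np.where(cls, lam_pb, lam_gc)
            new_sizes = rng.poisson(lam)
            new_sizes = np.maximum(new_sizes, 1)
            ids = np.repeat(np.arange(n_clones), new_sizes)
            if len(ids) > n_cells:
                ids = rng.choice(ids, size=n_cells, replace=False)
            fate = rng.random(len(ids)) < pi_pb
            sims[i] = _counts_from_arrays(ids, fate.astype(float), min_size)

    mean = sims.mean(axis=0)
    sd = sims.std(axis=0, ddof=1)
    z = np.zeros(3)
    p = np.ones(3)
    degenerate = {}
    for j, cat in enumerate(CATEGORIES):
        if sd[j] == 0:
            degenerate[cat] = True
            z[j] = 0.0 if observed[j] == mean[j] else np.inf * np.sign(observed[j] - mean[j])
            p[j] = 1.0 if observed[j] == mean[j] else 0.0
        else:
            degenerate[cat] = False
            z[j] = (observed[j] - mean[j]) / sd[j]
            p[j] = 2.0 * (1.0 - norm.cdf(abs(z[j])))
    return ClonalTestResult(
        observed=dict(zip(CATEGORIES, map(int, observed))),
        sim_mean=dict(zip(CATEGORIES, map(float, mean))),
        sim_sd=dict(zip(CATEGORIES, map(float, sd))),
        z=dict(zip(CATEGORIES, map(float, z))),
        p=dict(zip(CATEGORIES, map(float, p))),
        n_sim=n_sim,
        mode=mode,
        seed=seed,
        degenerate=degenerate,
    )
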