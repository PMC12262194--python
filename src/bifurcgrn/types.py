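"""Core containers shared across the pipeline stages.

The pipeline moves a paired single-cell multiome (gene counts + ATAC peak
counts with per-cell trajectory metadata) through regulatory-potential
modeling, in-silico deletion scoring, base-GRN assembly, state-specific
weighted GRN fitting, and perturbation simulation.  These dataclasses are
the interchange format between those stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

TF_ROLES = ("pro_PB", "pro_GC", "housekeeping")


@dataclass
class CRE:
    """A candidate cis-regulatory element planted for one gene.

    ``distance`` is the signed TSS distance in bp, negative upstream with
    respect to the gene's strand.  ``bound_tfs`` maps TF name -> signed
    binding strength (sign encodes activation/repression of the element's
    accessibility by that TF's activity).
    """

    distance: int
    bound_tfs: dict[str, float]
    width: int = 400


@dataclass
class TrueGRN:
    """Planted ground-truth regulatory architecture for the simulator.

    ``cre_table[g]`` lists the CREs of gene ``g``; ``gene_decay[g]`` holds
    the (upstream, downstream) exponential decay lengths in bp;
    ``link_sign[(tf, g)]`` and ``effect_size[(tf, g)]`` describe the planted
    TF->gene edges.  Every planted edge is realized by >=1 CRE of its
    target gene that is bound by the TF.
    """

    tf_names: list[str]
    tf_role: dict[str, str]
    gene_names: list[str]
    gene_role: dict[str, str]
    cre_table: dict[str, list[CRE]]
    gene_decay: dict[str, tuple[float, float]]
    link_sign: dict[tuple[str, str], int]
    effect_size: dict[tuple[str, str], float]
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)  # name, chrom, tss, strand
    window: int = 100_000
    seed: int | None = None

    def planted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.link_sign)

    def validate(self) -> None:
        for tf, role in self.tf_role.items():
            if role not in TF_ROLES:
                raise ValueError(f"unknown TF role {role!r} for {tf}")
        for g, (lu, ld) in self.gene_decay.items():
            if lu <= 0 or ld <= 0:
                raise ValueError(f"nonpositive decay length for gene {g}")
        for (tf, g) in self.link_sign:
            cres = self.cre_table.get(g, [])
            if not any(tf in cre.bound_tfs for cre in cres):
                raise ValueError(f"planted edge {tf}->{g} has no bound CRE")


@dataclass
class MultiomeDataset:
    """Paired gene x cell and peak x cell counts with trajectory metadata.

    ``cells`` columns: cell, state, pseudotime, branch, x, y, clonotype,
    replicate, libsize.  ``genes`` columns: name, chrom, tss, strand.
    ``peaks`` columns: chrom, start, end, name (0-based half-open).
    """

    expr: sp.csr_matrix
    acc: sp.csr_matrix
    cells: pd.DataFrame
    genes: pd.DataFrame
    peaks: pd.DataFrame

    def validate(self) -> None:
        if self.expr.shape != (len(self.genes), len(self.cells)):
            raise ValueError("expr shape does not match gene/cell tables")
        if self.acc.shape != (len(self.peaks), len(self.cells)):
            raise ValueError("acc shape does not match peak/cell tables")
        if (self.expr.data < 0).any() or (self.acc.data < 0).any():
            raise ValueError("negative counts")

    def expr_dense(self) -> np.ndarray:
        return np.asarray(self.expr.todense(), dtype=float)

    def acc_dense(self) -> np.ndarray:
        return np.asarray(self.acc.todense(), dtype=float)


@dataclass
class PeakGeneIndex:
    """Per-gene list of (peak name, signed distance, side) within a window.

    ``side`` is 'upstream'/'downstream' relative to the gene's strand;
    distance is TSS-to-nearest-peak-edge, 0 when the peak spans the TSS.
    """

    links: dict[str, list[tuple[str, int, str]]]
    window: int

    def peaks_for(self, gene: str) -> list[tuple[str, int, str]]:
        return self.links.get(gene, [])


@dataclass
class RPModel:
    """Fitted regulatory-potential model for one gene.

    Peak weights decay exponentially with absolute TSS distance:
    w_j = exp(-|d_j| / l_side), so w(0) = 1 and weights shrink with
    distance.  Expression is modeled as Poisson with rate
    libsize * exp(alpha + beta * RP) where RP_c = sum_j w_j * acc_jc.
    """

    gene: str
    l_up: float
    l_down: float
    peak_names: list[str]
    distances: np.ndarray
    sides: list[str]
    weights: np.ndarray
    alpha: float
    beta: float
    loglik: float
    null_loglik: float
    degenerate: bool = False


@dataclass
class ISDMatrix:
    """TF x gene in-silico deletion scores with per-entry provenance."""

    scores: pd.DataFrame  # index: TF, columns: gene
    provenance: pd.DataFrame  # same shape; name of the retained binding set


@dataclass
class BaseGRN:
    """Binary TF->gene candidate links seeding state-specific GRN fits."""

    links: pd.DataFrame  # columns: tf, gene, score, source in {isd, coaccessibility}
    tfs: list[str]
    genes: list[str]

    def targets_of(self, tf: str) -> list[str]:
        return self.links.loc[self.links["tf"] == tf, "gene"].tolist()


@dataclass
class VectorField:
    """Per-cell 2-D vectors plus the gridded scalar field they came from."""

    vectors: np.ndarray  # (n_cells, 2)
    grid_values: np.ndarray  # (grid_n, grid_n) mean pseudotime (NaN if empty)
    grid_vx: np.ndarray
    grid_vy: np.ndarray
    extent: tuple[float, float, float, float]
    kind: str = "differentiation"


@dataclass
class PerturbationResult:
    """Scalar scoring of one simulated TF knockout against the flow field."""

    tf: str
    ps: np.ndarray  # per-cell dot products
    net_gc: float
    net_pb: float

    @property
    def delta_ps(self) -> float:
        return self.net_gc - self.net_pb


@dataclass
class ClonalTestResult:
    """Monte-Carlo null test of clonal fate concordance.

    Per category (PB_only / GC_only / bifurcated): observed count,
    simulated mean/sd under the fate-independence null, z score and
    p = 2 * (1 - Phi(|z|)).
    """

    observed: dict[str, int]
    sim_mean: dict[str, float]
    sim_sd: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    n_sim: int
    mode: str
    seed: int | None
    degenerate: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cats = list(self.observed)
        return pd.DataFrame(
            {
                "category": cats,
                "observed": [self.observed[c] for c in cats],
                "sim_mean": [self.sim_mean[c] for c in cats],
                "sim_sd": [self.sim_sd[c] for c in cats],
                "z": [self.z[c] for c in cats],
                "p": [self.p[c] for c in cats],
            }
        )
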