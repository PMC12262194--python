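"""Ground-truth-bearing simulator for a bifurcating B cell multiome.

The generative model mirrors the assumptions the inference stages make:

* TF activities follow 4-parameter logistic profiles in pseudotime and
  become branch-specific after the branch point (an activated -> GC / PB
  toggle: pro-PB and pro-GC TFs mutually repress each other's target
  elements).
* cCRE accessibility counts are Poisson with log-rate
  ``basal + sum_t strength_t * activity_t(cell)``.
* Gene expression counts are Poisson with log-rate
  ``alpha_g + beta_g * RP_gc + log(libsize)`` where
  ``RP_gc = sum_j exp(-|d_j| / l_side) * acc_jc`` -- additive cCRE
  contributions with exponential distance decay.
* Clone sizes are 1 + Poisson(rate) with a tunable probability that a
  clone's cells share one fate.
* Peak sequences carry planted composite elements (EICE / ISRE / AP1 ...)
  inside the functional cCREs, recorded as seqlet intervals.

Everything is seeded; identical seeds give bit-identical fixtures.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import CRE, MultiomeDataset, TrueGRN

MIN_TFS = 4
_CRE_WIDTH = 400
_CHROM_GENES = 25  # genes per synthetic chromosome

# Consensus realizations used when planting composite elements.  The
# scanner (targets module) recognizes these families; sequences planted
# here are exact-consensus instances with concrete S/N fills.
_PLANT_SEQS = {
    "EICE": "GGAATTGAAA",
    "ISRE": "GAAACCGAAA",
    "AP1": "TGACTCA",
    "ETS": "AGGAAGT",
    "PRDM1": "GAAAGTGAAAGT",
    "AICE": "TGACTCATTGAAA",
    "PRDM1_IRF": "GAAAGTGAAAGT",
}

DEFAULT_ROLE_FAMILIES = {
    "pro_PB": ["ISRE"],
    "pro_GC": ["EICE"],
    "housekeeping": ["AP1"],
}


def default_family_map(truth: TrueGRN) -> dict[str, list[str]]:
    """Motif families attributed to each TF (by planted role)."""
    return {tf: list(DEFAULT_ROLE_FAMILIES[truth.tf_role[tf]]) for tf in truth.tf_names}


@dataclass
class SimulationConfig:
    """Tunable knobs of the multiome simulator (all rates per cell).

    The defaults define the reference study conditions used throughout the
    test-suite: moderate accessibility counts (mean around one fragment
    per peak per cell), a branch point at pseudotime 0.4, logistic TF
    induction with time-scale ``tau``, and log-normal library sizes.
    """

    branch_point: float = 0.4
    tf_base: float = 0.2
    tf_amp: float = 1.2
    tf_tau: float = 0.08
    tf_t0_offset: float = 0.2  # logistic midpoint, relative to branch point
    trunk_frac: float = 0.3  # shared pre-branch induction, fraction of amp
    acc_basal: float = 0.4
    acc_noise_sd: float = 0.3
    expr_mean: float = 2.0  # target mean gene count at libsize 1
    expr_effect: float = 1.0  # log-rate spread per SD of regulatory potential
    tf_expr_mean: float = 3.0
    tf_expr_slope: float = 1.2
    libsize_sd: float = 0.3
    embed_noise_sd: float = 0.025
    n_decoy_peaks: int = 20
    overdispersion: float = 0.0  # gamma-mixing phi; 0 = pure Poisson


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_true_grn(
    n_tf: int,
    n_gene: int,
    n_cre_per_gene: int = 5,
    window: int = 100_000,
    seed: int = 0,
) -> TrueGRN:
    """Draw a planted regulatory architecture with a PB/GC toggle motif.

    TFs are split into pro-PB, pro-GC and housekeeping roles (at least one
    pro-PB and one pro-GC).  Program genes are activated by same-program
    TFs and repressed by the opposing program's TFs; housekeeping genes
    are driven by housekeeping TFs.  Each planted edge is realized by at
    least one cCRE of the target gene bound by that TF.
    """
    if n_tf < MIN_TFS:
        raise ValueError(
            f"n_tf must be >= {MIN_TFS} (need at least one pro-PB and one "
            f"pro-GC TF plus housekeeping controls); got {n_tf}"
        )
    if window <= 0:
        raise ValueError("window must be positive")
    rng = np.random.default_rng(seed)

    tf_names = [f"TF{i:02d}" for i in range(n_tf)]
    n_pb = max(1, n_tf // 3)
    n_gc = max(1, n_tf // 3)
    tf_role = {}
    for i, tf in enumerate(tf_names):
        if i < n_pb:
            tf_role[tf] = "pro_PB"
        elif i < n_pb + n_gc:
            tf_role[tf] = "pro_GC"
        else:
            tf_role[tf] = "housekeeping"
    pb_tfs = [t for t in tf_names if tf_role[t] == "pro_PB"]
    gc_tfs = [t for t in tf_names if tf_role[t] == "pro_GC"]
    hk_tfs = [t for t in tf_names if tf_role[t] == "housekeeping"] or tf_names[:1]

    gene_names = [f"G{i:03d}" for i in range(n_gene)]
    gene_role = {}
    for i, g in enumerate(gene_names):
        r = i % 5
        gene_role[g] = "PB_program" if r in (0, 1) else ("GC_program" if r in (2, 3) else "housekeeping")

    # genome layout: genes spaced so that peak-gene windows never overlap
    spacing = 2 * window + 20_000
    chroms, tss_pos, strands = [], [], []
    for i in range(n_gene):
        chroms.append(f"chr{i // _CHROM_GENES + 1}")
        tss_pos.append(window + 10_000 + (i % _CHROM_GENES) * spacing)
        strands.append(rng.choice(["+", "-"]))
    genes = pd.DataFrame(
        {"name": gene_names, "chrom": chroms, "tss": tss_pos, "strand": strands}
    )

    cre_table: dict[str, list[CRE]] = {}
    gene_decay: dict[str, tuple[float, float]] = {}
    link_sign: dict[tuple[str, str], int] = {}
    effect_size: dict[tuple[str, str], float] = {}

    for g in gene_names:
        lu = float(np.exp(rng.uniform(np.log(2_000), np.log(30_000))))
        ld = float(np.exp(rng.uniform(np.log(2_000), np.log(30_000))))
        gene_decay[g] = (lu, ld)
        role = gene_role[g]
        n_cre = n_cre_per_gene if role == "housekeeping" else max(n_cre_per_gene, 1)
        if role == "PB_program":
            activators, repressors = pb_tfs, gc_tfs
        elif role == "GC_program":
            activators, repressors = gc_tfs, pb_tfs
        else:
            activators, repressors = hk_tfs, []

        # distinct CRE positions, >= 1 kb from the TSS, within the window
        dists: list[int] = []
        while len(dists) < n_cre:
            d = int(rng.integers(1_000, int(0.9 * window))) * int(rng.choice([-1, 1]))
            if all(abs(d - d0) > _CRE_WIDTH + 200 for d0 in dists):
                dists.append(d)
        cres = []
        for d in dists:
            bound: dict[str, float] = {}
            n_act = int(rng.integers(1, min(2, len(activators)) + 1))
            for tf in rng.choice(activators, size=n_act, replace=False):
                bound[str(tf)] = float(rng.uniform(0.5, 1.5))
            if repressors and rng.random() < 0.5:
                tf = str(rng.choice(repressors))
                bound[tf] = -float(rng.uniform(0.5, 1.5))
            cres.append(CRE(distance=d, bound_tfs=bound, width=_CRE_WIDTH))
        cre_table[g] = cres
        for cre in cres:
            for tf, s in cre.bound_tfs.items():
                key = (tf, g)
                link_sign[key] = 1 if s > 0 else -1
                effect_size[key] = max(effect_size.get(key, 0.0), abs(s))

    truth = TrueGRN(
        tf_names=tf_names,
        tf_role=tf_role,
        gene_names=gene_names,
        gene_role=gene_role,
        cre_table=cre_table,
        gene_decay=gene_decay,
        link_sign=link_sign,
        effect_size=effect_size,
        genes=genes,
        window=window,
        seed=seed,
    )
    truth.validate()
    return truth


def tf_activity(
    truth: TrueGRN,
    pseudotime: np.ndarray,
    branch: np.ndarray,
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Logistic TF activity profiles: shared trunk induction, then
    branch-specific rise (own branch) or decay (opposing branch)."""
    t = np.asarray(pseudotime, dtype=float)
    bp = cfg.branch_point
    base, amp, tau = cfg.tf_base, cfg.tf_amp, cfg.tf_tau
    trunk_amp = cfg.trunk_frac * amp
    t0 = bp + cfg.tf_t0_offset
    out = {}
    for tf in truth.tf_names:
        role = truth.tf_role[tf]
        if role == "housekeeping":
            out[tf] = np.full_like(t, 1.0)
            continue
        own = "PB" if role == "pro_PB" else "GC"
        a = base + trunk_amp * _sigmoid((t - 0.5 * bp) / tau)  # trunk profile
        on_own = branch == own
        on_other = (branch != own) & (branch != "trunk")
        a = np.where(
            on_own, base + trunk_amp + (amp - trunk_amp) * _sigmoid((t - t0) / tau), a
        )
        a = np.where(on_other, base + trunk_amp * (1.0 - _sigmoid((t - t0) / tau)), a)
        out[tf] = a
    return pd.DataFrame(out).T  # TF x cell


def simulate_multiome(
    truth: TrueGRN,
    n_cells: int = 2_000,
    branch_point: float | None = None,
    config: SimulationConfig | None = None,
    seed: int = 0,
    ko_tf: str | None = None,
) -> MultiomeDataset:
    """Simulate paired counts along an activated -> GC / PB bifurcation.

    ``ko_tf`` silences one TF (zero activity and near-zero transcript
    rate), emulating a CRISPR knockout arm; two arms simulated from the
    same truth with different seeds share true effects but have
    independent sampling noise.
    """
    cfg = config or SimulationConfig()
    if branch_point is not None:
        cfg = SimulationConfig(**{**asdict(cfg), "branch_point": branch_point})
    if not 0.0 < cfg.branch_point < 1.0:
        raise ValueError("branch_point must lie strictly between 0 and 1")
    truth.validate()
    if ko_tf is not None and ko_tf not in truth.tf_names:
        raise ValueError(f"unknown ko_tf {ko_tf!r}")
    rng = np.random.default_rng(seed)

    t = rng.uniform(0.0, 1.0, size=n_cells)
    branch = np.where(t < cfg.branch_point, "trunk", "")
    post = branch == ""
    branch[post] = np.where(rng.random(post.sum()) < 0.5, "PB", "GC")
    state = np.where(branch == "trunk", "ActB", branch)

    act = tf_activity(truth, t, branch, cfg)  # TF x cell
    act_ref = act.copy()  # unperturbed reference, calibrates alpha/beta
    if ko_tf is not None:
        act.loc[ko_tf] = 0.0

    # --- peaks: one row per cCRE plus unbound decoys -----------------
    gene_info = truth.genes.set_index("name")
    peak_rows = []
    strengths = []  # aligned list of dicts TF -> signed strength
    for g in truth.gene_names:
        chrom = gene_info.at[g, "chrom"]
        tss = int(gene_info.at[g, "tss"])
        strand = gene_info.at[g, "strand"]
        for j, cre in enumerate(truth.cre_table[g]):
            d_gen = cre.distance if strand == "+" else -cre.distance
            center = tss + d_gen
            peak_rows.append(
                {
                    "chrom": chrom,
                    "start": center - cre.width // 2,
                    "end": center + cre.width - cre.width // 2,
                    "name": f"{g}:cre{j}",
                }
            )
            strengths.append(cre.bound_tfs)
    chrom_span = {}
    for _, row in truth.genes.iterrows():
        lo, hi = chrom_span.get(row["chrom"], (np.inf, -np.inf))
        chrom_span[row["chrom"]] = (min(lo, row["tss"]), max(hi, row["tss"]))
    chrom_list = sorted(chrom_span)
    for k in range(cfg.n_decoy_peaks if chrom_list else 0):
        chrom = chrom_list[k % len(chrom_list)]
        lo, hi = chrom_span[chrom]
        pos = int(rng.integers(max(1_000, lo - truth.window), hi + truth.window))
        peak_rows.append(
            {"chrom": chrom, "start": pos, "end": pos + _CRE_WIDTH, "name": f"decoy{k:03d}"}
        )
        strengths.append({})
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "name"])

    act_arr = act.to_numpy()  # (n_tf, n_cells)
    tf_index = {tf: i for i, tf in enumerate(truth.tf_names)}
    n_peaks = len(peaks)
    log_rate = np.full((n_peaks, n_cells), np.log(cfg.acc_basal))
    for j, bound in enumerate(strengths):
        for tf, s in bound.items():
            log_rate[j] += s * (act_arr[tf_index[tf]] - cfg.tf_base)
    # expected accessibility under the unperturbed network: the gene
    # models are calibrated against this reference so that a TF knockout
    # shifts expression instead of being re-normalized away
    act_ref_arr = act_ref.to_numpy()
    log_rate_ref = np.full((n_peaks, n_cells), np.log(cfg.acc_basal))
    for j, bound in enumerate(strengths):
        for tf, s in bound.items():
            log_rate_ref[j] += s * (act_ref_arr[tf_index[tf]] - cfg.tf_base)
    acc_rate_ref = np.exp(log_rate_ref + 0.5 * cfg.acc_noise_sd**2)

    log_rate += rng.normal(0.0, cfg.acc_noise_sd, size=log_rate.shape)
    acc_rate = np.exp(log_rate)
    if cfg.overdispersion > 0:
        phi = cfg.overdispersion
        acc_rate = acc_rate * rng.gamma(1.0 / phi, phi, size=acc_rate.shape)
    acc = rng.poisson(acc_rate).astype(np.int64)

    # --- genes: RP-driven expression ---------------------------------
    libsize = np.exp(rng.normal(0.0, cfg.libsize_sd, size=n_cells))
    if n_cells:
        libsize /= libsize.mean()
    peak_row_of = {name: j for j, name in enumerate(peaks["name"])}
    expr_rows = []
    gene_rows = []
    for tf in truth.tf_names:  # TF transcripts track activity
        a = act_arr[tf_index[tf]]
        if ko_tf == tf:
            lr = np.full(n_cells, -6.0)
        else:
            a_mean = a.mean() if n_cells else 0.0
            lr = np.log(cfg.tf_expr_mean) + cfg.tf_expr_slope * (a - a_mean)
        expr_rows.append(np.exp(lr) * libsize)
        gene_rows.append({"name": tf, "chrom": "chrTF", "tss": 1_000 + 10_000 * tf_index[tf], "strand": "+"})
    for g in truth.gene_names:
        lu, ld = truth.gene_decay[g]
        cres = truth.cre_table[g]
        if cres:
            w = np.array(
                [np.exp(-abs(c.distance) / (lu if c.distance < 0 else ld)) for c in cres]
            )
            rows = [peak_row_of[f"{g}:cre{j}"] for j in range(len(cres))]
            rp = w @ acc[rows].astype(float)
            # KO-independent calibration: mean and dispersion of RP under
            # the unperturbed network, counting noise included
            rate_ref = acc_rate_ref[rows]
            rp_ref = w @ rate_ref
            count_var = rate_ref + rate_ref**2 * (np.exp(cfg.acc_noise_sd**2) - 1.0)
            var = rp_ref.var() + float((w**2 @ count_var).mean())
            mu, sd = rp_ref.mean(), np.sqrt(var)
            z = (rp - mu) / sd if sd > 1e-12 else np.zeros(n_cells)
        else:
            z = np.zeros(n_cells)
        lr = np.log(cfg.expr_mean) + cfg.expr_effect * z
        expr_rows.append(np.exp(lr) * libsize)
        info = gene_info.loc[g]
        gene_rows.append(
            {"name": g, "chrom": info["chrom"], "tss": int(info["tss"]), "strand": info["strand"]}
        )
    expr_rate = np.vstack(expr_rows)
    if cfg.overdispersion > 0:
        phi = cfg.overdispersion
        expr_rate = expr_rate * rng.gamma(1.0 / phi, phi, size=expr_rate.shape)
    expr = rng.poisson(expr_rate).astype(np.int64)

    offset = np.where(branch == "trunk", 0.0, (t - cfg.branch_point))
    y = np.where(branch == "PB", -offset, np.where(branch == "GC", offset, 0.0))
    x = t + rng.normal(0.0, cfg.embed_noise_sd, size=n_cells)
    y = y + rng.normal(0.0, cfg.embed_noise_sd, size=n_cells)

    cells = pd.DataFrame(
        {
            "cell": [f"c{i:05d}" for i in range(n_cells)],
            "state": state,
            "pseudotime": t,
            "branch": branch,
            "x": x,
            "y": y,
            "clonotype": [""] * n_cells,
            "replicate": np.where(rng.random(n_cells) < 0.5, "rep1", "rep2"),
            "libsize": libsize,
        }
    )
    ds = MultiomeDataset(
        expr=sp.csr_matrix(expr),
        acc=sp.csr_matrix(acc),
        cells=cells,
        genes=pd.DataFrame(gene_rows),
        peaks=peaks,
    )
    ds.validate()
    return ds


def simulate_clonotypes(
    n_clones: int,
    mean_size_pb: float = 2.0,
    mean_size_gc: float = 1.0,
    concordance: float = 0.8,
    pi_pb: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate clonotype membership with tunable fate concordance.

    Clone size is 1 + Poisson(rate of the clone's fate class), so every
    clone has at least one cell.  With probability ``concordance`` all of
    a clone's cells adopt the clone fate (Bernoulli(pi_pb) -> PB);
    otherwise each cell's fate is i.i.d. Bernoulli(pi_pb).
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must lie in [0, 1]")
    if not 0.0 <= pi_pb <= 1.0:
        raise ValueError("pi_pb must lie in [0, 1]")
    if mean_size_pb <= 0 or mean_size_gc <= 0:
        raise ValueError("clone-size rates must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    cell_id = 0
    for k in range(n_clones):
        clone_fate = "PB" if rng.random() < pi_pb else "GC"
        lam = mean_size_pb if clone_fate == "PB" else mean_size_gc
        size = 1 + int(rng.poisson(lam))
        concordant = rng.random() < concordance
        for _ in range(size):
            if concordant:
                fate = clone_fate
            else:
                fate = "PB" if rng.random() < pi_pb else "GC"
            rows.append({"cell": f"cell{cell_id:06d}", "clonotype": f"clone{k:05d}", "fate": fate})
            cell_id += 1
    return pd.DataFrame(rows, columns=["cell", "clonotype", "fate"])


def plant_sequences(
    truth: TrueGRN,
    peaks: pd.DataFrame,
    seed: int = 0,
    family_map: dict[str, list[str]] | None = None,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Random peak sequences with consensus composite elements planted in
    functional cCREs, one element per bound TF, at recorded offsets."""
    fam_map = family_map or default_family_map(truth)
    rng = np.random.default_rng(seed)
    records = []
    seqlet_rows = []
    cre_lookup = {}
    for g in truth.gene_names:
        for j, cre in enumerate(truth.cre_table[g]):
            cre_lookup[f"{g}:cre{j}"] = cre
    for _, row in peaks.iterrows():
        width = int(row["end"] - row["start"])
        seq = list(rng.choice(list("ACGT"), size=width))
        cre = cre_lookup.get(row["name"])
        if cre is not None:
            slot = 60
            for tf in sorted(cre.bound_tfs):
                for fam in fam_map.get(tf, []):
                    motif = _PLANT_SEQS[fam]
                    if slot + len(motif) > width - 20:
                        break
                    seq[slot : slot + len(motif)] = list(motif)
                    seqlet_rows.append(
                        {
                            "chrom": row["chrom"],
                            "start": int(row["start"]) + slot,
                            "end": int(row["start"]) + slot + len(motif),
                            "family": fam,
                            "strand": "+",
                            "seq": motif,
                        }
                    )
                    slot += len(motif) + 24
        records.append(
            SeqRecord(Seq("".join(seq)), id=str(row["name"]), description=f"{row['chrom']}:{row['start']}-{row['end']}")
        )
    seqlets = pd.DataFrame(
        seqlet_rows, columns=["chrom", "start", "end", "family", "strand", "seq"]
    ).drop_duplicates(subset=["chrom", "start", "end", "family"], ignore_index=True)
    return records, seqlets


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def emit_fixtures(
    dataset: MultiomeDataset,
    truth: TrueGRN,
    out_dir: str | Path,
    seed: int = 0,
) -> dict[str, str]:
    """Write the dataset + truth to plain-text fixtures and a manifest.

    Files: MatrixMarket counts, TSV label/metadata tables, BED intervals
    (0-based half-open, sorted), FASTA peak sequences with planted
    composite elements, JSON ground truth.  Returns {file: sha256}.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    mmwrite(str(out / "expr.mtx"), sp.coo_matrix(dataset.expr))
    mmwrite(str(out / "acc.mtx"), sp.coo_matrix(dataset.acc))
    dataset.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    dataset.cells.to_csv(out / "cells.tsv", sep="\t", index=False)
    tss = dataset.genes[["chrom", "tss", "strand", "name"]]
    tss.to_csv(out / "tss.tsv", sep="\t", index=False)

    peaks_sorted = dataset.peaks.sort_values(["chrom", "start", "end"], kind="mergesort")
    peaks_sorted[["chrom", "start", "end", "name"]].to_csv(
        out / "peaks.bed", sep="\t", index=False, header=False
    )

    # TF binding regions: the cCRE intervals each TF is planted to bind
    gene_info = truth.genes.set_index("name") if len(truth.genes) else pd.DataFrame()
    bind_rows = []
    peak_by_name = dataset.peaks.set_index("name") if len(dataset.peaks) else pd.DataFrame()
    for g in truth.gene_names:
        for j, cre in enumerate(truth.cre_table[g]):
            pname = f"{g}:cre{j}"
            if pname not in peak_by_name.index:
                continue
            prow = peak_by_name.loc[pname]
            for tf in sorted(cre.bound_tfs):
                bind_rows.append(
                    {"chrom": prow["chrom"], "start": int(prow["start"]), "end": int(prow["end"]), "name": tf}
                )
    pd.DataFrame(bind_rows, columns=["chrom", "start", "end", "name"]).sort_values(
        ["name", "chrom", "start"], kind="mergesort"
    ).to_csv(out / "tf_binding.bed", sep="\t", index=False, header=False)

    records, seqlets = plant_sequences(truth, dataset.peaks, seed=seed)
    SeqIO.write(records, str(out / "peak_sequences.fasta"), "fasta")
    seqlets.sort_values(["chrom", "start", "end"], kind="mergesort").to_csv(
        out / "seqlets.bed", sep="\t", index=False, header=False
    )

    truth_json = {
        "tf_names": truth.tf_names,
        "tf_role": truth.tf_role,
        "gene_names": truth.gene_names,
        "gene_role": truth.gene_role,
        "gene_decay": {g: list(v) for g, v in truth.gene_decay.items()},
        "link_sign": {f"{tf}|{g}": s for (tf, g), s in truth.link_sign.items()},
        "effect_size": {f"{tf}|{g}": v for (tf, g), v in truth.effect_size.items()},
        "cre_table": {
            g: [{"distance": c.distance, "bound_tfs": c.bound_tfs, "width": c.width} for c in cres]
            for g, cres in truth.cre_table.items()
        },
        "window": truth.window,
        "seed": truth.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=1, sort_keys=True))

    names = [
        "expr.mtx", "acc.mtx", "genes.tsv", "cells.tsv", "tss.tsv", "peaks.bed",
        "tf_binding.bed", "peak_sequences.fasta", "seqlets.bed", "truth.json",
    ]
    manifest = {n: _sha256(out / n) for n in names}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
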