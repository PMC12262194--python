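"""Direct TF target calling from perturbation DEGs and seqlet-anchored
regulatory-potential scores.

Stages: (1) per-replicate differential expression (Wilcoxon rank-sum,
Benjamini-Hochberg FDR) and the two-replicate concordance filter
(|fold change| > 1.25 strict, FDR <= 0.05 inclusive, matching sign);
(2) an exact IUPAC consensus scanner for simple and composite IRF-family
elements (EICE = GGAA-NN-GAAA, ISRE = GAAA-NN-GAAA, AP1 = TGASTCA, ...)
on both strands; (3) per TF-gene RP scores summing the decay weights of
the gene's linked cCREs that contain a cognate seqlet -- a DEG with at
least one such cCRE is called a direct target; (4) Fisher-exact overlap
statistics between target gene sets.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu
from statsmodels.stats.multitest import multipletests
from Bio import SeqIO

from .types import RPModel

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
_COMP = str.maketrans("ACGTN", "TGCAN")

FAMILY_CONSENSUS = {
    "EICE": "GGAANNGAAA",
    "ISRE": "GAAANNGAAA",
    "AP1": "TGASTCA",
    "ETS": "RGGAAR",
    "PRDM1": "GAAAGTGAAAGT",
}
COMPOSITE_FAMILIES = ("AICE", "PRDM1_IRF")
AICE_GAP_RANGE = (0, 4)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _scan_consensus(seq: str, consensus: str) -> list[int]:
    """Start positions of all (overlapping) exact IUPAC consensus matches."""
    m = len(consensus)
    allowed = [IUPAC[c] for c in consensus]
    hits = []
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in allowed[j] for j in range(m)):
            hits.append(i)
    return hits


def _aice_spans(seq: str) -> list[tuple[int, int]]:
    """AP1 (TGASTCA) and an IRF GAAA half-site with a 0-4 bp gap, either order."""
    ap1 = _scan_consensus(seq, FAMILY_CONSENSUS["AP1"])
    gaaa = _scan_consensus(seq, "GAAA")
    lo, hi = AICE_GAP_RANGE
    spans = []
    for a in ap1:
        for g in gaaa:
            if lo <= g - (a + 7) <= hi or lo <= a - (g + 4) <= hi:
                spans.append((min(a, g), max(a + 7, g + 4)))
    return sorted(set(spans))


def _prdm1_irf_spans(seq: str) -> list[tuple[int, int]]:
    """PRDM1 consensus hits overlapping an ISRE hit (>= 1 bp)."""
    prdm1 = _scan_consensus(seq, FAMILY_CONSENSUS["PRDM1"])
    isre = _scan_consensus(seq, FAMILY_CONSENSUS["ISRE"])
    spans = []
    for p in prdm1:
        for i in isre:
            if p < i + 10 and i < p + 12:
                spans.append((p, p + 12))
                break
    return sorted(set(spans))


def _family_spans(seq: str, family: str) -> list[tuple[int, int]]:
    if family in FAMILY_CONSENSUS:
        m = len(FAMILY_CONSENSUS[family])
        return [(i, i + m) for i in _scan_consensus(seq, FAMILY_CONSENSUS[family])]
    if family == "AICE":
        return _aice_spans(seq)
    if family == "PRDM1_IRF":
        return _prdm1_irf_spans(seq)
    raise ValueError(f"unknown motif family {family!r}")


def _load_sequences(sequences) -> dict[str, str]:
    if isinstance(sequences, (str, Path)):
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(sequences), "fasta")}
    if isinstance(sequences, dict):
        return {str(k): str(v) for k, v in sequences.items()}
    return {rec.id: str(rec.seq) for rec in sequences}


def scan_composite_elements(sequences, families) -> pd.DataFrame:
    """Scan sequences for motif-family hits on both strands.

    ``sequences`` is a FASTA path, a {name: sequence} dict, or SeqRecords.
    Minus-strand hits are reported in plus-strand coordinates with the
    matched sequence on the motif strand.  All overlapping matches are
    reported.  Returns columns chrom/start/end/family/strand/seq
    (0-based half-open).
    """
    seqs = _load_sequences(sequences)
    rows = []
    for name, raw in seqs.items():
        seq = raw.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"record {name!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        rc = _revcomp(seq)
        L = len(seq)
        for fam in families:
            for s, e in _family_spans(seq, fam):
                rows.append({"chrom": name, "start": s, "end": e, "family": fam,
                             "strand": "+", "seq": seq[s:e]})
            for s, e in _family_spans(rc, fam):
                ps, pe = L - e, L - s
                rows.append({"chrom": name, "start": ps, "end": pe, "family": fam,
                             "strand": "-", "seq": rc[s:e]})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "family", "strand", "seq"])
    return df.sort_values(["chrom", "start", "end", "family", "strand"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------
# differential expression and the two-replicate concordance filter
# ---------------------------------------------------------------------

def deg_stats(
    counts: pd.DataFrame,
    group_ko: np.ndarray,
    group_ctl: np.ndarray,
    scale: float = 1e4,
) -> pd.DataFrame:
    """Per-gene log2 fold change, Wilcoxon rank-sum p and BH-FDR.

    Counts are library-size normalized per cell (to ``scale``); the fold
    change compares group mean normalized expression with a 1e-9
    pseudocount.  Genes that are all-zero in both groups get p=1, FC=0.
    """
    ko = counts.loc[:, group_ko]
    ctl = counts.loc[:, group_ctl]
    if ko.shape[1] == 0 or ctl.shape[1] == 0:
        raise ValueError("both groups must be non-empty")

    def _norm(df: pd.DataFrame) -> pd.DataFrame:
        lib = df.sum(axis=0).astype(float).replace(0, np.nan)
        return (df / lib * scale).fillna(0.0)

    ko_n, ctl_n = _norm(ko), _norm(ctl)
    eps = 1e-9
    m_ko = ko_n.mean(axis=1)
    m_ctl = ctl_n.mean(axis=1)
    log2fc = np.log2((m_ko + eps) / (m_ctl + eps))
    pvals = np.ones(len(counts))
    for i, g in enumerate(counts.index):
        a = ko_n.loc[g].to_numpy()
        b = ctl_n.loc[g].to_numpy()
        if not a.any() and not b.any():
            log2fc.iloc[i] = 0.0
            continue
        pvals[i] = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"gene": counts.index, "log2fc": log2fc.to_numpy(), "p": pvals, "fdr": fdr}
    ).set_index("gene")


def concordant_degs(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    fc_cut: float = 1.25,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Genes passing |FC| > fc_cut (strict) and FDR <= fdr_cut (inclusive)
    in BOTH replicates with matching sign; adds a direction column."""
    shared = rep1.index.intersection(rep2.index)
    r1, r2 = rep1.loc[shared], rep2.loc[shared]
    log2_cut = np.log2(fc_cut)
    ok = (
        (r1["log2fc"].abs() > log2_cut)
        & (r2["log2fc"].abs() > log2_cut)
        & (r1["fdr"] <= fdr_cut)
        & (r2["fdr"] <= fdr_cut)
        & (np.sign(r1["log2fc"]) == np.sign(r2["log2fc"]))
        & (r1["log2fc"] != 0)
    )
    out = pd.DataFrame(
        {
            "log2fc_rep1": r1.loc[ok, "log2fc"],
            "log2fc_rep2": r2.loc[ok, "log2fc"],
            "direction": np.where(r1.loc[ok, "log2fc"] > 0, "up", "down"),
        }
    )
    return out


# ---------------------------------------------------------------------
# seqlet-anchored RP scoring
# ---------------------------------------------------------------------

def _seqlet_hits_per_peak(
    peaks: pd.DataFrame, seqlets: pd.DataFrame, families: set[str]
) -> set[str]:
    """Peak names containing >= 1 bp overlap with a seqlet of ``families``."""
    sub = seqlets.loc[seqlets["family"].isin(families)]
    hit: set[str] = set()
    for chrom, s in sub.groupby("chrom"):
        pk = peaks.loc[peaks["chrom"] == chrom]
        if pk.empty:
            continue
        ps = pk["start"].to_numpy()[:, None]
        pe = pk["end"].to_numpy()[:, None]
        ss = s["start"].to_numpy()[None, :]
        se = s["end"].to_numpy()[None, :]
        mask = ((ps < se) & (ss < pe)).any(axis=1)
        hit |= set(pk.loc[mask, "name"])
    return hit


def rp_score_targets(
    degs_by_tf: dict[str, pd.DataFrame],
    models: dict[str, RPModel],
    seqlets: pd.DataFrame,
    family_map: dict[str, list[str]],
    peaks: pd.DataFrame,
) -> pd.DataFrame:
    """RP score per (TF, DEG): sum of seqlet-containing linked-cCRE weights.

    A gene is a direct target of a TF when it is a DEG of that TF's
    knockout AND at least one of its RP-model cCREs contains a cognate
    seqlet.  DEGs without an RP model are flagged and excluded from
    direct targets.
    """
    rows = []
    for tf, degs in sorted(degs_by_tf.items()):
        fams = set(family_map.get(tf, []))
        genes = list(degs.index) if isinstance(degs, pd.DataFrame) else list(degs)
        hit_peaks = _seqlet_hits_per_peak(peaks, seqlets, fams) if fams else set()
        for g in genes:
            model = models.get(g)
            if model is None:
                rows.append({"tf": tf, "gene": g, "rp_score": np.nan,
                             "n_seqlet_cres": 0, "direct_target": False, "flag": "no_model"})
                continue
            mask = np.array([p in hit_peaks for p in model.peak_names])
            score = float(model.weights[mask].sum())
            n = int(mask.sum())
            rows.append({"tf": tf, "gene": g, "rp_score": score,
                         "n_seqlet_cres": n, "direct_target": n >= 1, "flag": ""})
    return pd.DataFrame(
        rows, columns=["tf", "gene", "rp_score", "n_seqlet_cres", "direct_target", "flag"]
    )


# ---------------------------------------------------------------------
# gene-set overlap statistics
# ---------------------------------------------------------------------

def target_overlap(set_a, set_b, universe) -> tuple[float, float]:
    """Two-sided Fisher exact test of the 2x2 membership table.

    Returns (odds ratio, p).  The odds ratio is the sample odds ratio
    with a 0.5 continuity correction applied when any cell is zero.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    if not set(set_a) <= universe or not set(set_b) <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(universe) - n11 - n10 - n01
    table = np.array([[n11, n10], [n01, n00]], dtype=float)
    _, p = fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        table = table + 0.5
    odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return float(odds), float(p)


def target_overlap_batch(
    pairs: dict[str, tuple[set, set]], universe
) -> pd.DataFrame:
    """Fisher overlap for a batch of set pairs with BH-FDR across pairs."""
    names = sorted(pairs)
    odds, ps = [], []
    for name in names:
        a, b = pairs[name]
        o, p = target_overlap(a, b, universe)
        odds.append(o)
        ps.append(p)
    fdr = multipletests(ps, method="fdr_bh")[1] if names else []
    return pd.DataFrame({"pair": names, "odds_ratio": odds, "p": ps, "fdr": fdr}).set_index("pair")
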