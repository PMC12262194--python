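"""Assembly of the binary base-GRN from ISD scores.

The base-GRN keeps the globally largest TF-gene ISD scores: with a
retention quantile q, exactly ``round(q * n_TF * n_gene)`` links survive,
regardless of the score distribution (deterministic tie-breaking by
descending score, then TF name, then gene name).  TFs entirely absent
from the ISD matrix -- e.g. lacking usable binding data -- can be rescued
through co-accessibility links (score strictly above a threshold,
restricted to the modeled gene set).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import BaseGRN, ISDMatrix

logger = logging.getLogger(__name__)


def assemble_base_grn(
    isd: ISDMatrix | pd.DataFrame,
    quantile: float = 0.05,
    coacc: pd.DataFrame | None = None,
    coacc_min: float = 0.8,
    modeled_genes: list[str] | None = None,
) -> BaseGRN:
    """Retain the top-``quantile`` ISD links plus co-accessibility rescues.

    ``coacc`` (optional) has columns tf/gene/score; only rows for TFs not
    present in the ISD matrix are used, with ``score > coacc_min``
    (strict) and gene restricted to ``modeled_genes`` (defaults to the
    ISD matrix's gene set).
    """
    scores = isd.scores if isinstance(isd, ISDMatrix) else isd
    if scores.size == 0:
        raise ValueError("empty ISD matrix")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie strictly between 0 and 1")
    genes = [str(g) for g in scores.columns]
    tfs = [str(t) for t in scores.index]
    modeled = list(modeled_genes) if modeled_genes is not None else genes

    long = scores.stack().rename("score").reset_index()
    long.columns = ["tf", "gene", "score"]
    if not (long["score"] != 0).any():
        logger.warning("all ISD scores are zero; ISD-sourced link set is empty")
        retained = long.iloc[0:0]
    else:
        k = int(round(quantile * len(long)))
        long = long.sort_values(
            ["score", "tf", "gene"], ascending=[False, True, True], kind="mergesort"
        )
        retained = long.head(k)
    links = retained.assign(source="isd")

    if coacc is not None and len(coacc):
        extra = coacc.loc[
            ~coacc["tf"].isin(tfs)
            & (coacc["score"] > coacc_min)
            & coacc["gene"].isin(modeled)
        ]
        extra = extra[["tf", "gene", "score"]].assign(source="coaccessibility")
        links = pd.concat([links, extra], ignore_index=True)
        tfs = tfs + sorted(set(extra["tf"]) - set(tfs))

    links = links.drop_duplicates(subset=["tf", "gene"], ignore_index=True)
    return BaseGRN(links=links.reset_index(drop=True), tfs=tfs, genes=modeled)


def mean_targets_per_tf(grn: BaseGRN) -> float:
    """Average number of target genes per TF in the base-GRN."""
    if not grn.tfs:
        return 0.0
    return len(grn.links) / len(grn.tfs)
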