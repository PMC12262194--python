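# bifurcgrn

State-specific gene regulatory network (GRN) inference, in-silico
transcription-factor perturbation and clonal fate analysis for a
bifurcating B cell differentiation system.

Activated human B cells bifurcate into plasmablasts (PB; IRF4-high,
BLIMP1-high antibody secretors) and germinal center B cells (GCBC;
IRF8/BCL6/BATF-associated). `bifurcgrn` implements a complete desk-scale
pipeline for studying how transcription factors (TFs) control such a
bifurcation from paired single-cell multiome data (gene expression +
chromatin accessibility), together with a seeded synthetic-data generator
that plants a known regulatory architecture so every stage can be
validated against ground truth.

## What the pipeline computes

1. **Regulatory-potential (RP) models** (`bifurcgrn.rp`). Candidate
   cis-regulatory elements (cCREs, i.e. ATAC peaks) within ±100 kb of a
   gene's TSS contribute additively to the gene's regulatory potential,
   weighted by an exponential decay in distance with separate upstream and
   downstream decay lengths:

       RP_c = Σ_j exp(−|d_j| / ℓ_side) · a_jc,
       E[y_c] = libsize_c · exp(α + β · RP_c)   (Poisson, log link)

   Decay lengths are chosen by exhaustive grid search on the profile
   log-likelihood (12 log-spaced points per side, 500 bp – 100 kb).

2. **In-silico deletion (ISD) scoring**. A TF's influence on a gene is the
   log-likelihood drop after deleting the model peaks overlapping that
   TF's binding regions and refitting (α, β) with decay lengths frozen.
   With multiple binding sets per TF the top score per TF–gene pair is
   retained.

3. **Base-GRN assembly** (`bifurcgrn.base_grn`). The top 5% of all
   TF×gene ISD scores (global quantile) become binary candidate links —
   with 50 TFs and 4,306 modeled genes this averages ~215 targets per TF.
   TFs lacking binding data can be rescued by co-accessibility links
   (score strictly > 0.8, modeled genes only).

4. **State-specific weighted GRNs** (`bifurcgrn.state_grn`). Per cell
   state, each gene is regressed on its candidate TFs by Bayesian ridge
   (evidence approximation); the top 10,000 edges with p < 0.001 are
   refit in a second round. TF eigenvector centralities per state and
   k-means clusters of scaled centrality profiles summarize network
   reconfiguration.

5. **In-silico TF knockouts** (`bifurcgrn.perturb`). A knockout is
   propagated through the state GRN for three steps (primary, secondary,
   tertiary targets), embedded as a 2-D perturbation vector field via a
   neighbor-correlation kernel, and scored per cell as the dot product
   with the pseudotime-gradient differentiation flow. The summary
   `delta_PS = net_GC − net_PB` is positive when the knockout skews cells
   toward the GC fate.

6. **Clonal fate concordance** (`bifurcgrn.clonal`). Clonotypes (≥ 2
   cells) are classified as PB-only / GC-only / bifurcated and tested
   against a fate-independence null by Monte-Carlo simulation
   (permutation of fates, or Poisson-resampled clone sizes), with
   z-scores and p = 2·(1 − Φ(|z|)).

7. **Direct target calling** (`bifurcgrn.targets`). Knockout DEGs that
   are concordant across two replicates (|FC| > 1.25, FDR ≤ 0.05, same
   sign) are scored by the summed RP weights of their linked cCREs that
   contain a cognate seqlet; an exact IUPAC consensus scanner finds the
   composite IRF elements (EICE `GGAANNGAAA`, ISRE `GAAANNGAAA`, AICE,
   AP1, ETS, PRDM1) on both strands.

## Worked example

```python
import pandas as pd
import bifurcgrn as bg
from bifurcgrn import pipeline

truth = bg.generate_true_grn(n_tf=8, n_gene=30, seed=0)
ds = bg.simulate_multiome(truth, n_cells=1000, seed=1)
expr, acc, lib = pipeline.frames(ds)
norm = bg.normalize_expression(expr)
states = pd.Series(ds.cells["state"].to_numpy(), index=ds.cells["cell"].to_numpy())

base = pipeline.base_grn_from_truth(truth)
edges = pipeline.fit_state_grns(base, norm, states, ["ActB", "GC", "PB"])
for tf in ("TF00", "TF02"):
    res = pipeline.ko_delta_ps(edges, norm, ds, tf)
    print(f"{tf} ({truth.tf_role[tf]:7s})  net_GC={res.net_gc:+.2f}  "
          f"net_PB={res.net_pb:+.2f}  delta_PS={res.delta_ps:+.2f}")

tab = bg.simulate_clonotypes(200, concordance=0.9, seed=2)
print(bg.clonal_null_test(tab, n_sim=1000, seed=3).to_frame().round(3).to_string(index=False))
```

prints

```
TF00 (pro_PB )  net_GC=+10.36  net_PB=-2.74  delta_PS=+13.09
TF02 (pro_GC )  net_GC=-3.04  net_PB=+5.96  delta_PS=-9.00
  category  observed  sim_mean  sim_sd       z   p
   PB_only        86    43.178   3.839  11.153 0.0
   GC_only        56    14.117   2.943  14.232 0.0
bifurcated        18   102.705   5.272 -16.066 0.0
```

Knocking out the planted PB-promoting TF gives a positive delta-PS (cells
pushed toward the GC fate) and the GC-promoting TF the opposite — the
directional logic expected of counteracting fate regulators. With 90%
clonal fate concordance, one-fate clonotypes far exceed the
fate-independence null and bifurcated clones fall far below it.

A thin CLI covers the file-oriented steps:

```sh
bifurcgrn simulate --seed 5 --out fixtures/
bifurcgrn clonal-test --table clones.tsv --n-sim 1000 --seed 1
bifurcgrn scan-ce --fasta peaks.fasta --families EICE,ISRE --out hits.tsv
bifurcgrn base-grn --isd isd.tsv --out base.tsv
```

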