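# Methods

This note documents the models implemented in `bifurcgrn`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Regulatory-potential model

Each modeled gene's expression is linked to the accessibility of its
flanking cCREs through an additive, exponentially decaying weight:

    w_j = exp(−|d_j| / ℓ_side),   RP_c = Σ_j w_j · a_jc

where `d_j` is the signed TSS-to-nearest-peak-edge distance (0 if the
peak spans the TSS; upstream/downstream determined by gene strand) and
`ℓ_up`, `ℓ_down` are per-gene decay lengths in bp. Counts are modeled as
Poisson with a log link and a library-size offset,
`E[y_c] = libsize_c · exp(α + β·RP_c)`. This is the simplest likelihood
consistent with correlating peak accessibility and expression; it also
matches the synthetic generator exactly, which keeps recovery
experiments interpretable.

Numerical choices:

* **Decay grid.** ℓ is fit by exhaustive search over a logarithmic grid,
  12 points from 500 bp to 100 kb per side (step ratio ≈ 1.62). A grid
  keeps the oracle exact (the arg-max can be verified by enumeration)
  and avoids non-convex continuous optimization. Ties break toward
  larger ℓ, i.e. the smoother model.
* **Peak–gene window.** ±100 kb from the TSS, configurable.
* **(α, β) fit.** Two-parameter Newton/IRLS on the standardized
  predictor, with step damping and a linear-predictor clip at ±30;
  log-likelihoods drop the `log(y!)` constant, so only differences are
  meaningful (all reported scores are differences). The implementation
  is cross-checked against statsmodels' Poisson GLM in the test-suite.
* **Degenerate genes.** All-zero accessibility yields an intercept-only
  model with β = 0 and a `degenerate` flag; ISD scores of degenerate
  models are 0.

## In-silico deletion (ISD)

The influence of a TF on a gene is the drop in RP-model log-likelihood
after deleting the model peaks that overlap (≥ 1 bp) the TF's binding
regions: `score = L_full − L_deleted`, where the deleted model refits
(α, β) only, with decay lengths frozen. Freezing ℓ keeps scores
comparable across TFs; deleting every peak reduces exactly to the
intercept-only refit (asserted to 1e-8 in the tests). Hard deletion with
refit is used rather than probabilistic masking. When a TF has several
binding sets, the maximum score per TF–gene pair is retained and the
arg-max set recorded as provenance.

## Base-GRN

The binary candidate network keeps the `round(q·n_TF·n_gene)` largest
ISD scores at the global (matrix-wide) quantile q = 0.05 — global rather
than per-TF because that is what makes 5% of a 50 × 4,306 score matrix
average ~215 targets per TF. Ties break deterministically (descending
score, then TF name, then gene name). Co-accessibility rescues apply
only to TFs absent from the ISD matrix, require score strictly > 0.8 and
are restricted to modeled genes. The 5% is interpreted as a fraction of
all pairs, not of nonzero pairs.

## State-specific GRNs

Per state, each gene with incoming candidate links is regressed on its
candidate TFs' expression (log1p counts scaled to the median library
size) using Bayesian ridge regression with hyperparameters set by
MacKay's evidence approximation; fixing the weight-precision
hyperparameter near zero recovers OLS (tested against the closed form),
and the adaptive fit is cross-checked against scikit-learn's
`BayesianRidge`. Edge p-values are two-sided normal tails of
|weight|/se, unadjusted. Selection is two-round: round 1 keeps up to
10,000 edges with p < 0.001 (p filter first, cap second; ranked by
ascending p, ties by descending |weight|, then lexically), round 2
refits each gene on its retained TFs and is marked final.

TF centrality per state is the principal eigenvector of the undirected
TF/gene graph weighted by |weight| (unsigned, so the Perron vector is
well-defined), computed by power iteration to 1e-10. Because the
TF→gene graph is bipartite-layered, iteration runs on A + I — the same
eigenvectors without the ±λ oscillation of bipartite spectra. The
vector is normalized to unit Euclidean norm over all nodes and TF rows
are reported; per-TF standardization across states feeds k-means
(default k = 6, 50 restarts, seeded).

## Knockout propagation and perturbation scoring

A TF knockout sets the TF coordinate to −x_tf per cell and propagates
through the state's TF→gene weight matrix for `n_steps = 3` steps
(primary/secondary/tertiary targets), clamping simulated expression at
zero after each step and holding the knocked-out TF at zero. Cells in
states without a fitted GRN keep ΔX = 0.

The gene-space shift is embedded in 2-D by a transition kernel over each
cell's k = 200 nearest embedding neighbors: softmax (temperature 0.05)
of the Pearson correlation between ΔX and each neighbor's expression
offset, minus the uniform-neighbor baseline. The differentiation flow
is the central-difference gradient of mean pseudotime on a 40 × 40 grid
over the embedding (one-sided differences at occupancy edges, Gaussian
smoothing with σ = 1 bin, empty-neighborhood bins get zero vectors).
Per-cell perturbation scores are raw (post-smoothing) dot products;
`delta_PS = net_GC − net_PB`, so knocking out a PB-promoting TF yields
delta_PS > 0.

## Clonal fate test

Clones with ≥ 2 cells are classified PB-only / GC-only / bifurcated.
Two null modes are provided because the procedure "shuffle clonotype
indices after fitting Poisson clone-size distributions" admits two
readings: the default `permutation` mode permutes fate labels over cells
(conditioning exactly on the observed clone-size multiset and marginal
fate counts), and `poisson` mode redraws clone sizes from Poisson fits
to the observed per-fate-class size distributions, assigns fates
i.i.d. and subsamples to the observed cell count. Deviations are scored
by z = (obs − sim mean)/sim sd with p = 2·(1 − Φ(|z|)) — the normal
approximation to the simulated null, not the empirical rank — and
replicate RNG streams are spawned from the seed. With the estimated null
sd, Var(z) ≈ 1 + 1/n_sim under the null, so type-I error at n_sim = 200
sits slightly above nominal (~0.053); the calibration experiment bounds
it within the exact binomial 95% interval of 0.05.

## Composite-element scanner

Exact IUPAC consensus matching (no PWM scores — the element definitions
are consensus strings): EICE `GGAANNGAAA`, ISRE `GAAANNGAAA`, AP1
`TGASTCA`, ETS `RGGAAR`, PRDM1 `GAAAGTGAAAGT`; AICE is an AP1 site and a
`GAAA` IRF half-site co-occurring with a 0–4 bp gap in either order
(both 0- and 4-bp-spaced AICEs are described in the literature);
PRDM1_IRF is a PRDM1 hit overlapping an ISRE hit. Both strands are
scanned, minus-strand hits are reported in plus-strand coordinates with
the motif-strand sequence, and all overlapping matches are reported.
The DEG concordance filter takes |FC| > 1.25 as strict and FDR ≤ 0.05
as inclusive, with FC interpreted on the linear scale
(|log2FC| > log2 1.25).

## Synthetic data: what it emulates

The generator plants a toggle architecture: pro-PB and pro-GC TFs
activate their own program's genes and repress the opposing program's
cCREs; housekeeping TFs and genes are constant. TF activities follow
4-parameter logistic profiles in pseudotime — shared mild induction on
the trunk, branch-specific rise/decay after the branch point (default
0.4). Accessibility counts are Poisson with log-rate
`basal + Σ_t strength·activity_t`; expression is Poisson with log-rate
`α_g + β_g·RP + log(libsize)` computed from the planted decay weights.
Counts are Poisson by default (matching the fitting likelihood) with an
optional gamma-mixed overdispersion switch. Clone sizes are
1 + Poisson(λ) — size ≥ 1 always, Poisson-shaped tail — with per-fate λ
defaults of 2.0 (PB) and 1.0 (GC), reflecting the larger division
number of the PB fate; these are free parameters, not calibrated to any
dataset. The 2-D embedding is analytic (pseudotime, signed branch
offset) plus Gaussian noise, giving a closed-form differentiation
gradient for oracle tests.

Two calibration details matter:

* **(α_g, β_g) are derived from the unperturbed network's expected
  accessibility rates** (including the counting-noise contribution to
  the RP dispersion), not from each simulated dataset's own moments.
  Otherwise a TF-knockout arm would re-standardize its shifted RP and
  erase the planted differential-expression signal between arms.
* **Decay-recovery experiments run without decoy peaks**
  (`n_decoy_peaks=0`): unbound decoys inside the gene window are not
  part of the planted RP model, so including them misspecifies the
  candidate family and biases ℓ downward. The default configuration
  keeps 20 decoys for all other experiments.

What the generator does **not** emulate: read-level artifacts, ambient
RNA/doublets, negative-binomial overdispersion by default, learned
manifolds, BCR sequence evolution, or batch effects. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated model, not robustness to real-data violations of it.

## Problem sizes

The test-suite and acceptance script use: 8 TFs × 30 genes × 1,000–2,000
cells for pipeline-level experiments; 20 simulations at n = 2,000 cells
for decay-length recovery (recovered within one grid step in ≥ 80% of
runs); three datasets at n = 2,000 for edge-sign recovery (≥ 80% of
planted edges with effect ≥ 0.5); 20 simulations at n = 1,000 for
knockout directionality (delta_PS sign correct in ≥ 90%); 500 runs × 200
null replicates for clonal-test calibration and 200 clones at full
concordance for power. The full suite runs in well under a minute of
compute per module on one CPU.

## Known limitations

* The ISD score of a TF bound only to far-distal cCREs is ~0 by
  construction — influence under the model, not binding, is scored.
* Decay lengths for genes whose cCREs all sit on one side of the TSS, or
  all far from it, are weakly identified; the recovery criterion is
  statistical (≥ 80% of seeds), not per-gene.
* Eigenvector centrality uses unsigned weights; activating and
  repressing hubs are not distinguished.
* The perturbation kernel (k, temperature, baseline subtraction) is
  plumbing with sensible defaults, exposed in the API; only the sign
  and relative magnitude of delta_PS are meaningful, not its units.
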