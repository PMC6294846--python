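# Methods

This note documents the statistical model behind each pipeline stage,
the simulation that the tests calibrate against, and the design choices
made where the analysis chain is genuinely underdetermined.

## Differential expression

Expression is assumed log2-scale and roughly Gaussian per gene. For each
gene the model is a two-group mean difference: `lfc_g` is the case-minus
control mean (orientation is taken from the design file's line order and
logged), and the pooled residual variance `s²_g` has `d = n₁ + n₂ − 2`
degrees of freedom. Gene-wise variances are shrunk toward a common prior
by treating them as draws from a scaled inverse chi-square with
parameters `(d₀, s₀²)`, estimated by moment matching on `log s²_g`: with
`e_g = log s²_g − ψ(d/2) + log(d/2)`, the model implies
`Var[e] = ψ′(d/2) + ψ′(d₀/2)` and a mean equation for `s₀²`, so `d₀`
solves `ψ′(d₀/2) = var(e) − ψ′(d/2)` (Newton iteration on the trigamma
inverse) and the moderated variance is `s̃²_g = (d₀s₀² + d·s²_g)/(d₀+d)`.
The moderated t is referred to `d + d₀` degrees of freedom. Three edge
cases: when the observed spread of log variances is no larger than
chi-square sampling noise, `d₀ = ∞` and every gene gets `s̃² = s₀²` with
a normal reference (this is the correct limit for homoskedastic data and
is what the homoskedastic simulation produces); with moderation disabled
(`moderated=False`) the statistic is exactly the textbook pooled t, which
is the oracle used in tests; a gene with zero residual variance and zero
fold change carries no evidence and gets p = 1, while a nonzero fold
change is still referred to the (positive) moderated variance.

Selection is strict on both criteria — `p < 0.02` and `|lfc| > 2` — so
boundary records are excluded. No multiple-testing correction is applied
by default because the screen is defined on raw p-values; `fit(fdr=True)`
switches selection to Benjamini–Hochberg q-values
(statsmodels' implementation).

## Co-expression network

The edge weight between two genes is the Spearman rank correlation
across all samples: Pearson correlation of mid-ranks, ties averaged
(computed with `scipy.stats.spearmanr`; a brute-force mid-rank oracle
checks it in the tests). Every unordered pair of selected DEGs becomes
an edge, giving a complete graph — `n(n−1)/2` edges — whose dense weight
matrix is what the voting stage consumes. A constant gene has undefined
rank correlations; its entries are set to 0 with a warning rather than
dropping the gene, keeping the matrix shape stable.

Thresholding for the high-confidence subnetwork uses `|SRCC| > cut`
(strict), keeping the signed weight on the edge: anti-correlation is
co-expression evidence, and discarding it would silently halve the
evidence on two-branch modules. `signed=True` restores the
positive-only reading. Nodes with no surviving edge are dropped from the
subnetwork. Degree rankings break ties by gene id ascending so hub lists
are deterministic.

## Annotations

Memberships are read from GAF 2.x (comment lines skipped, any `NOT`
qualifier excludes the line, duplicates collapse) or a two-column TSV,
then intersected with the chosen universe. The universe defaults to the
DEG network's node set, not the whole matrix, because both the voting
denominator and the in/out counts of the multifunctionality score are
defined over network neighbors; `universe="matrix"` switches to the full
gene list. The term filter keeps terms with strictly more than
`min_genes` (default 20) universe genes and is idempotent. Ontology
ancestor propagation (is_a / part_of, via obonet) is available but off
by default — it changes term sizes and hence the filter, so it is a
deliberate modelling decision rather than silent preprocessing.

## Neighbor voting, cross-validation, AUC

Voting scores are computed densely: `score(i,K)` is the |SRCC|-weighted
fraction of visible genes annotated to K among all visible genes
`j ≠ i`. Using the full weight matrix rather than a thresholded edge
set is what propagates indirect (weak, many-path) co-expression
evidence; `restrict_to_edges=True` confines voting to an explicit edge
set when a thresholded subnetwork is the object of interest. A gene with
zero total weight to visible genes falls back to the term prior
(visible in-count / visible count). Scores are in [0,1].

Cross-validation partitions *genes* (not gene–term pairs) into
near-equal seeded folds; all terms are evaluated on the same folds so
their AUCs are comparable. In each fold the held-out genes' annotations
are hidden, every gene is rescored from the visible labels, and each
term gets the ROC AUC of held-out members vs held-out non-members. AUC
is computed by the tie-corrected Mann–Whitney rank formula and equals
exhaustive pair counting exactly. Terms with fewer positives than folds
are skipped; a fold where a term lacks one of the two classes is
recorded as missing and excluded from that term's mean, and the output
carries `n_folds_used` so such terms are visible. A term's mean AUC is
the arithmetic mean of its defined fold AUCs, and "optimal functions"
are terms with mean AUC strictly above 0.7.

The per-gene multifunctionality score `MF_i = Σ_{K∋i} 1/(in_K · out_K)`
is a pure function of annotation structure. The summation runs over the
terms containing gene i — the only reading under which MF is a per-gene
quantity and can rank genes. Two roles: (a) the MF profile is reported
with the results; (b) the MF ranking — one gene ordering applied to
every term — is evaluated through the same folds as a baseline
predictor, so terms whose apparent performance is explained by
annotation bias rather than network structure are identifiable
(`mf_auc` next to `mean_auc`). The baseline is computed once from the
full annotation set: a held-out gene's MF is undefined without its own
annotations, so the MF column is a bias diagnostic, not a leakage-free
predictor; the voting scores themselves never see a held-out gene's
annotations (a dedicated test alters a held-out gene's annotations and
asserts its fold scores are unchanged). An optional combined predictor
(mean of the two within-fold rank positions) is available behind
`combined=True`.

## Synthetic data

The generator emulates the motivating study design: two arms of 8
samples, a few thousand genes (scaled down to hundreds for routine
runs), planted DE effects beyond the |log2FC| > 2 screen, correlated
modules, and GO terms partially coherent with those modules. For gene
*g* in sample *s*

    x[g,s] = μ_g + δ_g·1[case] + σ·(√ρ·f[m(g),s] + √(1−ρ)·ε[g,s])

with baseline `μ_g ~ N(7, 1.5²)` (a log2 microarray-intensity scale),
noise σ (`noise_sd`, default 1), one standard-normal factor `f` per
module giving exact population within-module correlation ρ
(`module_rho`), and `δ_g = ±de_lfc_mean` for planted DE genes (default
3, i.e. comfortably beyond the screen at n = 8 per arm: the mean
difference has SE `σ√(2/8) = 0.5`). Non-module genes are independent.

DE *status* is planted uniformly at random, independent of module
membership. DE *direction* is shared within a module by default
(`de_sign_by_module=True`): a co-regulated module is modelled as
responding to disease coherently. This matters quantitatively — the
group shift itself induces cross-group correlation ≈ δ²/4 / (δ²/4 + σ²)
between any two same-direction DE genes (≈ 0.69 at δ = 3, σ = 1); with
random within-module signs, half the module pairs would anti-correlate
at a *weaker* magnitude (|−δ²/4 + ρσ²|/(δ²/4 + σ²)) than that background
and module structure would be unrecoverable from |SRCC| by construction.
With coherent signs, within-module pairs sit at (δ²/4 + ρσ²)/(δ²/4 + σ²)
— above the background for any ρ > 0 — which is the regime the network
and voting stages are designed for.

Coherent terms are assigned to modules round-robin; a fraction
`term_coherence` of each such term's members is drawn from its module
and the rest uniformly; incoherent terms are uniform. Term sizes are
uniform integers in `[min_term_size, max_term_size]`. All randomness
flows from one master seed through named substreams (expression, DE
assignment, annotations, CV), so changing the annotation settings never
perturbs the expression draw; the substream ids are recorded in the run
manifest.

What the simulation does *not* model: probe-level artifacts,
normalization, mean–variance trends, heavy-tailed noise, overlapping or
hierarchical modules, and the GO DAG (terms are flat sets). Passing
tests therefore demonstrate that the chain recovers the signal it is
specified to recover under a clean factor model — not that any
particular real dataset carries such signal.

## Calibration benchmarks and problem sizes

`netgba.benchmarks` fixes two end-to-end study conditions at 500 genes,
8 + 8 samples, 10 modules of 25 genes, terms of 25 genes:

* moderate signal (ρ = 0.7, coherence 0.5, 20 terms): summary is the
  mean cross-validated AUC over retained terms, which a working
  predictor holds at or above chance (0.5); observed ≈ 0.71–0.73 across
  seeds.
* strong signal (ρ = 0.9, coherence 0.9, 10 coherent terms): summary is
  the *minimum* mean AUC over planted coherent terms, which must clear
  the 0.7 optimal-function screen; observed ≈ 0.86–0.91 across seeds.

Both conditions plant DE effects in every gene. This is deliberate: the
evaluation universe is the post-screen DEG network, and a term can only
be retained if more than 20 of its members survive the screen, so the
benchmark mirrors an analysis in which the GO evaluation operates on the
DEG set, exactly as the screening chain prescribes. The 500-gene scale
keeps a full pipeline run under a few seconds while leaving every stage
non-trivial (≈490-node complete network, ≈120k edges).

The null-calibration suite uses incoherent terms (memberships
independent of modules) and a label permutation of the gene universe:
term sizes and the bipartite degree sequence are preserved while any
relation to expression is destroyed. Incoherent terms are near-disjoint,
so their null AUCs are close to independent and the per-run mean across
15 terms of 30 genes on a 150-gene network (≥ 1200 evaluable pairs per
term) concentrates tightly around 0.5.

## Known limitations

* The moderated test assumes equal group variances and a common prior
  across genes; strong mean–variance dependence would call for a trend
  term that is not implemented.
* AUC evaluation treats GO terms as independent flat gene sets; related
  terms share members and their AUCs are correlated.
* The MF baseline is a diagnostic, not a leakage-free predictor (above).
* With 16 samples, Spearman estimates carry sampling error ≈ 0.15 near
  zero correlation; the 0.8 subnetwork threshold is conservative but
  individual weak edges are noisy.
* The dense-voting formulation is O(n²) in network genes per fold; it is
  comfortable at the hundreds-of-DEGs scale it targets, not at
  whole-transcriptome scale.
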