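# netgba

Network-based guilt-by-association (GBA) prediction of gene function from
small two-group expression studies.

Small case/control expression experiments — the motivating design is a
placental study of early-onset preeclampsia (EOPE) with 8 cases and 8
gestational-age-matched controls — yield a shortlist of differentially
expressed genes (DEGs) but say nothing directly about what those genes
*do*. `netgba` implements the standard inference chain that turns such a
shortlist into ranked functional hypotheses, and evaluates how far each
Gene Ontology (GO) term can actually be predicted from co-expression:

1. **DEG screen** — a gene-wise two-group linear model with
   empirical-Bayes variance moderation. The moderated statistic is
   `t_g = lfc_g / (s̃_g √(1/n₁ + 1/n₂))` with
   `s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d)`, where the prior `(d₀, s₀²)` is
   estimated by moment matching on the log variances. Genes with
   `p < 0.02` and `|log2FC| > 2` (both strict) are the DEGs.
2. **Co-expression network** — every DEG pair gets an edge weighted by
   the Spearman rank correlation (SRCC) of their expression across all
   samples, so `n` DEGs give a complete graph with `n(n−1)/2` edges
   (81 DEGs → 3240 edges). A subnetwork keeps edges with `|SRCC| > 0.8`.
3. **Annotation filter** — gene↔GO memberships (GAF 2.x or two-column
   TSV) are restricted to the network genes; only terms annotating
   strictly more than 20 of them are evaluated.
4. **Neighbor voting with cross-validated AUC** — a gene's score for
   term K is the weight-normalized vote of its annotated neighbors,
   `score(i,K) = Σ_j |w_ij|·1[j∈K] / Σ_j |w_ij|` over visible genes
   `j ≠ i`. Genes are split into 3 folds; each fold's annotations are
   hidden in turn and the held-out genes are scored from the rest. Each
   term receives the Mann–Whitney ROC AUC of held-out members vs
   non-members, averaged over folds. Per-gene annotation bias is
   summarised by the multifunctionality score
   `MF_i = Σ_{K∋i} 1/(Num_in_K · Num_out_K)` and the MF ranking is
   evaluated alongside as a network-free baseline.
5. **Optimal functions** — terms with mean cross-validated AUC strictly
   above 0.7.

A synthetic-data module generates matched expression matrices and GO
annotations with planted DE genes, correlated modules and
module-coherent terms, so the whole chain is testable and calibratable
with no external data.

## Worked example

```python
import netgba as ng

cfg = ng.SimulationConfig(
    n_genes=500, n_per_group=8, n_de_genes=500, de_lfc_mean=3.0,
    n_modules=10, module_size=25, module_rho=0.9, noise_sd=1.0,
    n_terms=10, term_coherence=0.9, min_term_size=25, max_term_size=25,
    seed=1,
)
matrix, truth = ng.generate_expression(cfg)
ann, truth = ng.generate_annotations(truth, cfg)

deg = ng.DifferentialExpression(matrix).fit(p_threshold=0.02, lfc_threshold=2.0)
net = ng.build_network(ng.spearman_matrix(matrix, deg.deg_ids))
retained = ng.filter_terms(ann.restrict(deg.deg_ids), min_genes=20)
res = ng.NeighborVoting(net, retained).fit(n_folds=3, seed=1, auc_threshold=0.7)
print(res.summary())
```

which prints

```
Guilt-by-association function prediction
================================================
network genes       489
terms evaluated     10
cross-validation    3-fold, seed 1
mean AUC (voting)   0.936
mean AUC (MF only)  0.780
optimal functions   10 (mean AUC > 0.7)

      term              name  in_count  mean_auc   mf_auc
GO:0000009  synthetic term 9        25  0.986469 0.747928
GO:0000004  synthetic term 4        25  0.960357 0.779705
...
GO:0000001  synthetic term 1        25  0.858200 0.737965
```

489 of the 500 genes pass the DEG screen (planted effects of |log2FC| = 3
against unit noise), forming a complete 489-node network with 119,316
weighted edges. All 10 planted module-coherent terms are learnable from
co-expression alone: their cross-validated voting AUCs range from 0.86
to 0.99, every one clears the 0.7 screen, and the voting predictor beats
the multifunctionality baseline (0.936 vs 0.780 mean AUC), i.e. the
signal is network structure, not annotation bias.

The same analysis is available from the shell:

```bash
netgba simulate --outdir data --n-de-genes 500 --module-rho 0.9 --term-coherence 0.9
netgba run --config pipeline.yaml        # or: netgba degs / network / predict
```

Each stage writes plain TSV/GraphML outputs (Cytoscape-importable edge
lists, the SRCC matrix, per-term performance, AUC histogram data) plus a
`manifest.json` capturing config, seed substreams and stage counts;
identical config + seed reproduce the outputs byte for byte.

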