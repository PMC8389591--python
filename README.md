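# survmod

Survival-weighted differential co-expression network analysis: module
discovery and hub-gene selection on protein–protein interaction (PPI)
scaffolds.

## The problem

In tumor cohorts with follow-up data (e.g. oral squamous cell carcinoma
cohorts with RNA-seq and clinical survival), gene pairs whose
*co-expression* differs between shorter- and longer-surviving patients
carry prognostic information that per-gene differential expression
misses. `survmod` turns an unweighted PPI scaffold into a
survival-weighted network, finds densely differential gene modules in
it, screens each module's summary expression against survival, and
nominates hub genes — the workflow a systems-biology group would run on
a TCGA-style cohort, here packaged so every stage is testable against
planted ground truth.

## The method

Given a genes × samples log2 expression matrix, a survival table
(time, event) and a scaffold edge list, the pipeline runs five stages:

1. **Differential expression.** Duplicate gene rows are averaged; an
   empirical-Bayes moderated two-sample *t* (per-gene variances shrunk
   toward a moment-matched scaled-F prior) with Benjamini–Hochberg
   control calls DEGs at |log2FC| > 2, adjusted p < 0.05; the scaffold
   is restricted to DEGs.
2. **Edge weighting.** Tumor samples are split 60/40 into train/test;
   each partition is stratified at the median follow-up time into
   shorter/longer survivors. Every scaffold edge (x, y) gets

   D_xy = |Z(r_L) − Z(r_S)| / √( 1/(n_L−3) + 1/(n_S−3) ),

   where r_L, r_S are Pearson correlations of x and y across the
   longer/shorter strata and Z(r) = ½ ln((1+r)/(1−r)) is Fisher's
   transformation. Under equal population correlations D is
   asymptotically |N(0,1)|, so large D flags survival-linked
   co-expression changes.
3. **Overlapping module detection.** Seed-expansion community detection
   on the weighted network: the heaviest unvisited edge seeds a
   community, neighbors with ≥ 2 members in their neighborhood join
   while they increase the weighted fitness W_in/(W_in+W_out), members
   whose removal raises fitness are pruned, and nodes may belong to
   several modules. Modules with more than five nodes are kept.
4. **Module survival screening.** Each module's eigengene (ME) — the
   first right-singular vector of its row-standardised expression — is
   median-split; the two groups are compared with Kaplan–Meier curves
   and the log-rank test (z, χ² = z², two-sided p, per-group hazard
   rates, O/E hazard ratio with 95% CI), separately on the training and
   test partitions. A module counts as survival-associated when
   p < 0.05 in **both**.
5. **Hub selection.** Genes of the selected module are ranked by
   weighted degree and eigenvector centrality; module genes are tested
   for over-representation against a local GMT collection
   (hypergeometric tail + BH); the two top-10 centrality sets, the
   significant-pathway genes and an external DEG list are intersected
   into the final hub set, whose pairwise Spearman correlations are
   reported.

A first-class synthetic generator plants all of this structure — a
planted-partition scaffold, one-factor Gaussian co-expression whose
strength differs by a latent survival class in one module, exponential
survival whose hazard follows that module's eigengene, and exponential
censoring — so recovery is checkable end to end.

## Worked example

```bash
survmod simulate --outdir sim --seed 3
cat > run.yaml <<EOF
expr: sim/expression.tsv
surv: sim/survival.tsv
edges: sim/scaffold_edges.tsv
classes: sim/sample_classes.tsv
gmt: sim/gene_sets.gmt
degs: sim/external_degs.tsv
outdir: out
seed: 3
EOF
survmod run --config run.yaml
```

The run prints the per-stage manifest (abridged):

```
"de":               {"n_up": 50, "n_down": 50}
"weighting":        {"n_nodes": 100, "n_edges": 306, "n_train": 120, "n_test": 80}
"module_detection": {"n_modules": 44, "n_modules_filtered": 15}
"module_survival":  {"n_significant_both": 3, "selected_module": 24}
"hub_selection":    {"n_hubs": 10, "hubs": ["G0001", ..., "G0010"]}
```

All 100 planted DE genes are recalled (50 up, 50 down), the weighted
training network keeps 306 edges among them, and of the 15 filtered
modules three are log-rank significant in both partitions. The selected
module (13 genes, 48 edges) contains the entire planted survival module
G0001–G0010 and scores z = 3.63, p = 2.8e−4, HR = 2.02 in training and
z = 4.85, p = 1.0e−6, HR = 3.06 in test (`out/module_survival.tsv`);
the hub set recovers the planted top-degree gene G0006. High-ME samples
die faster because the generator ties the hazard to the planted
eigengene — exactly what the screen is built to detect.

Every stage is also available as a standalone subcommand
(`simulate`, `de`, `weight`, `modules`, `survival`, `hubs`,
`validate`) and as plain library functions (`survmod.run_analysis`
works on in-memory frames and graphs).

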