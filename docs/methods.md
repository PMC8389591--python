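# Methods

## Model and procedure

`survmod` implements a five-stage survival-guided network analysis.
The statistical core is the differential co-expression edge statistic

    D_xy = |Z(r_L) − Z(r_S)| / sqrt(1/(n_L − 3) + 1/(n_S − 3)),

with Z(r) = arctanh(r). For bivariate-normal expression and equal
population correlation in both survival strata, Z(r̂) is approximately
normal with variance 1/(n − 3), so D is asymptotically |N(0,1)|; the
package's calibration benchmark verifies the 5% exceedance of 1.96 at
ρ ∈ {0, 0.3, 0.6}. The statistic is symmetric in the two strata and
scales as √n for fixed correlations.

Module survival screening summarises a module by its eigengene: gene
rows are standardised to zero mean and unit variance across samples,
and the ME is the first right-singular vector of that matrix (unit
norm; automatically zero-mean because every standardised row is).
`variance_explained` is σ₁²/Σσ². The sign is fixed by positive
correlation with the module's mean standardised expression, and the
reported `sign_anchor` is the gene with the largest loading. Samples
are split at the ME median (the median value itself goes to the high
group — a deterministic tie rule), and the groups are compared with the
product-limit estimator and the standard two-group log-rank test.

The log-rank report mirrors the schema of survival tables in this
literature: per-group hazard rate (events per unit person-time), the
O/E hazard ratio (O_high/E_high)/(O_low/E_low) with CI
exp(log HR ± 1.96·√(1/E_high + 1/E_low)), the signed z with χ² = z²,
and the two-tailed normal p. The O/E form was chosen because it shares
its ingredients with the log-rank z that is reported next to it; a Cox
HR would be a drop-in alternative but introduces a second model.
A module is survival-associated when p < α (default 0.05) in the
training *and* the test partition; per-module statistics are always
emitted so a user can apply a different α after the fact.

## Module detection

The overlapping community detector is a deterministic seed-expansion
scheme on the D-weighted network: edges sorted by descending weight
(lexicographic tie-break); the heaviest edge not yet inside a found
community seeds a new one; boundary nodes join greedily by the largest
positive gain of f(C) = W_in/(W_in + W_out)^α (α = 1 by default), where
W_in sums internal and W_out boundary edge weights; after expansion,
members whose removal raises f are pruned, and the add/prune cycle
repeats until f is a local maximum under single-node moves. Nodes may
join multiple communities, so overlap emerges naturally; duplicate
communities are collapsed and communities below the size filter
(default: strictly more than five nodes; an edge-count variant is a
config switch) are dropped.

Two details matter numerically. First, past the two-node seed a
candidate must have at least two neighbors inside the community.
Without this, any pendant node trivially increases the ratio fitness
(its outside weight is zero), and detected modules absorb single-edge
attachments; requiring two-member neighborhood support is the concrete
form of "neighborhood proximity" used for admission. Second, ties in
fitness gain are broken by the node-pair proximity score
P(u,v) = (w(u,v) + Σ_{c∈N(u)∩N(v)} min(w(u,c), w(v,c))) / min(s(u), s(v))
and then by gene name, keeping the output invariant to edge insertion
order.

## Differential expression

DE calling uses the empirical-Bayes moderated t: per-gene pooled
variances s²_g on d = n_t + n_n − 2 df are shrunk toward a prior
s̃² = (d₀s₀² + d s²)/(d₀ + d), with (d₀, s₀²) fitted by moment-matching
log s²_g under the scaled-F model (digamma/trigamma identities; the
trigamma equation is inverted by Newton iteration). When the empirical
log-variance spread does not exceed the χ² sampling spread, d₀ = ∞ and
all variances shrink to s₀². Zero-variance genes are flagged and
assigned p = 1 rather than dropped. DEG thresholds are strict
inequalities: |log2FC| > 2 and BH-adjusted p < 0.05. The implementation
agrees with Bioconductor limma's lmFit/eBayes to ~1e−13 on a frozen
fixture. Upstream count normalisation (VST, batch correction) is out of
scope by contract: inputs are already log2-normalised.

## Synthetic data generator

The generator emulates the statistical regime the pipeline assumes:

- **Scaffold**: planted-partition graph; same-module pairs connect with
  p_in = 0.9, all other pairs with p_out = 0.02 — a dense-module,
  sparse-background regime representative of a high-confidence
  interaction network. Defaults: 120 genes, five planted modules of 10.
- **Expression**: one-factor Gaussian model,
  gene_i = √r·f + √(1−r)·ε_i, giving exact pairwise population
  correlation r between module genes. The first planted module is
  survival-linked: its latent factor is the planted ME, samples at or
  above the ME median form the latent short-survival class, and r is
  r_short = 0.1 there versus r_long = 0.8 in the long class. Because
  thresholding shrinks the factor's within-class variance (which would
  dilute the realised correlation), the factor is re-standardised
  within each class with class means preserved, so within-class
  pairwise correlation converges exactly to the planted r. Other
  planted modules use r_long in both classes: co-expressed but not
  differentially, so only the survival-linked module carries edge
  signal. Background genes are i.i.d. N(0,1).
- **Differential expression**: all planted-module genes are shifted up
  by de_lfc = 3 in tumors and an equally sized random background set
  down, exercising both DEG lists; 30 normal samples by default.
- **Survival**: exponential death times with hazard
  baseline_hazard·exp(hazard_coef·ME) (defaults 0.1 and 1.0),
  independent exponential censoring at rate 0.02, event = death before
  censoring. Time units are abstract.

What it does **not** emulate: negative-binomial count noise, batch
effects, copy-number structure, informative or administrative
censoring, and overlapping planted modules. Passing recovery tests
therefore demonstrates correctness of the machinery under the model's
own assumptions, not robustness to real RNA-seq artefacts.

## Numerical choices and degenerate inputs

- Correlations are clamped to ±(1 − 1e−12) before Fisher Z; edges
  touching a zero-variance gene in a stratum are dropped with a
  warning rather than imputed.
- The survival stratifier defaults to a median split on observed
  follow-up time, ignoring event status (parameter-free and always
  defined); an event-aware variant (`median_event_time`) is a config
  option. Groups below 4 samples raise, since Fisher's variance
  1/(n − 3) degenerates.
- The train fraction is free (default 0.6) and |train| = round(f·n)
  half-up, so a 352-sample cohort at f = 0.619 gives 218.
- Eigenvector centrality runs power iteration to 1e−10 on the weighted
  adjacency plus a positive spectral shift (bipartite-safe); on a
  disconnected module it is computed on the largest component.
- One global seed drives everything; per-stage seeds derive from it by
  CRC32 of the stage name, so stages can be rerun in isolation and two
  identical runs give byte-identical tables.

## Benchmark problem sizes

The property benchmarks run at desk scale, chosen to keep the full
suite interactive while leaving comfortable statistical margins: 10,000
simulated edges per ρ for null calibration; 500 random datasets for the
survival oracles; 100 random matrices for the eigengene oracle; 20 full
pipeline runs (200 tumor + 30 normal samples, 120 genes) for planted
recovery; 200 reduced replicates (100 tumor samples, 50 genes, five
8-gene modules, modules with ≥ 3 nodes evaluated) for the α² null
false-positive control.

## Known limitations

- The overlapping detector is a documented stand-in with the stated
  properties (weighted, overlapping, proximity-driven); it is not a
  reimplementation of any specific published algorithm, and its
  admission rule (two-member support) means it cannot attach
  single-edge satellites even when they truly belong.
- The O/E hazard ratio is biased toward 1 relative to a Cox estimate
  when hazards are strongly non-proportional.
- Eigengene orientation by mean-expression correlation can flip for
  modules containing balanced anti-correlated halves; the anchor gene
  is reported so the orientation is auditable.
- With 200 tumor samples the observed-time median split agrees with
  the latent survival class only ~80% of the time (exponential noise),
  which attenuates realised edge weights relative to the planted
  correlations; the recovery benchmarks already include this
  attenuation.
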