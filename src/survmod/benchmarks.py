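"""Reproducible property benchmarks of the whole pipeline.

Each function re-runs part or all of the analysis on freshly generated
synthetic data and returns summary numbers: the null calibration of the
differential co-expression statistic, planted-module recovery and hub
recovery rates, and the null false-positive control of the two-partition
survival screen.  These power the reproducibility script and the
corresponding tests.
"""

from __future__ import annotations

import numpy as np

from .modules import best_match_jaccard, detect_modules, filter_modules
from .pipeline import PipelineConfig, run_analysis
from .survival import evaluate_modules
from .synthetic import SyntheticDesign, gene_sets_for_truth, generate_study
from .weighting import fisher_z, split_train_test, stratify_survival, weight_network


def d_null_calibration(
    rhos=(0.0, 0.3, 0.6),
    n_per_group: int = 100,
    n_edges: int = 10_000,
    seed: int = 0,
) -> dict[float, float]:
    """Fraction of null edges with D > 1.96 per common correlation rho.

    Both survival groups share the population correlation, so D should be
    asymptotically |N(0, 1)| and the exceedance rate ~5%.
    """
    rng = np.random.default_rng(seed)
    n = n_per_group

    def _corr(a, b):
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
        return (a * b).sum(1) / np.sqrt((a * a).sum(1) * (b * b).sum(1))

    rates = {}
    se = np.sqrt(2.0 / (n - 3))
    for rho in rhos:
        x_l = rng.standard_normal((n_edges, n))
        y_l = rho * x_l + np.sqrt(1 - rho**2) * rng.standard_normal((n_edges, n))
        x_s = rng.standard_normal((n_edges, n))
        y_s = rho * x_s + np.sqrt(1 - rho**2) * rng.standard_normal((n_edges, n))
        D = np.abs(fisher_z(_corr(x_l, y_l)) - fisher_z(_corr(x_s, y_s))) / se
        rates[rho] = float((D > 1.96).mean())
    return rates


def planted_recovery(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Full-pipeline recovery of the planted survival module.

    Runs the default design (5 planted modules of 10 genes, differential
    co-expression 0.8 vs 0.1 in the survival-linked one, hazard
    coefficient 1, 200 tumor samples) once per seed and counts: seeds
    where the module is log-rank significant in both partitions, seeds
    where the planted top-degree gene lands in the final hub set, and the
    best-match Jaccard between detected and planted module.
    """
    sig = hub = 0
    jaccards = []
    for k in range(n_seeds):
        seed = base_seed + k
        design = SyntheticDesign(seed=seed)
        scaffold, expr, classes, surv, truth = generate_study(design)
        gmt = gene_sets_for_truth(truth, list(expr.index), seed=seed)
        result = run_analysis(
            scaffold, expr, classes, surv, gmt, list(truth.de_genes),
            PipelineConfig(seed=seed),
        )
        planted = set(truth.module_genes(truth.survival_module_id))
        jaccards.append(best_match_jaccard(result.modules_filtered, planted))
        sig += result.selected_module is not None
        hub += truth.expected_hub in result.hub_set
    return {
        "n_seeds": n_seeds,
        "significant_both": sig,
        "hub_recovered": hub,
        "jaccards": jaccards,
        "mean_jaccard": float(np.mean(jaccards)),
        "n_jaccard_ge_08": int(sum(j >= 0.8 for j in jaccards)),
    }


def null_false_positive_control(
    n_reps: int = 200,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> dict:
    """Two-partition survival screen under the null (hazard_coef = 0).

    Per replicate: generate a reduced design with no survival signal,
    weight the scaffold on the training stratification, detect modules
    (>= 3 nodes evaluated so each replicate contributes several tests),
    and screen them in both partitions.  The expected number of modules
    significant in both is alpha^2 per module tested.
    """
    total_sig = total_modules = 0
    for k in range(n_reps):
        seed = base_seed + k
        design = SyntheticDesign(
            n_genes=50,
            n_tumor=100,
            n_normal=0,
            module_sizes=(8, 8, 8, 8, 8),
            hazard_coef=0.0,
            seed=seed,
        )
        scaffold, expr, classes, surv, _ = generate_study(design)
        surv_idx = surv.set_index("sample_id")
        tumor = [s for s in expr.columns if classes.get(s) == "tumor"]
        train, test = split_train_test(tumor, 0.6, seed)
        weighted = weight_network(scaffold, expr, stratify_survival(surv_idx, train))
        mods = filter_modules(detect_modules(weighted), min_nodes=3)
        report = evaluate_modules(
            mods, expr.loc[:, train], surv_idx.loc[train],
            expr.loc[:, test], surv_idx.loc[test], alpha,
        )
        total_modules += len(report)
        total_sig += int(report["significant_both"].sum()) if len(report) else 0
    expected = total_modules * alpha**2
    se = float(np.sqrt(total_modules * alpha**2 * (1 - alpha**2)))
    return {
        "n_reps": n_reps,
        "n_module_tests": total_modules,
        "observed_significant_both": total_sig,
        "expected_significant_both": expected,
        "se": se,
    }
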