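"""Synthetic benchmark generator with planted, verifiable structure.

Emulates the data regime the pipeline targets: a modular protein-
interaction scaffold (planted-partition graph), a log2 expression matrix
whose within-module co-expression differs between latent short- and
long-survival tumor samples, and exponential survival times whose hazard
is tied to the survival-linked module's latent eigengene.

Construction, per tumor sample j and planted module m:

    gene_i = sqrt(r) * f_mj + sqrt(1 - r) * eps_ij

with f_mj, eps_ij iid standard normal, giving exact pairwise population
correlation r between module genes.  The survival-linked module's factor
f is the planted module eigengene (ME): samples above its median form the
latent short-survival class, below it the long-survival class, and the
class selects r (r_short vs r_long) for that module.  Other planted
modules use r_long in both classes, so only the survival-linked module is
differentially co-expressed.  Death times are Exp(baseline_hazard *
exp(hazard_coef * ME)); censoring is an independent Exp(censor_rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of one simulated study.

    Sizes default to a desk-scale version of a tumor cohort with a
    high-confidence interaction scaffold: dense planted modules
    (p_in=0.9) on a sparse background (p_out=0.02), strong differential
    co-expression (0.8 vs 0.1) in the survival-linked module, a log2
    fold-change of 3 for DE genes, and mild exponential censoring.
    """

    n_genes: int = 120
    n_tumor: int = 200
    n_normal: int = 30
    module_sizes: tuple[int, ...] = (10, 10, 10, 10, 10)
    p_in: float = 0.9
    p_out: float = 0.02
    r_long: float = 0.8
    r_short: float = 0.1
    de_lfc: float = 3.0
    hazard_coef: float = 1.0
    baseline_hazard: float = 0.1
    censor_rate: float = 0.02
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes: total planted genes exceed n_genes")
        if any(m < 3 for m in self.module_sizes):
            raise ValueError("module_sizes: every planted module needs >= 3 genes")
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out <= p_in <= 1")
        if self.n_tumor < 10:
            raise ValueError("n_tumor must be >= 10")
        if self.n_normal < 0:
            raise ValueError("n_normal must be >= 0")
        for name in ("r_long", "r_short"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if not np.isfinite(self.hazard_coef):
            raise ValueError("hazard_coef must be finite")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: what a correct analysis should recover."""

    module_assignment: dict[str, int]
    survival_module_id: int
    de_genes: tuple[str, ...]
    expected_hub: str | None = None
    latent_me: dict[str, float] | None = None
    survival_class: dict[str, str] | None = None

    def module_genes(self, module_id: int) -> list[str]:
        return sorted(g for g, m in self.module_assignment.items() if m == module_id)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_scaffold(design: SyntheticDesign) -> tuple[nx.Graph, GroundTruth]:
    """Planted-partition scaffold graph.

    Same-module gene pairs are connected with probability p_in, all other
    pairs with p_out.  Deterministic given ``design.seed``.  The returned
    ground truth names the survival-linked module (the first one) and its
    highest-degree member as the expected hub.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    genes = _gene_names(design.n_genes)
    assignment: dict[str, int] = {}
    pos = 0
    for mid, size in enumerate(design.module_sizes, start=1):
        for g in genes[pos : pos + size]:
            assignment[g] = mid
        pos += size

    G = nx.Graph()
    G.add_nodes_from(genes)
    n = len(genes)
    # vectorised Bernoulli draw over the upper triangle
    iu, ju = np.triu_indices(n, k=1)
    mids = np.array([assignment.get(g, 0) for g in genes])
    same = (mids[iu] == mids[ju]) & (mids[iu] > 0)
    prob = np.where(same, design.p_in, design.p_out)
    keep = rng.random(prob.size) < prob
    G.add_edges_from((genes[i], genes[j]) for i, j in zip(iu[keep], ju[keep]))

    surv_mid = 1
    surv_genes = [g for g, m in assignment.items() if m == surv_mid]
    hub = max(sorted(surv_genes), key=lambda g: G.degree(g)) if surv_genes else None
    truth = GroundTruth(
        module_assignment=assignment,
        survival_module_id=surv_mid,
        de_genes=(),
        expected_hub=hub,
    )
    return G, truth


def generate_dataset(
    design: SyntheticDesign,
    scaffold: nx.Graph,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, GroundTruth]:
    """Expression matrix, sample classes and survival table for a scaffold.

    Returns ``(expr, sample_class, survival, truth)`` where ``expr`` is
    genes x samples (log2 scale), ``sample_class`` maps samples to
    tumor/normal and ``survival`` has columns sample_id/time/event for the
    tumor samples.  DE genes are every planted-module gene (shifted up by
    ``de_lfc`` in tumors) plus an equally sized random background set
    shifted down.
    """
    design.validate()
    rng = np.random.default_rng(design.seed + 1)
    genes = list(scaffold.nodes)
    n_genes = len(genes)
    tumor_ids = [f"T{i:04d}" for i in range(1, design.n_tumor + 1)]
    normal_ids = [f"N{i:04d}" for i in range(1, design.n_normal + 1)]

    assignment = truth.module_assignment
    surv_mid = truth.survival_module_id

    # latent module factors for tumor samples; module `surv_mid`'s factor is the planted ME
    factors = {mid: rng.standard_normal(design.n_tumor) for mid in range(1, design.n_modules + 1)}
    me = factors[surv_mid]
    short_class = me >= np.median(me)  # high ME -> higher hazard -> short survival

    # Thresholding shrinks the factor's variance within each class, which
    # would dilute the planted correlation; re-standardise the factor per
    # class (keeping class means) so within-class pairwise correlation is
    # exactly r_short / r_long.  The hazard below still uses the raw ME.
    me_std = me.copy()
    for mask in (short_class, ~short_class):
        mu, sd = me[mask].mean(), me[mask].std()
        me_std[mask] = mu + (me[mask] - mu) / sd
    factors = dict(factors)
    factors[surv_mid] = me_std

    gene_index = {g: i for i, g in enumerate(genes)}
    X_tumor = rng.standard_normal((n_genes, design.n_tumor))
    for g, mid in assignment.items():
        i = gene_index[g]
        f = factors[mid]
        eps = X_tumor[i].copy()
        if mid == surv_mid:
            r = np.where(short_class, design.r_short, design.r_long)
        else:
            r = np.full(design.n_tumor, design.r_long)
        X_tumor[i] = np.sqrt(r) * f + np.sqrt(1.0 - r) * eps

    X_normal = rng.standard_normal((n_genes, design.n_normal))

    # differential expression: module genes up, matched background set down
    module_genes = sorted(assignment)
    background = [g for g in genes if g not in assignment]
    n_down = min(len(module_genes), len(background))
    down_genes = sorted(rng.choice(background, size=n_down, replace=False)) if n_down else []
    for g in module_genes:
        X_tumor[gene_index[g]] += design.de_lfc
    for g in down_genes:
        X_tumor[gene_index[g]] -= design.de_lfc

    expr = pd.DataFrame(
        np.hstack([X_tumor, X_normal]) if design.n_normal else X_tumor,
        index=pd.Index(genes, name="gene"),
        columns=tumor_ids + normal_ids,
    )
    sample_class = pd.Series(
        ["tumor"] * design.n_tumor + ["normal"] * design.n_normal,
        index=tumor_ids + normal_ids,
        name="class",
    )

    # exponential survival: hazard_i = baseline * exp(hazard_coef * ME_i)
    hazard = design.baseline_hazard * np.exp(design.hazard_coef * me)
    if not np.all(np.isfinite(hazard)) or np.any(hazard <= 0):
        raise ValueError("hazard_coef/baseline_hazard produce non-finite or non-positive hazards")
    death = rng.exponential(1.0 / hazard)
    if design.censor_rate > 0:
        censor = rng.exponential(1.0 / design.censor_rate, size=design.n_tumor)
    else:
        censor = np.full(design.n_tumor, np.inf)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    if not np.all(np.isfinite(time)):
        raise ValueError("survival times are non-finite; check hazard parameters")
    survival = pd.DataFrame({"sample_id": tumor_ids, "time": time, "event": event})

    full_truth = GroundTruth(
        module_assignment=assignment,
        survival_module_id=surv_mid,
        de_genes=tuple(module_genes + list(down_genes)),
        expected_hub=truth.expected_hub,
        latent_me=dict(zip(tumor_ids, me.tolist())),
        survival_class=dict(
            zip(tumor_ids, np.where(short_class, "short", "long").tolist())
        ),
    )
    return expr, sample_class, survival, full_truth


def generate_study(design: SyntheticDesign):
    """Scaffold + dataset in one call; returns (scaffold, expr, classes, survival, truth)."""
    scaffold, truth = generate_scaffold(design)
    expr, classes, survival, truth = generate_dataset(design, scaffold, truth)
    return scaffold, expr, classes, survival, truth


def gene_sets_for_truth(
    truth: GroundTruth,
    genes: list[str],
    n_random_sets: int = 10,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Local gene-set collection for enrichment tests.

    One set per planted module (its genes plus a few random extras) and
    ``n_random_sets`` random background sets, so over-representation of a
    recovered module lights up exactly its planted set.
    """
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    module_ids = sorted(set(truth.module_assignment.values()))
    for mid in module_ids:
        members = truth.module_genes(mid)
        extras = [g for g in genes if g not in members]
        pad = rng.choice(extras, size=min(5, len(extras)), replace=False)
        sets[f"PLANTED_MODULE_{mid}"] = sorted(members + list(pad))
    for k in range(1, n_random_sets + 1):
        size = int(rng.integers(8, 20))
        sets[f"RANDOM_SET_{k:02d}"] = sorted(rng.choice(genes, size=min(size, len(genes)), replace=False))
    return sets
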