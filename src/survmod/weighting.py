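"""Survival-stratified differential co-expression edge weighting.

Every scaffold edge (x, y) receives the weight

    D_xy = |Z(r_L) - Z(r_S)| / sqrt(1/(n_L - 3) + 1/(n_S - 3))

where r_L and r_S are Pearson correlations of the two genes across the
longer- and shorter-survival training samples and Z is Fisher's
variance-stabilising transformation Z(r) = arctanh(r).  Under equal
population correlations (bivariate normal data) D is asymptotically the
absolute value of a standard normal, so large D flags gene pairs whose
co-expression differs between survival groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# correlations numerically at +-1 would map to infinite Z
_R_CLAMP = 1.0 - 1e-12


@dataclass(frozen=True)
class SurvivalStrata:
    """Longer/shorter survival sample groups of one partition."""

    longer: tuple[str, ...]
    shorter: tuple[str, ...]

    @property
    def n_L(self) -> int:
        return len(self.longer)

    @property
    def n_S(self) -> int:
        return len(self.shorter)


@dataclass(frozen=True)
class WeightedEdge:
    gene_x: str
    gene_y: str
    r_L: float
    r_S: float
    z_L: float
    z_S: float
    D: float


def split_train_test(
    samples: list[str] | np.ndarray,
    train_frac: float = 0.6,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Randomly partition ``samples`` into training and test sets.

    ``|train| = round(train_frac * n)`` with half-up rounding, so a
    352-sample cohort at ``train_frac=0.619`` yields 218 training samples.
    Deterministic for a fixed seed.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    samples = list(samples)
    n = len(samples)
    if n < 10:
        raise ValueError(f"need at least 10 samples to split, got {n}")
    n_train = int(math.floor(train_frac * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [samples[i] for i in sorted(perm[:n_train])]
    test = [samples[i] for i in sorted(perm[n_train:])]
    return train, test


def stratify_survival(
    surv: pd.DataFrame,
    samples: list[str],
    rule: str = "median_time",
) -> SurvivalStrata:
    """Split ``samples`` into shorter/longer survival groups.

    Default rule is a median split on observed follow-up time: shorter =
    time < median, longer = time >= median.  ``median_event_time`` computes
    the median over uncensored samples only (the split itself still covers
    every sample).  Fisher's variance 1/(n-3) requires at least 4 samples
    per group.
    """
    surv = surv.set_index("sample_id") if "sample_id" in surv.columns else surv
    missing = [s for s in samples if s not in surv.index]
    if missing:
        raise KeyError(f"samples missing from survival table: {missing[:5]}")
    times = surv.loc[samples, "time"].to_numpy(dtype=float)
    if rule == "median_time":
        med = float(np.median(times))
    elif rule == "median_event_time":
        events = surv.loc[samples, "event"].to_numpy(dtype=int)
        if events.sum() == 0:
            raise ValueError("median_event_time rule needs at least one event")
        med = float(np.median(times[events == 1]))
    else:
        raise ValueError(f"unknown stratify rule: {rule!r}")
    shorter = tuple(s for s, t in zip(samples, times) if t < med)
    longer = tuple(s for s, t in zip(samples, times) if t >= med)
    if len(longer) < 4 or len(shorter) < 4:
        raise ValueError(
            "degenerate survival split: "
            f"n_L={len(longer)}, n_S={len(shorter)} (need >= 4 each)"
        )
    return SurvivalStrata(longer=longer, shorter=shorter)


def fisher_z(r):
    """Fisher's Z transformation, Z(r) = 0.5 * ln((1 + r) / (1 - r)).

    Odd and strictly increasing on (-1, 1); |r| >= 1 is rejected.
    Accepts scalars or arrays.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def edge_weight(r_L: float, r_S: float, n_L: int, n_S: int) -> float:
    """Differential co-expression statistic D for one edge.

    D = |Z(r_L) - Z(r_S)| / sqrt(1/(n_L-3) + 1/(n_S-3)); zero when the two
    correlations agree, asymptotically |N(0,1)| under the null.
    """
    if n_L <= 3 or n_S <= 3:
        raise ValueError(f"group sizes must exceed 3, got n_L={n_L}, n_S={n_S}")
    se = math.sqrt(1.0 / (n_L - 3) + 1.0 / (n_S - 3))
    return abs(fisher_z(r_L) - fisher_z(r_S)) / se


def _stratum_zscores(expr: pd.DataFrame, samples: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardised expression over one stratum; returns (Z, ok_rows)."""
    X = expr.loc[:, list(samples)].to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    sd[~ok] = 1.0
    return (X - mu) / sd, ok


def weight_network(
    scaffold: nx.Graph,
    expr: pd.DataFrame,
    strata: SurvivalStrata,
) -> nx.Graph:
    """Weight every scaffold edge with the D statistic.

    ``expr`` is a genes x samples log2 expression frame containing every
    stratified sample.  Edges touching a gene with zero variance in either
    stratum are dropped with a warning.  Returns a new graph whose edges
    carry ``r_L, r_S, z_L, z_S`` and ``weight`` (= D).
    """
    missing = [g for g in scaffold.nodes if g not in expr.index]
    if missing:
        raise KeyError(f"scaffold gene(s) absent from expression matrix: {missing[:5]}")
    n_L, n_S = strata.n_L, strata.n_S
    if n_L <= 3 or n_S <= 3:
        raise ValueError("strata too small for Fisher variance (need > 3 per group)")

    genes = sorted(scaffold.nodes)
    sub = expr.loc[genes]
    Z_L, ok_L = _stratum_zscores(sub, strata.longer)
    Z_S, ok_S = _stratum_zscores(sub, strata.shorter)
    idx = {g: i for i, g in enumerate(genes)}

    se = math.sqrt(1.0 / (n_L - 3) + 1.0 / (n_S - 3))
    out = nx.Graph()
    out.add_nodes_from(genes)
    n_dropped = 0
    for u, v in sorted(tuple(sorted(e)) for e in scaffold.edges):
        i, j = idx[u], idx[v]
        if not (ok_L[i] and ok_L[j] and ok_S[i] and ok_S[j]):
            n_dropped += 1
            continue
        r_L = float(np.clip(Z_L[i] @ Z_L[j] / n_L, -_R_CLAMP, _R_CLAMP))
        r_S = float(np.clip(Z_S[i] @ Z_S[j] / n_S, -_R_CLAMP, _R_CLAMP))
        z_L = float(np.arctanh(r_L))
        z_S = float(np.arctanh(r_S))
        out.add_edge(u, v, r_L=r_L, r_S=r_S, z_L=z_L, z_S=z_S, weight=abs(z_L - z_S) / se)
    if n_dropped:
        logger.warning("dropped %d edge(s) with a zero-variance gene in a stratum", n_dropped)
    return out


def weighted_edge_table(net: nx.Graph) -> pd.DataFrame:
    """Edge attributes of a weighted network as a sorted DataFrame."""
    rows = [
        {
            "gene_x": u,
            "gene_y": v,
            "r_L": d["r_L"],
            "r_S": d["r_S"],
            "z_L": d["z_L"],
            "z_S": d["z_S"],
            "D": d["weight"],
        }
        for u, v, d in sorted(net.edges(data=True), key=lambda e: (e[0], e[1]))
    ]
    return pd.DataFrame(rows, columns=["gene_x", "gene_y", "r_L", "r_S", "z_L", "z_S", "D"])
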