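"""Differential expression on log2 expression matrices.

Duplicate gene rows are collapsed by averaging, then tumor-vs-normal
differential expression is called with an empirical-Bayes moderated
two-sample t statistic: per-gene pooled variances are shrunk toward a
prior (d0, s0^2) fitted by moment-matching the scaled-F distribution of
the sample variances, and the resulting t statistics gain d0 extra
degrees of freedom.  Genes pass at |log2FC| > 2 and BH-adjusted p < 0.05
by default (strict inequalities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModeratedTPrior:
    """Fitted variance prior: d0 degrees of freedom, s0^2 location."""

    d0: float
    s0_sq: float


def collapse_duplicates(expr: pd.DataFrame) -> pd.DataFrame:
    """Average rows sharing a gene identifier, one row per unique gene.

    Row order follows first appearance of each identifier.
    """
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("empty expression matrix")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    if expr.index.is_unique:
        return expr.copy()
    order = expr.index.drop_duplicates()
    out = expr.groupby(level=0, sort=False).mean()
    return out.loc[order]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s_sq: np.ndarray, df: float) -> ModeratedTPrior:
    """Moment-match (d0, s0^2) of the scaled-F model s^2 ~ s0^2 F(df, d0).

    Works on z = log(s^2): the excess of var(z) over trigamma(df/2)
    identifies d0 through trigamma(d0/2); the mean of z then gives s0^2.
    A non-positive excess means the variances are essentially homogeneous
    and d0 is infinite (complete shrinkage to s0^2).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[s_sq > 0]
    if s_sq.size == 0:
        raise ValueError("cannot fit variance prior: all gene variances are zero")
    z = np.log(s_sq)
    z_mean = z.mean()
    z_var = z.var(ddof=1) if z.size > 1 else 0.0
    expected_var_term = float(special.polygamma(1, df / 2.0))
    excess = z_var - expected_var_term
    if excess <= 0:
        d0 = np.inf
        log_s0 = z_mean - special.digamma(df / 2.0) + np.log(df / 2.0)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0 = (
            z_mean
            - special.digamma(df / 2.0)
            + special.digamma(d0 / 2.0)
            + np.log(df / d0)
        )
    return ModeratedTPrior(d0=float(d0), s0_sq=float(np.exp(log_s0)))


def moderated_t(
    expr: pd.DataFrame,
    sample_class: pd.Series | dict,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t, tumor minus normal.

    Returns a per-gene frame with columns ``log2fc, t_stat, p, p_adj``
    (BH within this call) plus ``zero_variance`` flagging degenerate rows,
    which are assigned t = 0, p = 1.  ``d0_override`` forces the prior df
    (0 recovers the ordinary pooled t); primarily for verification.
    """
    classes = pd.Series(sample_class)
    tumor = [s for s in expr.columns if classes.get(s) == "tumor"]
    normal = [s for s in expr.columns if classes.get(s) == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"need >= 2 samples per class, got {len(tumor)} tumor / {len(normal)} normal"
        )
    Xt = expr.loc[:, tumor].to_numpy(dtype=float)
    Xn = expr.loc[:, normal].to_numpy(dtype=float)
    n_t, n_n = len(tumor), len(normal)
    df = n_t + n_n - 2

    lfc = Xt.mean(axis=1) - Xn.mean(axis=1)
    ss = Xt.var(axis=1, ddof=1) * (n_t - 1) + Xn.var(axis=1, ddof=1) * (n_n - 1)
    s_sq = ss / df
    zero_var = s_sq <= 0

    if zero_var.all():
        raise ValueError("all genes have zero pooled variance; cannot fit prior")

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = 0.0 if d0 == 0 else fit_variance_prior(s_sq[~zero_var], df).s0_sq
    else:
        prior = fit_variance_prior(s_sq[~zero_var], df)
        d0, s0_sq = prior.d0, prior.s0_sq
        logger.info("moderated-t prior: d0=%.4g, s0^2=%.4g", d0, s0_sq)

    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        total_df = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + df * s_sq) / (d0 + df)
        total_df = df + d0
    denom = np.sqrt(s_tilde_sq * (1.0 / n_t + 1.0 / n_n))

    t = np.zeros_like(lfc)
    ok = ~zero_var & (denom > 0)
    t[ok] = lfc[ok] / denom[ok]
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p[zero_var] = 1.0
    t[zero_var] = 0.0
    if zero_var.any():
        logger.warning("%d gene(s) with zero variance in both classes flagged", zero_var.sum())

    p_adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "t_stat": t,
            "p": p,
            "p_adj": p_adj,
            "zero_variance": zero_var,
        },
        index=expr.index.rename("gene"),
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1)) or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def filter_degs(
    results: pd.DataFrame,
    lfc_thr: float = 2.0,
    alpha: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Up-/down-regulated gene lists at |log2FC| > lfc_thr, BH p < alpha."""
    sig = results["p_adj"] < alpha
    up = results.index[sig & (results["log2fc"] > lfc_thr)].tolist()
    down = results.index[sig & (results["log2fc"] < -lfc_thr)].tolist()
    return up, down


def de_table(results: pd.DataFrame, lfc_thr: float = 2.0, alpha: float = 0.05) -> pd.DataFrame:
    """Attach an up/down/ns direction column to moderated-t results."""
    up, down = filter_degs(results, lfc_thr, alpha)
    direction = pd.Series("ns", index=results.index)
    direction[results.index.isin(up)] = "up"
    direction[results.index.isin(down)] = "down"
    out = results.copy()
    out["direction"] = direction
    return out
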