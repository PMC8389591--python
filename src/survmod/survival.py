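"""Module-level survival screening.

Each module is summarised by its eigengene (first right-singular vector
of the standardised gene x sample expression block), samples are split
at the eigengene median, and the two groups are compared with the
Kaplan-Meier estimator and the two-group log-rank test.  The report per
module carries per-group hazard rates (events per unit person-time), the
O/E hazard ratio with its log-scale 95% CI, the signed z value and the
two-tailed p — for both the training and test partitions.  A module is
called survival-associated when p < alpha in both partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModuleEigengene:
    module_id: int
    sample_scores: pd.Series  # unit-norm, zero-mean over samples
    variance_explained: float
    sign_anchor: str


@dataclass(frozen=True)
class KMCurve:
    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    z: float
    p_two_sided: float
    hazard_rate_low: float
    hazard_rate_high: float
    hazard_ratio: float
    ci95: tuple[float, float]
    n_low: int
    n_high: int


def module_eigengene(expr: pd.DataFrame, genes, module_id: int = 0) -> ModuleEigengene:
    """Module eigengene by singular value decomposition.

    Gene rows are standardised (zero mean, unit variance across samples;
    constant rows dropped), the first right-singular vector of the
    standardised block is taken as the eigengene (unit Euclidean norm,
    zero mean), and its sign is fixed so it correlates positively with
    the module's mean standardised expression.  ``variance_explained`` is
    the first squared singular value over the sum of all squared singular
    values.
    """
    present = [g for g in genes if g in expr.index]
    X = expr.loc[present].to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 3:
        raise ValueError("module eigengene needs >= 2 genes present and >= 3 samples")
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant module genes")
    if not keep.all():
        logger.warning("dropped %d constant gene row(s) from module %d", (~keep).sum(), module_id)
    X = X[keep]
    present = [g for g, k in zip(present, keep) if k]
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    me = Vt[0]
    mean_profile = Z.mean(axis=0)
    if float(me @ mean_profile) < 0:
        me = -me
    loadings = Z @ me
    anchor = present[int(np.argmax(loadings))]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return ModuleEigengene(
        module_id=module_id,
        sample_scores=pd.Series(me, index=expr.columns, name=f"ME{module_id}"),
        variance_explained=var_explained,
        sign_anchor=anchor,
    )


def median_split(me: ModuleEigengene) -> tuple[list[str], list[str]]:
    """Split samples at the eigengene median; the median itself goes high."""
    scores = me.sample_scores
    med = float(scores.median())
    low = scores.index[scores < med].tolist()
    high = scores.index[scores >= med].tolist()
    if not low or not high:
        raise ValueError("degenerate eigengene: median split leaves a group empty")
    return low, high


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator over distinct event times."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(t < 0) or not np.isfinite(t).all():
        raise ValueError("times must be finite and non-negative")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1")
    event_times = np.unique(t[e == 1])
    at_risk = np.empty(event_times.size, dtype=int)
    d = np.empty(event_times.size, dtype=int)
    surv = np.empty(event_times.size)
    s = 1.0
    for k, ti in enumerate(event_times):
        n_i = int(np.sum(t >= ti))
        d_i = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d_i / n_i
        at_risk[k], d[k], surv[k] = n_i, d_i, s
    return KMCurve(event_times=event_times, at_risk=at_risk, events=d, survival=surv)


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test with the O/E hazard-ratio report.

    Group "a" is reported as the high group, "b" as the low group.  At
    each distinct event time the expected events and hypergeometric
    variance are accumulated; z = (O_a - E_a)/sqrt(V), chi2 = z^2, two-
    sided p from the normal.  Per-group hazard rates are events per unit
    follow-up; HR = (O_a/E_a)/(O_b/E_b) with CI exp(log HR +- 1.96 *
    sqrt(1/E_a + 1/E_b)).
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank needs at least one event")

    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    grp_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(all_t[all_e == 1])

    O_a = float(ea.sum())
    O_b = float(eb.sum())
    E_a = E_b = V = 0.0
    for ti in event_times:
        at_risk = all_t >= ti
        n = float(at_risk.sum())
        n_a = float((at_risk & grp_a).sum())
        d = float(((all_t == ti) & (all_e == 1)).sum())
        E_a += d * n_a / n
        E_b += d * (n - n_a) / n
        if n > 1:
            V += d * (n_a / n) * ((n - n_a) / n) * (n - d) / (n - 1)
    if V <= 0:
        raise ValueError("log-rank variance is zero (no between-group information)")
    z = (O_a - E_a) / np.sqrt(V)
    chi2 = z * z
    p = float(2.0 * stats.norm.sf(abs(z)))

    rate_a = O_a / ta.sum() if ta.sum() > 0 else np.nan
    rate_b = O_b / tb.sum() if tb.sum() > 0 else np.nan
    if E_a > 0 and E_b > 0 and O_a > 0 and O_b > 0:
        hr = (O_a / E_a) / (O_b / E_b)
        half = 1.96 * np.sqrt(1.0 / E_a + 1.0 / E_b)
        ci = (float(hr * np.exp(-half)), float(hr * np.exp(half)))
    else:
        hr, ci = np.nan, (np.nan, np.nan)
    return LogRankResult(
        chi2=float(chi2),
        z=float(z),
        p_two_sided=p,
        hazard_rate_low=float(rate_b),
        hazard_rate_high=float(rate_a),
        hazard_ratio=float(hr),
        ci95=ci,
        n_low=int(tb.size),
        n_high=int(ta.size),
    )


def _score_partition(module_genes, module_id, expr, surv, alpha):
    surv = surv.set_index("sample_id") if "sample_id" in surv.columns else surv
    cols = [s for s in expr.columns if s in surv.index]
    me = module_eigengene(expr.loc[:, cols], module_genes, module_id)
    low, high = median_split(me)
    res = logrank_test(
        surv.loc[high, "time"].to_numpy(),
        surv.loc[high, "event"].to_numpy(),
        surv.loc[low, "time"].to_numpy(),
        surv.loc[low, "event"].to_numpy(),
    )
    return me, res


def evaluate_modules(
    modules,
    expr_train: pd.DataFrame,
    surv_train: pd.DataFrame,
    expr_test: pd.DataFrame,
    surv_test: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every module in both partitions; flag those significant in both.

    Each partition computes its own eigengene and its own median split.
    Returns one row per scored module with train/test z, p, HR, CI and the
    ``significant_both`` verdict at level ``alpha``; modules whose genes
    are (almost entirely) missing from the expression matrix are skipped
    with a warning.
    """
    rows = []
    for m in modules:
        genes = sorted(m.genes)
        try:
            _, r_train = _score_partition(genes, m.id, expr_train, surv_train, alpha)
            _, r_test = _score_partition(genes, m.id, expr_test, surv_test, alpha)
        except (ValueError, KeyError) as exc:
            logger.warning("module %d skipped: %s", m.id, exc)
            continue
        rows.append(
            {
                "module_id": m.id,
                "n_genes": m.n_nodes,
                "n_edges": m.n_edges,
                "train_z": r_train.z,
                "train_p": r_train.p_two_sided,
                "train_hr": r_train.hazard_ratio,
                "train_ci_low": r_train.ci95[0],
                "train_ci_high": r_train.ci95[1],
                "train_hazard_rate_low": r_train.hazard_rate_low,
                "train_hazard_rate_high": r_train.hazard_rate_high,
                "test_z": r_test.z,
                "test_p": r_test.p_two_sided,
                "test_hr": r_test.hazard_ratio,
                "test_ci_low": r_test.ci95[0],
                "test_ci_high": r_test.ci95[1],
                "test_hazard_rate_low": r_test.hazard_rate_low,
                "test_hazard_rate_high": r_test.hazard_rate_high,
                "significant_both": bool(
                    r_train.p_two_sided < alpha and r_test.p_two_sided < alpha
                ),
            }
        )
    return pd.DataFrame(rows)
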