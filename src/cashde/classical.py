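"""Conventional two-group differential expression: Welch's t, moderated t, BH FDR.

Welch's unequal-variance t-test is computed gene-by-gene from the closed
formulas with Welch–Satterthwaite degrees of freedom.  The empirical-Bayes
moderated t shrinks each gene's pooled residual variance toward a prior
variance s0^2 with d0 prior degrees of freedom; (d0, s0^2) are estimated by
the standard method of moments on log variances (digamma/trigamma matching),
and the moderated statistic is referred to a t distribution on d0 + d_g
degrees of freedom.  BH is the classical step-up procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .datasets import ExpressionDataset
from .errors import ValidationError

# p-values are floored at the smallest positive normal so BH stays defined
# and logs never overflow; this only triggers for zero residual variance.
_P_FLOOR = float(np.finfo(float).tiny)


def _group_arrays(ds: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    case = ds.case_matrix().to_numpy()
    ctrl = ds.control_matrix().to_numpy()
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValidationError("both groups need >=2 samples")
    return case, ctrl


def welch_t(ds: ExpressionDataset) -> pd.DataFrame:
    """Per-gene Welch t, Welch–Satterthwaite df and two-sided p.

    Degenerate genes: zero variance in both groups with zero mean difference
    give t = 0, p = 1; zero variance with a non-zero difference gives an
    infinite t and the floored minimum p-value.
    """
    case, ctrl = _group_arrays(ds)
    n1, n2 = case.shape[1], ctrl.shape[1]
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    v1, v2 = case.var(axis=1, ddof=1), ctrl.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    zero_se = se2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    df = np.where(zero_se, n1 + n2 - 2, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(np.where(np.isinf(t), 0.0, p), _P_FLOOR, 1.0)
    return pd.DataFrame(
        {"mean_case": m1, "mean_ctrl": m2, "t": t, "df": df, "p": p},
        index=ds.values.index,
    )


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < tol:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F variance prior (d0, s0^2).

    Matches the first two moments of log s_g^2 under the hierarchical model
    s_g^2 | sigma_g^2 ~ sigma_g^2 chi^2_d / d, sigma_g^2 ~ s0^2 d0 / chi^2_d0,
    using digamma/trigamma identities.  Returns d0 = inf (no heterogeneity
    beyond sampling noise) when the excess variance of log s^2 is <= 0.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        raise ValidationError("variance prior needs >=2 genes")
    z = np.log(np.maximum(s2, _P_FLOOR))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    excess = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(s2.mean())
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def ebayes_moderated_t(
    ds: ExpressionDataset,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t with empirical-Bayes variance shrinkage.

    ``prior_df`` / ``prior_var`` override the estimated hyperparameters
    (d0 = 0 recovers the ordinary pooled-variance t; d0 = inf uses the
    common prior variance for every gene).
    """
    case, ctrl = _group_arrays(ds)
    if ds.n_genes < 2:
        raise ValidationError("moderated t needs >=2 genes to estimate the prior")
    n1, n2 = case.shape[1], ctrl.shape[1]
    d_res = n1 + n2 - 2
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d_res
    if prior_df is None or prior_var is None:
        d0_est, s0_est = estimate_variance_prior(s2, d_res)
        d0 = d0_est if prior_df is None else prior_df
        s0_2 = s0_est if prior_var is None else prior_var
    else:
        d0, s0_2 = prior_df, prior_var
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d_res * s2) / (d0 + d_res)
        df_total = d0 + d_res
    diff = m1 - m2
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = diff / se
    t_mod = np.where(se == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t_mod)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(np.where(np.isinf(t_mod), 0.0, p), _P_FLOOR, 1.0)
    return pd.DataFrame(
        {
            "mean_case": m1,
            "mean_ctrl": m2,
            "t_mod": t_mod,
            "df_total": np.full(len(s2), df_total, dtype=float),
            "p": p,
            "s2": s2,
            "s2_post": s2_post,
            "d0": np.full(len(s2), d0, dtype=float),
            "s0_2": np.full(len(s2), s0_2, dtype=float),
        },
        index=ds.values.index,
    )


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; stable under ties and
    returned in the original order.
    """
    index = p.index if isinstance(p, pd.Series) else None
    arr = np.asarray(p, dtype=float)
    if arr.size and (((arr <= 0) | (arr > 1)).any() or not np.isfinite(arr).all()):
        raise ValidationError("p-values must lie in (0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="mergesort")
    ranked = arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return pd.Series(q, index=index) if index is not None else q


def classical_results(ds: ExpressionDataset) -> pd.DataFrame:
    """Welch + moderated t with BH q-values, in one table."""
    w = welch_t(ds)
    e = ebayes_moderated_t(ds)
    return pd.DataFrame(
        {
            "mean_case": w["mean_case"],
            "mean_ctrl": w["mean_ctrl"],
            "t_welch": w["t"],
            "df_welch": w["df"],
            "p_welch": w["p"],
            "q_welch": bh_fdr(w["p"]),
            "t_ebayes": e["t_mod"],
            "df_ebayes": e["df_total"],
            "p_ebayes": e["p"],
            "q_ebayes": bh_fdr(e["p"]),
        },
        index=ds.values.index,
    )
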