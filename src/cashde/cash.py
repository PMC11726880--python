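"""The CASh procedure: Shapley-difference statistics with a bootstrap null.

Pipeline: genes are preselected by raw p-value, expression is dichotomized
against the control mean +/- SD separately for over- and under-expression,
microarray games are built per group and the per-gene Shapley values
compared.  The observed difference d_g = Phi_case - Phi_ctrl is referred to
a bootstrap null built by pooling the case and control sample columns and
redrawing pseudo-groups of the original sizes with replacement; resamples
are shared across genes so gene-gene dependence is preserved.  The two
directions are combined Bonferroni-style and BH-corrected across the
preselected genes; a |fold change| > threshold filter is available on top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classical import bh_fdr, welch_t, ebayes_moderated_t
from .datasets import ExpressionDataset
from .errors import ValidationError
from .games import (
    OVER,
    UNDER,
    BooleanExpressionMatrix,
    control_reference,
    discretize,
    shapley_matrix,
    split_by_group,
)


@dataclass(frozen=True)
class CashConfig:
    """Tuning knobs of the CASh run.

    preselect_alpha : raw p cutoff for gene preselection (0.01 strict, 0.05 lax)
    n_boot          : bootstrap iterations B (1000 by default)
    fc_threshold    : fold-change cutoff; a DEG needs |FC| strictly above it
    fdr_alpha       : BH threshold for the FDR-corrected gene list
    seed            : seed for the bootstrap resampling
    preselect_method: source of the preselection raw p ("welch" or "ebayes")
    """

    preselect_alpha: float = 0.05
    n_boot: int = 1000
    fc_threshold: float = 2.0
    fdr_alpha: float = 0.05
    seed: int = 0
    preselect_method: str = "welch"

    def __post_init__(self) -> None:
        if not 0 < self.preselect_alpha <= 1:
            raise ValidationError("preselect_alpha must be in (0, 1]")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")
        if self.fc_threshold <= 1:
            raise ValidationError("fc_threshold must exceed 1")
        if not 0 < self.fdr_alpha < 1:
            raise ValidationError("fdr_alpha must be in (0, 1)")
        if self.preselect_method not in ("welch", "ebayes"):
            raise ValidationError("preselect_method must be 'welch' or 'ebayes'")


CASH_RESULT_COLUMNS = [
    "gene",
    "phi_case_over",
    "phi_ctrl_over",
    "phi_case_under",
    "phi_ctrl_under",
    "d_over",
    "d_under",
    "p_over",
    "p_under",
    "p_gene",
    "q_gene",
    "delta_log2",
    "fold_change",
    "direction",
    "sig_raw",
    "sig_fdr",
    "passes_fc",
]


def preselect_genes(
    ds: ExpressionDataset, alpha: float, method: str = "welch"
) -> list[str]:
    """Genes with raw p < alpha (strict), in dataset order; may be empty."""
    if method == "welch":
        p = welch_t(ds)["p"]
    elif method == "ebayes":
        p = ebayes_moderated_t(ds)["p"]
    else:
        raise ValidationError("method must be 'welch' or 'ebayes'")
    return list(p.index[p.to_numpy() < alpha])


def bootstrap_pvalues(
    b_case: BooleanExpressionMatrix,
    b_ctrl: BooleanExpressionMatrix,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed Shapley differences and two-sided bootstrap p-values.

    The pooled columns of both matrices are redrawn with replacement into
    pseudo-groups of the original sizes; p_g = (1 + #{|d*| >= |d|}) / (B+1).
    A sample's credit split b_gj / k_j depends only on its own column, so it
    is precomputed once and reused across all resamples.
    """
    if b_case.genes != b_ctrl.genes:
        raise ValidationError("case/control Boolean matrices index different genes")
    m1, m2 = b_case.values.shape[1], b_ctrl.values.shape[1]
    if m1 < 2 or m2 < 2:
        raise ValidationError("bootstrap needs >=2 samples per group")
    pooled = np.concatenate([b_case.values, b_ctrl.values], axis=1).astype(float)
    k = pooled.sum(axis=0)
    contrib = np.divide(pooled, k, out=np.zeros_like(pooled), where=k > 0)
    d_obs = contrib[:, :m1].mean(axis=1) - contrib[:, m1:].mean(axis=1)
    abs_obs = np.abs(d_obs)
    m = m1 + m2
    exceed = np.zeros(len(abs_obs), dtype=int)
    for _ in range(n_boot):
        idx_case = rng.integers(0, m, size=m1)
        idx_ctrl = rng.integers(0, m, size=m2)
        d_star = contrib[:, idx_case].mean(axis=1) - contrib[:, idx_ctrl].mean(axis=1)
        exceed += np.abs(d_star) >= abs_obs
    p = (1.0 + exceed) / (n_boot + 1.0)
    return d_obs, p


def combine_directions(
    p_over: np.ndarray,
    p_under: np.ndarray,
    d_over: np.ndarray,
    d_under: np.ndarray,
    delta: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni over the two one-direction games: p_gene = min(1, 2 min(p)).

    The reported direction comes from the minimizing side together with the
    sign of its Shapley difference: a winning over-game with d_over > 0 (or a
    winning under-game with d_under < 0 — cases *less* under-expressed than
    controls) is "up", and symmetrically for "down".  Remaining ties follow
    the sign of the mean log2 difference ``delta``, then default to up.
    """
    p_over = np.asarray(p_over, dtype=float)
    p_under = np.asarray(p_under, dtype=float)
    d_over = np.asarray(d_over, dtype=float)
    d_under = np.asarray(d_under, dtype=float)
    delta = np.zeros_like(p_over) if delta is None else np.asarray(delta, dtype=float)
    p_gene = np.minimum(1.0, 2.0 * np.minimum(p_over, p_under))
    fallback = np.where(delta < 0, "down", "up")
    dir_over = np.where(d_over > 0, "up", np.where(d_over < 0, "down", fallback))
    dir_under = np.where(d_under > 0, "down", np.where(d_under < 0, "up", fallback))
    direction = np.where(
        p_over < p_under, dir_over, np.where(p_under < p_over, dir_under, fallback)
    )
    return p_gene, direction


def fold_change(ds: ExpressionDataset) -> pd.DataFrame:
    """Mean log2 difference (case - control) and signed fold change 2^|delta|."""
    delta = ds.case_matrix().mean(axis=1) - ds.control_matrix().mean(axis=1)
    fc = np.where(delta >= 0, 2.0**delta, -(2.0 ** (-delta)))
    return pd.DataFrame({"delta_log2": delta, "fold_change": fc}, index=ds.values.index)


def run_cash(ds: ExpressionDataset, cfg: CashConfig) -> pd.DataFrame:
    """End-to-end CASh run; one result row per preselected gene.

    Returns a DataFrame with :data:`CASH_RESULT_COLUMNS`; an empty
    preselection yields an empty (but well-formed) table.
    """
    ds._require_groups()
    selected = preselect_genes(ds, cfg.preselect_alpha, cfg.preselect_method)
    if not selected:
        return pd.DataFrame(columns=CASH_RESULT_COLUMNS)
    sub = ds.subset_genes(selected)
    ref = control_reference(sub)
    fc = fold_change(sub)
    delta = fc["delta_log2"].to_numpy()

    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(2)]
    phi = {}
    d = {}
    p = {}
    for direction, rng in zip((OVER, UNDER), rngs):
        b = discretize(sub, ref, direction)
        b_case, b_ctrl = split_by_group(b, sub.groups)
        phi[(direction, "case")] = shapley_matrix(b_case.values.astype(float))
        phi[(direction, "ctrl")] = shapley_matrix(b_ctrl.values.astype(float))
        d[direction], p[direction] = bootstrap_pvalues(b_case, b_ctrl, cfg.n_boot, rng)

    p_gene, direction = combine_directions(p[OVER], p[UNDER], d[OVER], d[UNDER], delta)
    q_gene = bh_fdr(p_gene)
    passes_fc = np.abs(delta) > np.log2(cfg.fc_threshold)
    return pd.DataFrame(
        {
            "gene": sub.genes,
            "phi_case_over": phi[(OVER, "case")],
            "phi_ctrl_over": phi[(OVER, "ctrl")],
            "phi_case_under": phi[(UNDER, "case")],
            "phi_ctrl_under": phi[(UNDER, "ctrl")],
            "d_over": d[OVER],
            "d_under": d[UNDER],
            "p_over": p[OVER],
            "p_under": p[UNDER],
            "p_gene": p_gene,
            "q_gene": q_gene,
            "delta_log2": delta,
            "fold_change": fc["fold_change"].to_numpy(),
            "direction": direction,
            "sig_raw": p_gene < cfg.preselect_alpha,
            "sig_fdr": q_gene < cfg.fdr_alpha,
            "passes_fc": passes_fc,
        }
    )


def write_cash_results(results: pd.DataFrame, path) -> None:
    """Deterministic TSV rendering (6 significant digits, fixed column order)."""
    df = results[CASH_RESULT_COLUMNS].copy()
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].map({True: "1", False: "0"})
        elif df[col].dtype.kind == "f":
            df[col] = [f"{x:.6g}" for x in df[col]]
    df.to_csv(path, sep="\t", index=False)
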