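"""Microarray games: discretization, coalitional game construction, Shapley values.

Expression is dichotomized against the control group's per-gene mean +/- SD.
Each sample j then contributes a *support* sp(j) — the set of genes flagged
abnormal in that sample — and the group of samples defines a coalitional game

    v(S) = |{j : sp(j) != empty and sp(j) subset of S}| / m

i.e. a coalition of genes is worth the fraction of samples it fully explains.
The Shapley value of this game has the exact closed form

    Phi_g = (1/m) * sum over samples j with k_j > 0 of b_gj / k_j

with k_j = |sp(j)|: each sample splits one unit of credit equally among the
genes it flags, and samples flagging nothing contribute nothing (but still
count in m).  :func:`shapley_bruteforce` recomputes Phi from the definition
(average marginal contribution over all gene orderings) as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from .datasets import CASE, CONTROL, ControlReference, ExpressionDataset
from .errors import ValidationError

OVER = "over"
UNDER = "under"


@dataclass(frozen=True)
class BooleanExpressionMatrix:
    """{0,1} abnormal-expression indicator matrix for one direction."""

    direction: str
    values: np.ndarray  # uint8, genes x samples
    genes: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        if self.direction not in (OVER, UNDER):
            raise ValidationError(f"direction must be {OVER!r} or {UNDER!r}")
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape != (len(self.genes), len(self.samples)):
            raise ValidationError("Boolean matrix shape does not match id lists")
        if v.size and not np.isin(v, (0, 1)).all():
            raise ValidationError("Boolean matrix entries must be 0/1")
        object.__setattr__(self, "values", v.astype(np.uint8))


@dataclass(frozen=True)
class MicroarrayGame:
    """Coalitional game induced by one Boolean matrix (one group, one direction)."""

    n_genes: int
    m: int  # number of samples, including those with empty support
    supports: list[frozenset[int]]  # per sample: indices of flagged genes

    def __post_init__(self) -> None:
        if self.m < 1 or self.m != len(self.supports):
            raise ValidationError("game needs >=1 sample and one support per sample")
        for sp in self.supports:
            if sp and (min(sp) < 0 or max(sp) >= self.n_genes):
                raise ValidationError("support indexes a gene out of range")

    @property
    def k(self) -> np.ndarray:
        """Support sizes k_j."""
        return np.array([len(sp) for sp in self.supports], dtype=int)

    def worth(self, coalition: frozenset[int] | set[int]) -> float:
        """v(S): fraction of samples with non-empty support contained in S."""
        s = set(coalition)
        hits = sum(1 for sp in self.supports if sp and sp <= s)
        return hits / self.m


def control_reference(ds: ExpressionDataset) -> ControlReference:
    """Per-gene mean and sample SD (n-1 denominator) over control samples."""
    ctrl = ds.control_matrix()
    if ctrl.shape[1] < 2:
        raise ValidationError("control reference requires >=2 control samples")
    return ControlReference(mean=ctrl.mean(axis=1), sd=ctrl.std(axis=1, ddof=1))


def discretize(
    ds: ExpressionDataset, ref: ControlReference, direction: str
) -> BooleanExpressionMatrix:
    """Dichotomize all samples against the control reference.

    over:  b = 1  iff  x >= mean + sd   (boundary inclusive)
    under: b = 1  iff  x <  mean - sd   (strictly below)

    Genes whose control SD is zero are non-informative and yield all-zero
    rows in both directions.
    """
    if list(ref.mean.index) != ds.genes:
        raise ValidationError("control reference gene list does not match dataset")
    x = ds.values.to_numpy()
    mean = ref.mean.to_numpy()[:, None]
    sd = ref.sd.to_numpy()[:, None]
    if direction == OVER:
        b = x >= mean + sd
    elif direction == UNDER:
        b = x < mean - sd
    else:
        raise ValidationError(f"direction must be {OVER!r} or {UNDER!r}")
    b &= sd > 0
    return BooleanExpressionMatrix(direction, b.astype(np.uint8), ds.genes, ds.samples)


def split_by_group(
    b: BooleanExpressionMatrix, groups: pd.Series
) -> tuple[BooleanExpressionMatrix, BooleanExpressionMatrix]:
    """Partition columns into (case, control) matrices, preserving order."""
    if sorted(groups.index) != sorted(b.samples):
        raise ValidationError("group labels do not cover the Boolean matrix samples")
    case_cols = [j for j, s in enumerate(b.samples) if groups[s] == CASE]
    ctrl_cols = [j for j, s in enumerate(b.samples) if groups[s] == CONTROL]
    mk = lambda cols: BooleanExpressionMatrix(
        b.direction, b.values[:, cols], b.genes, [b.samples[j] for j in cols]
    )
    return mk(case_cols), mk(ctrl_cols)


def build_game(b: BooleanExpressionMatrix) -> MicroarrayGame:
    """Collect per-sample supports sp(j) = {g : b_gj = 1} into a game."""
    if b.values.shape[1] == 0:
        raise ValidationError("cannot build a game from an empty matrix")
    supports = [
        frozenset(np.flatnonzero(b.values[:, j]).tolist())
        for j in range(b.values.shape[1])
    ]
    return MicroarrayGame(n_genes=b.values.shape[0], m=len(supports), supports=supports)


def shapley(game: MicroarrayGame) -> np.ndarray:
    """Closed-form Shapley vector: Phi_g = (1/m) sum_{j: k_j>0} b_gj / k_j."""
    phi = np.zeros(game.n_genes)
    for sp in game.supports:
        if sp:
            share = 1.0 / len(sp)
            for g in sp:
                phi[g] += share
    return phi / game.m


def shapley_matrix(b: np.ndarray) -> np.ndarray:
    """Vectorized closed-form Shapley values straight from a 0/1 matrix."""
    k = b.sum(axis=0)
    contrib = np.divide(b, k, out=np.zeros(b.shape, dtype=float), where=k > 0)
    return contrib.mean(axis=1)


def shapley_bruteforce(game: MicroarrayGame) -> np.ndarray:
    """Exact Shapley values from the permutation definition (oracle).

    Averages the marginal contribution v(P u {g}) - v(P) of each gene over
    all n! gene orderings; evaluated by weighting each predecessor coalition
    S with |S|! (n-|S|-1)! / n!, which is the exact permutation count.
    Guarded to n_genes <= 10.
    """
    n = game.n_genes
    if n > 10:
        raise ValidationError(f"brute-force Shapley limited to 10 genes, got {n}")
    full = (1 << n) - 1
    # v over all 2^n coalitions, via support bitmasks
    masks = [sum(1 << g for g in sp) for sp in game.supports if sp]
    v = np.zeros(full + 1)
    for s in range(full + 1):
        v[s] = sum(1 for mk in masks if mk & ~s == 0) / game.m
    w = [factorial(s) * factorial(n - s - 1) / factorial(n) for s in range(n)]
    phi = np.zeros(n)
    for g in range(n):
        bit = 1 << g
        for s in range(full + 1):
            if not s & bit:
                phi[g] += w[bin(s).count("1")] * (v[s | bit] - v[s])
    return phi
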