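"""Synthetic expression data with planted, possibly partially penetrant DEGs.

The generator emulates RMA-style normalized log2 microarray data: per-gene
baselines drawn from a population distribution, i.i.d. Gaussian noise, and a
minority of genes shifted in the case group.  Crucially the shift can be
*partially penetrant* — present in only a fraction of the case samples —
which is the heterogeneous-dysregulation regime where group-mean tests lose
power but sample-level discretization does not.  The default profile mirrors
a small autism blood study (12 cases vs 14 controls) at 2000 genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import CASE, CONTROL, ExpressionDataset
from .errors import ValidationError


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth generative settings.

    n_genes       : number of simulated genes
    n_case/n_control : group sizes (>=2 each)
    frac_de       : fraction of genes differentially expressed
    effect_size   : shift magnitude, in units of the noise SD
    penetrance    : fraction of case samples actually carrying each effect
    direction_mix : fraction of DE genes shifted upward
    baseline_mean/baseline_sd : population of per-gene baselines, log2 units
    noise_sd      : within-gene sample-to-sample SD, log2 units
    seed          : fully determines the output
    """

    n_genes: int = 2000
    n_case: int = 12
    n_control: int = 14
    frac_de: float = 0.025
    effect_size: float = 2.0
    penetrance: float = 1.0
    direction_mix: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if self.n_case < 2 or self.n_control < 2:
            raise ValidationError("need >=2 samples per group")
        for name in ("frac_de", "direction_mix"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not 0 < self.penetrance <= 1:
            raise ValidationError("penetrance must be in (0, 1]")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValidationError("standard deviations must be >= 0")

    @property
    def n_de(self) -> int:
        return _round_half_up(self.n_genes * self.frac_de)

    @property
    def n_affected(self) -> int:
        return _round_half_up(self.penetrance * self.n_case)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure: which genes are DE, in which direction, and where."""

    table: pd.DataFrame  # index gene; columns is_de, direction, effect_size
    affected: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        for gene, row in t.iterrows():
            if not row["is_de"]:
                if row["direction"] != "none" or self.affected.get(gene):
                    raise ValidationError(f"non-DE gene {gene!r} carries DE metadata")

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_de"]])


def generate_dataset(cfg: SimulationConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Draw one dataset and its ground truth; identical seeds give identical data.

    Per-gene baseline mu_g ~ N(baseline_mean, baseline_sd^2); every sample
    value ~ N(mu_g, noise_sd^2); each DE gene shifts a fixed-size random
    subset of round(penetrance * n_case) case samples by +-effect_size *
    noise_sd.
    """
    n_de = cfg.n_de
    if n_de > 0 and cfg.n_affected < 1:
        raise ValidationError(
            "penetrance * n_case rounds below 1: planted effects would be empty"
        )
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    samples = [f"case_{i:03d}" for i in range(cfg.n_case)] + [
        f"ctrl_{i:03d}" for i in range(cfg.n_control)
    ]
    n_total = cfg.n_case + cfg.n_control
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    x = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_total))

    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    n_up = _round_half_up(n_de * cfg.direction_mix)
    directions = np.array(["up"] * n_up + ["down"] * (n_de - n_up))
    rng.shuffle(directions)

    is_de = np.zeros(cfg.n_genes, dtype=bool)
    gene_dir = np.array(["none"] * cfg.n_genes, dtype=object)
    effect = np.zeros(cfg.n_genes)
    affected: dict[str, list[str]] = {}
    shift = cfg.effect_size * cfg.noise_sd
    for gi, direction in zip(de_idx, directions):
        cols = rng.choice(cfg.n_case, size=cfg.n_affected, replace=False)
        sign = 1.0 if direction == "up" else -1.0
        x[gi, cols] += sign * shift
        is_de[gi] = True
        gene_dir[gi] = direction
        effect[gi] = shift
        affected[genes[gi]] = sorted(samples[c] for c in cols)

    values = pd.DataFrame(x, index=genes, columns=samples)
    groups = pd.Series([CASE] * cfg.n_case + [CONTROL] * cfg.n_control, index=samples)
    truth = SyntheticTruth(
        table=pd.DataFrame(
            {"is_de": is_de, "direction": gene_dir, "effect_size": effect}, index=genes
        ),
        affected=affected,
    )
    return ExpressionDataset(values, groups), truth


def null_permutation_dataset(ds: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Randomly reassign group labels (sizes preserved), severing any signal."""
    g = ds._require_groups()
    rng = np.random.default_rng(seed)
    shuffled = g.to_numpy().copy()
    rng.shuffle(shuffled)
    return ds.with_groups(pd.Series(shuffled, index=g.index))


def write_truth(truth: SyntheticTruth, path) -> None:
    """TSV with per-gene DE flag, direction, effect and affected sample list."""
    df = truth.table.copy()
    df["affected_samples"] = [
        ",".join(truth.affected.get(g, [])) for g in df.index
    ]
    df.to_csv(path, sep="\t", index_label="gene_id")


def default_config(**overrides) -> SimulationConfig:
    return replace(SimulationConfig(), **overrides)
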