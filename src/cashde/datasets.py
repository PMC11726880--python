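"""Core data containers and tabular I/O.

The pipeline operates on a normalized, log2-scale gene x sample expression
matrix together with a binary case/control assignment of the samples.  Both
live in :class:`ExpressionDataset`, a thin validated wrapper around a pandas
DataFrame.  Per-gene result tables are serialized as deterministic TSV via
:func:`write_deg_table` / :func:`read_deg_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

CASE = "case"
CONTROL = "control"

# Sample-sheet labels accepted as synonyms for the two groups.
_GROUP_SYNONYMS: dict[str, str] = {
    "case": CASE,
    "patient": CASE,
    "patients": CASE,
    "disease": CASE,
    "affected": CASE,
    "experimental": CASE,
    "control": CONTROL,
    "controls": CONTROL,
    "ctrl": CONTROL,
    "healthy": CONTROL,
    "normal": CONTROL,
    "reference": CONTROL,
}


@dataclass(frozen=True)
class ExpressionDataset:
    """Log2-scale expression matrix (genes x samples) with optional group labels.

    Parameters
    ----------
    values
        DataFrame with unique gene ids as index and unique sample ids as
        columns; all entries finite floats on the log2 scale.
    groups
        Optional mapping sample id -> ``"case"`` | ``"control"``, stored as a
        pandas Series aligned to ``values.columns``.  When present, each group
        must contain at least two samples.
    """

    values: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dup[:5]}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dup[:5]}")
        arr = v.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if arr.size and not np.isfinite(arr).all():
            n_bad = int((~np.isfinite(arr)).sum())
            raise ValidationError(
                f"expression matrix contains {n_bad} missing/non-finite values"
            )
        g = self.groups
        if g is not None:
            if not g.index.equals(v.columns):
                raise ValidationError("group labels do not cover exactly the samples")
            bad = sorted(set(g.unique()) - {CASE, CONTROL})
            if bad:
                raise ValidationError(f"unknown group labels: {bad}")
            counts = g.value_counts()
            for grp in (CASE, CONTROL):
                if counts.get(grp, 0) < 2:
                    raise ValidationError(
                        f"group {grp!r} has {counts.get(grp, 0)} samples; >=2 required"
                    )

    # -- accessors -----------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def _require_groups(self) -> pd.Series:
        if self.groups is None:
            raise ValidationError("dataset has no group labels; call attach_groups")
        return self.groups

    def group_samples(self, group: str) -> list[str]:
        g = self._require_groups()
        return list(g.index[g == group])

    @property
    def n_case(self) -> int:
        return len(self.group_samples(CASE))

    @property
    def n_control(self) -> int:
        return len(self.group_samples(CONTROL))

    def case_matrix(self) -> pd.DataFrame:
        return self.values[self.group_samples(CASE)]

    def control_matrix(self) -> pd.DataFrame:
        return self.values[self.group_samples(CONTROL)]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        """Restrict to the given genes, preserving the dataset's gene order."""
        keep = set(genes)
        missing = keep - set(self.values.index)
        if missing:
            raise ValidationError(f"unknown genes requested: {sorted(missing)[:5]}")
        idx = [g for g in self.values.index if g in keep]
        return ExpressionDataset(self.values.loc[idx], self.groups)

    def with_groups(self, groups: pd.Series) -> "ExpressionDataset":
        return ExpressionDataset(self.values, groups)


@dataclass(frozen=True)
class ControlReference:
    """Per-gene mean and sample SD (ddof=1) of the control-group expression."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index):
            raise ValidationError("control reference mean/sd indexed differently")
        if (self.sd.to_numpy() < 0).any():
            raise ValidationError("negative control standard deviation")


def read_expression_matrix(path: str | Path, log2_transform: bool = False) -> ExpressionDataset:
    """Read a TSV expression matrix (genes in rows, samples in columns).

    The first column holds gene ids, the header row sample ids, the body
    numeric expression values.  With ``log2_transform`` the raw intensities x
    are stored as log2(x + 1); otherwise values are taken to be log2 already.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.name is None and raw.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col].str.strip(), errors="coerce")
        bad = converted.isna() & (raw[col].str.strip() != "")
        if bad.any():
            gene = raw.index[bad.to_numpy()][0]
            raise ParseError(
                f"{path}: malformed numeric cell at gene {gene!r}, sample {col!r}: "
                f"{raw.loc[gene, col]!r}"
            )
        empty = raw[col].str.strip() == ""
        if empty.any():
            gene = raw.index[empty.to_numpy()][0]
            raise ValidationError(
                f"{path}: missing value at gene {gene!r}, sample {col!r}"
            )
        numeric[col] = converted
    if log2_transform:
        if (numeric.to_numpy() < 0).any():
            raise ValidationError(f"{path}: negative intensity under log2 transform")
        numeric = np.log2(numeric + 1.0)
    return ExpressionDataset(numeric)


def read_sample_sheet(path: str | Path) -> pd.Series:
    """Read a 2-column (sample_id, group) sheet; separator sniffed from header."""
    path = Path(path)
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    sheet = pd.read_csv(path, sep=sep, dtype=str)
    if sheet.shape[1] < 2:
        raise ParseError(f"{path}: sample sheet needs two columns (sample_id, group)")
    s = pd.Series(sheet.iloc[:, 1].values, index=sheet.iloc[:, 0].values)
    return s


def attach_groups(
    ds: ExpressionDataset, sheet: pd.Series | Mapping[str, str]
) -> ExpressionDataset:
    """Attach case/control labels from a sample sheet.

    Every dataset sample must appear exactly once; group synonyms such as
    "patient" or "healthy" are normalized to case/control.
    """
    s = pd.Series(dict(sheet)) if not isinstance(sheet, pd.Series) else sheet
    if s.index.has_duplicates:
        dup = s.index[s.index.duplicated()].unique().tolist()
        raise ValidationError(f"sample sheet lists samples more than once: {dup[:5]}")
    unknown = sorted(set(s.index) - set(ds.samples))
    if unknown:
        raise ValidationError(f"sample sheet names unknown samples: {unknown[:5]}")
    missing = sorted(set(ds.samples) - set(s.index))
    if missing:
        raise ValidationError(f"sample sheet missing samples: {missing[:5]}")
    normalized = {}
    for sample, label in s.items():
        key = str(label).strip().lower()
        if key not in _GROUP_SYNONYMS:
            raise ValidationError(f"unrecognized group label {label!r} for {sample!r}")
        normalized[sample] = _GROUP_SYNONYMS[key]
    groups = pd.Series([normalized[c] for c in ds.samples], index=ds.values.columns)
    return ds.with_groups(groups)


def write_expression_matrix(ds: ExpressionDataset, path: str | Path) -> None:
    """Write the matrix as TSV with full float precision (round-trip exact)."""
    ds.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def write_sample_sheet(ds: ExpressionDataset, path: str | Path) -> None:
    g = ds._require_groups()
    pd.DataFrame({"sample_id": g.index, "group": g.values}).to_csv(
        path, sep="\t", index=False
    )


# -- DEG tables --------------------------------------------------------------

DEG_TABLE_COLUMNS = [
    "gene",
    "method",
    "p",
    "q",
    "fold_change",
    "direction",
    "sig_raw_01",
    "sig_raw_05",
    "sig_fdr_05",
]
_DEG_FLOATS = ("p", "q", "fold_change")
_DEG_FLAGS = ("sig_raw_01", "sig_raw_05", "sig_fdr_05")


@dataclass(frozen=True)
class DegTable:
    """Long-format per-gene, per-method result table for serialization.

    Each row carries a raw p, BH q, signed fold change, an up/down direction
    (empty unless some significance flag is set) and the three significance
    flags used in the count summaries.
    """

    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=DEG_TABLE_COLUMNS))

    def __post_init__(self) -> None:
        df = self.rows
        if list(df.columns) != DEG_TABLE_COLUMNS:
            raise ValidationError(
                f"DEG table columns must be {DEG_TABLE_COLUMNS}, got {list(df.columns)}"
            )
        if len(df):
            for col in ("p", "q"):
                vals = df[col].to_numpy(dtype=float)
                if ((vals <= 0) | (vals > 1)).any():
                    raise ValidationError(f"{col} values must lie in (0, 1]")
            bad_dir = ~df["direction"].isin(["up", "down", ""])
            if bad_dir.any():
                raise ValidationError("direction must be 'up', 'down' or empty")
            flagged = df[list(_DEG_FLAGS)].astype(bool).any(axis=1)
            if ((df["direction"] == "") & flagged).any():
                raise ValidationError("flagged rows must carry a direction")
            if ((df["direction"] != "") & ~flagged).any():
                raise ValidationError("direction present on unflagged row")

    def sorted(self) -> pd.DataFrame:
        return self.rows.sort_values(["gene", "method"], kind="mergesort").reset_index(drop=True)


def write_deg_table(table: DegTable, path: str | Path) -> None:
    """Serialize as TSV: fixed column order, 6 significant digits, sorted rows."""
    df = table.sorted().copy()
    for col in _DEG_FLOATS:
        df[col] = [f"{float(x):.6g}" for x in df[col]]
    for col in _DEG_FLAGS:
        df[col] = df[col].astype(bool).map({True: "1", False: "0"})
    df.to_csv(path, sep="\t", index=False)


def read_deg_table(path: str | Path) -> DegTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != DEG_TABLE_COLUMNS:
        raise ParseError(f"{path}: unexpected DEG table header {list(df.columns)}")
    for col in _DEG_FLOATS:
        df[col] = df[col].astype(float)
    for col in _DEG_FLAGS:
        df[col] = df[col].map({"1": True, "0": False})
        if df[col].isna().any():
            raise ParseError(f"{path}: non-boolean flag in column {col}")
    return DegTable(df)
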