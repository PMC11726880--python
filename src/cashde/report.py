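"""Count summaries, DEG-set overlaps and reproducibility manifests."""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__
from .errors import ValidationError


@dataclass(frozen=True)
class MethodCountRow:
    """One dataset's DEG counts per method, Table-style.

    CASh cells carry up/down breakdowns; up + down must equal the total.
    """

    label: str
    welch_fdr05: int
    ebayes_fdr01: int
    ebayes_fdr05: int
    cash05_fdr: tuple[int, int]  # (up, down) at preselection 0.05, BH < fdr_alpha
    cash01_raw: tuple[int, int]
    cash05_raw: tuple[int, int]

    def __post_init__(self) -> None:
        for name in ("welch_fdr05", "ebayes_fdr01", "ebayes_fdr05"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} count negative")
        for name in ("cash05_fdr", "cash01_raw", "cash05_raw"):
            up, down = getattr(self, name)
            if up < 0 or down < 0:
                raise ValidationError(f"{name} up/down counts negative")


def _cash_cell(results: pd.DataFrame, flag: str) -> tuple[int, int]:
    if results.empty:
        return (0, 0)
    sig = results[results[flag].astype(bool)]
    return (
        int((sig["direction"] == "up").sum()),
        int((sig["direction"] == "down").sum()),
    )


def summarize_counts(
    label: str,
    classical: pd.DataFrame,
    cash_by_alpha: Mapping[float, pd.DataFrame],
    fdr_alpha: float = 0.05,
) -> MethodCountRow:
    """Recompute Table-style DEG counts from the stored per-gene flags.

    ``classical`` is the output of :func:`cashde.classical.classical_results`;
    ``cash_by_alpha`` maps preselection alpha (0.01 / 0.05) to CASh results.
    All result tables must come from the same gene universe.
    """
    universes = {
        frozenset(r["gene"]) if "gene" in r else frozenset(r.index)
        for r in cash_by_alpha.values()
        if len(r)
    }
    full = frozenset(classical.index)
    for u in universes:
        if not u <= full:
            raise ValidationError("CASh results name genes absent from classical table")
    cash01 = cash_by_alpha.get(0.01, pd.DataFrame())
    cash05 = cash_by_alpha.get(0.05, pd.DataFrame())
    return MethodCountRow(
        label=label,
        welch_fdr05=int((classical["q_welch"] < fdr_alpha).sum()),
        ebayes_fdr01=int((classical["q_ebayes"] < 0.01).sum()),
        ebayes_fdr05=int((classical["q_ebayes"] < fdr_alpha).sum()),
        cash05_fdr=_cash_cell(cash05, "sig_fdr"),
        cash01_raw=_cash_cell(cash01, "sig_raw"),
        cash05_raw=_cash_cell(cash05, "sig_raw"),
    )


def format_count_table(rows: Iterable[MethodCountRow], ascii_arrows: bool = False) -> str:
    """Render rows as TSV with "total (x ↑, y ↓)" CASh cells."""
    up, down = ("up", "down") if ascii_arrows else ("↑", "↓")

    def cell(pair: tuple[int, int]) -> str:
        u, d = pair
        return f"{u + d} ({u} {up}, {d} {down})"

    header = [
        "dataset",
        "welch_fdr05",
        "ebayes_fdr01",
        "ebayes_fdr05",
        "cash05_fdr",
        "cash01_raw",
        "cash05_raw",
    ]
    lines = ["\t".join(header)]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r.label,
                    str(r.welch_fdr05),
                    str(r.ebayes_fdr01),
                    str(r.ebayes_fdr05),
                    cell(r.cash05_fdr),
                    cell(r.cash01_raw),
                    cell(r.cash05_raw),
                ]
            )
        )
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class OverlapReport:
    """Shared DEG identifiers for every combination of >=2 named sets."""

    overlaps: dict[tuple[str, ...], list[str]] = field(default_factory=dict)

    def size(self, names: tuple[str, ...]) -> int:
        return len(self.overlaps[tuple(sorted(names))])


def deg_overlap(deg_lists) -> OverlapReport:
    """Exact intersections for every combination of two or more named sets.

    Accepts a mapping name -> iterable of gene ids, or an iterable of
    (name, ids) pairs; duplicate names are rejected.
    """
    if isinstance(deg_lists, Mapping):
        pairs = list(deg_lists.items())
    else:
        pairs = list(deg_lists)
    names = [n for n, _ in pairs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate DEG-set names")
    if len(pairs) < 2:
        raise ValidationError("overlap needs >=2 named sets")
    sets = {n: set(ids) for n, ids in pairs}
    out: dict[tuple[str, ...], list[str]] = {}
    for r in range(2, len(names) + 1):
        for combo in combinations(sorted(names), r):
            shared = set.intersection(*(sets[n] for n in combo))
            out[combo] = sorted(shared)
    return OverlapReport(out)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_manifest(
    config: Mapping, seed: int, inputs: Mapping[str, str], outputs: Mapping[str, str]
) -> dict:
    """JSON-serializable record sufficient to reproduce a run bit-for-bit."""
    return {
        "tool": "cashde",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": int(seed),
        "config": dict(config),
        "input_digests": {name: _digest(p) for name, p in inputs.items()},
        "output_digests": {name: _digest(p) for name, p in outputs.items()},
    }


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
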