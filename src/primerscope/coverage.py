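"""Taxonomy-resolved coverage tables and primer-pair comparisons.

Coverage of a primer pair at a taxon is the percentage of that taxon's
reference records for which an amplicon would form.  Tables are computed
per rank, with an explicit ``unclassified`` bin for records lacking an
annotation at the queried rank — those records are excluded from named
taxon denominators but never silently dropped.  Pair comparisons report
percentage-point deltas (B − A); an empty taxon's coverage is *undefined*,
which is distinct from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pcr import PrimerPair, covered
from .refdb import RANKS, RefSet, subset_by_taxon

__all__ = [
    "UNCLASSIFIED",
    "CoverageRow",
    "CoverageTable",
    "DeltaRow",
    "CoverageDelta",
    "coverage_by_rank",
    "compare_primer_pairs",
    "lineage_drilldown",
]

#: bin label for records lacking an annotation at the queried rank
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class CoverageRow:
    taxon: str
    total: int
    matched: int

    @property
    def coverage_pct(self) -> float:
        """100·matched/total; NaN (undefined) for an empty taxon."""
        return 100.0 * self.matched / self.total if self.total else math.nan


@dataclass(frozen=True)
class CoverageTable:
    rank: str
    rows: tuple[CoverageRow, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": [r.taxon for r in self.rows],
                "total": [r.total for r in self.rows],
                "matched": [r.matched for r in self.rows],
                "coverage_pct": [r.coverage_pct for r in self.rows],
            }
        )

    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        _write_tsv(self.to_frame(), path, header_lines)

    def __getitem__(self, taxon: str) -> CoverageRow:
        for r in self.rows:
            if r.taxon == taxon:
                return r
        raise KeyError(taxon)


@dataclass(frozen=True)
class DeltaRow:
    rank: str
    taxon: str
    total: int
    coverage_pct_a: float
    coverage_pct_b: float

    @property
    def delta_pct(self) -> float:
        """B − A in percentage points; NaN when undefined (empty taxon)."""
        return self.coverage_pct_b - self.coverage_pct_a

    @property
    def defined(self) -> bool:
        return self.total > 0


@dataclass(frozen=True)
class CoverageDelta:
    rank: str
    rows: tuple[DeltaRow, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": [r.rank for r in self.rows],
                "taxon": [r.taxon for r in self.rows],
                "total": [r.total for r in self.rows],
                "coverage_pct_a": [r.coverage_pct_a for r in self.rows],
                "coverage_pct_b": [r.coverage_pct_b for r in self.rows],
                "delta_pct": [r.delta_pct for r in self.rows],
                "defined": [r.defined for r in self.rows],
            }
        )

    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        _write_tsv(self.to_frame(), path, header_lines)

    def __getitem__(self, taxon: str) -> DeltaRow:
        for r in self.rows:
            if r.taxon == taxon:
                return r
        raise KeyError(taxon)


def _write_tsv(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def _taxon_of(rec, rank: str) -> str:
    name = rec.lineage.get(rank)
    return name if name is not None else UNCLASSIFIED


def _counts_by_taxon(refset: RefSet, flags: np.ndarray, rank: str) -> dict[str, tuple[int, int]]:
    counts: dict[str, list[int]] = {}
    for rec, flag in zip(refset, flags):
        taxon = _taxon_of(rec, rank)
        tm = counts.setdefault(taxon, [0, 0])
        tm[0] += 1
        tm[1] += int(flag)
    return {k: (v[0], v[1]) for k, v in counts.items()}


def coverage_by_rank(
    pair: PrimerPair,
    refset: RefSet,
    rank: str,
    max_mismatch: int = 0,
    mode: str = "pair",
) -> CoverageTable:
    """Per-taxon coverage at one rank: one row per name present at that
    rank plus the ``unclassified`` bin (always emitted, possibly empty).

    ``mode`` is forwarded to :func:`primerscope.pcr.covered` — ``"pair"``
    (amplicon formation, default) or per-primer ``"forward"``/``"reverse"``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; ladder: {RANKS}")
    flags = covered(pair, refset, max_mismatch, mode=mode)
    counts = _counts_by_taxon(refset, flags, rank)
    named = sorted(t for t in counts if t != UNCLASSIFIED)
    rows = [CoverageRow(t, *counts[t]) for t in named]
    uncl = counts.get(UNCLASSIFIED, (0, 0))
    rows.append(CoverageRow(UNCLASSIFIED, *uncl))
    return CoverageTable(rank=rank, rows=tuple(rows))


def compare_primer_pairs(
    pair_a: PrimerPair,
    pair_b: PrimerPair,
    refset: RefSet,
    rank: str,
    max_mismatch: int = 0,
    min_delta_pct: float = 0.0,
    mode: str = "pair",
) -> CoverageDelta:
    """Joined per-taxon coverage deltas (B − A, percentage points) at one
    rank, filtered to |delta| >= ``min_delta_pct`` and sorted by descending
    delta (ties by taxon name).

    ``min_delta_pct=25`` reproduces the conventional "show only taxa whose
    coverage changed by more than 25 points" display rule.
    """
    ta = coverage_by_rank(pair_a, refset, rank, max_mismatch, mode)
    tb = coverage_by_rank(pair_b, refset, rank, max_mismatch, mode)
    by_taxon_b = {r.taxon: r for r in tb.rows}
    rows = []
    for ra in ta.rows:
        rb = by_taxon_b[ra.taxon]
        row = DeltaRow(rank, ra.taxon, ra.total, ra.coverage_pct, rb.coverage_pct)
        if row.defined and abs(row.delta_pct) >= min_delta_pct:
            rows.append(row)
    rows.sort(key=lambda r: (-r.delta_pct, r.taxon))
    return CoverageDelta(rank=rank, rows=tuple(rows))


def lineage_drilldown(
    pair_a: PrimerPair,
    pair_b: PrimerPair,
    refset: RefSet,
    lineage_path: list[tuple[str, str]],
    max_mismatch: int = 0,
    mode: str = "pair",
) -> list[DeltaRow]:
    """Coverage deltas along a root-to-genus path, one row per rank.

    ``lineage_path`` is an ordered list of (rank, name) pairs in ladder
    order, e.g. phylum Planctomycetes → class Planctomycetia → ... → genus.
    A name absent from the refset yields a row with total 0 flagged
    undefined, not an error.
    """
    order = {r: i for i, r in enumerate(RANKS)}
    last = -1
    for rank, _ in lineage_path:
        if rank not in order:
            raise ValueError(f"unknown rank {rank!r}")
        if order[rank] <= last:
            raise ValueError("lineage_path ranks must be strictly descending the ladder")
        last = order[rank]

    rows = []
    for rank, name in lineage_path:
        sub = subset_by_taxon(refset, rank, name)
        total = len(sub)
        if total:
            pct_a = 100.0 * int(covered(pair_a, sub, max_mismatch, mode=mode).sum()) / total
            pct_b = 100.0 * int(covered(pair_b, sub, max_mismatch, mode=mode).sum()) / total
        else:
            pct_a = pct_b = math.nan
        rows.append(DeltaRow(rank, name, total, pct_a, pct_b))
    return rows
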