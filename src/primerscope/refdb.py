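"""Taxonomically annotated 16S reference sets: I/O, filtering, taxonomy model.

A reference set is a collection of rRNA sequences, each carrying a lineage
over the fixed six-rank ladder kingdom > phylum > class > order > family >
genus.  Two annotation dialects are read:

* ``header`` — RDP-style FASTA headers embedding
  ``Lineage=Root;rootrank;Bacteria;domain;...`` name/rank pairs.  Unofficial
  intermediate ranks (subclass, suborder, ...) are dropped when mapping onto
  the six-rank ladder.
* a sidecar TSV — two columns, ``seq_id<TAB>k__...;p__...;c__...;o__...;
  f__...;g__...`` (rank-prefixed, semicolon-separated).

Records whose lineage cannot be parsed are kept with an empty lineage and
counted in the parse report; sequence characters outside the IUPAC alphabet
are replaced by N (counted, warned) so that a single corrupt record cannot
abort a whole-database run.  Duplicate FASTA ids, by contrast, are fatal.

Quality filtering follows the convention of keeping only near-full-length
records: strictly greater than 1200 bp by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO

from .iupac import IUPAC_CODES

logger = logging.getLogger(__name__)

__all__ = [
    "RANKS",
    "TaxonomyLineage",
    "RefSeq",
    "RefSet",
    "ParseReport",
    "read_refset",
    "write_refset",
    "filter_high_quality",
    "subset_by_taxon",
]

#: the rank ladder, shallowest first
RANKS: tuple[str, ...] = ("kingdom", "phylum", "class", "order", "family", "genus")

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

# RDP header rank names -> ladder ranks; anything unmapped (rootrank,
# subclass, suborder, ...) is dropped.
_RDP_RANK_MAP = {
    "domain": "kingdom",
    "kingdom": "kingdom",
    "phylum": "phylum",
    "class": "class",
    "order": "order",
    "family": "family",
    "genus": "genus",
}

_TSV_PREFIX_MAP = {
    "k": "kingdom",
    "d": "kingdom",
    "sk": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
}

_VALID_SEQ_CHARS = frozenset(IUPAC_CODES) | {"U"}


def _norm_name(name: str) -> str:
    """Trim and collapse internal whitespace; 'Candidatus' stays part of
    the name."""
    return " ".join(name.split())


@dataclass(frozen=True)
class TaxonomyLineage:
    """Rank->name assignment over the six-rank ladder.

    ``names`` is a 6-tuple aligned with :data:`RANKS`; a ``None`` at one
    rank implies ``None`` at all deeper ranks (enforced by truncation).
    """

    names: tuple[str | None, ...] = (None,) * 6

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(f"lineage must cover {len(RANKS)} ranks, got {len(self.names)}")
        cleaned: list[str | None] = []
        seen_gap = False
        for n in self.names:
            if n is not None:
                n = _norm_name(str(n)) or None
            if n is None:
                seen_gap = True
            cleaned.append(None if seen_gap else n)
        object.__setattr__(self, "names", tuple(cleaned))

    @classmethod
    def from_dict(cls, mapping: dict[str, str]) -> "TaxonomyLineage":
        unknown = set(mapping) - set(RANKS)
        if unknown:
            raise ValueError(f"unknown ranks: {sorted(unknown)}")
        return cls(tuple(mapping.get(r) for r in RANKS))

    @classmethod
    def from_prefixed(cls, text: str) -> "TaxonomyLineage":
        """Parse ``k__Bacteria;p__Planctomycetes;...`` (missing or empty
        fields allowed)."""
        names: dict[str, str] = {}
        for token in text.split(";"):
            token = token.strip()
            if not token or "__" not in token:
                continue
            prefix, _, name = token.partition("__")
            rank = _TSV_PREFIX_MAP.get(prefix.strip().lower())
            if rank is None or not name.strip():
                continue
            names.setdefault(rank, name)
        return cls.from_dict(names)

    @classmethod
    def from_rdp_header(cls, description: str) -> "TaxonomyLineage":
        """Parse an RDP-dialect header containing
        ``Lineage=Root;rootrank;Bacteria;domain;...`` name/rank pairs."""
        marker = "Lineage="
        idx = description.find(marker)
        if idx < 0:
            raise ValueError("no Lineage= field in header")
        tokens = [t.strip().strip('"') for t in description[idx + len(marker):].split(";")]
        names: dict[str, str] = {}
        for name, rank in zip(tokens[::2], tokens[1::2]):
            ladder_rank = _RDP_RANK_MAP.get(rank.strip().lower())
            if ladder_rank is not None and name:
                names.setdefault(ladder_rank, name)
        return cls.from_dict(names)

    def get(self, rank: str) -> str | None:
        try:
            return self.names[_RANK_INDEX[rank]]
        except KeyError:
            raise ValueError(f"unknown rank {rank!r}; ladder: {RANKS}") from None

    def to_prefixed(self) -> str:
        prefixes = ("k", "p", "c", "o", "f", "g")
        return ";".join(f"{p}__{n if n is not None else ''}" for p, n in zip(prefixes, self.names))

    def to_rdp_header(self) -> str:
        rdp_ranks = ("domain", "phylum", "class", "order", "family", "genus")
        parts = ["Root", "rootrank"]
        for name, rank in zip(self.names, rdp_ranks):
            if name is None:
                break
            parts += [name, rank]
        return "Lineage=" + ";".join(parts)

    @property
    def empty(self) -> bool:
        return all(n is None for n in self.names)


EMPTY_LINEAGE = TaxonomyLineage()


@dataclass(frozen=True)
class RefSeq:
    """One reference sequence with its lineage annotation."""

    id: str
    sequence: str
    lineage: TaxonomyLineage = EMPTY_LINEAGE

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ParseReport:
    """Counts accumulated while reading a reference set."""

    n_records: int = 0
    n_lineage_failures: int = 0
    n_orphan_tsv_ids: int = 0
    n_char_replacements: int = 0

    def to_tsv(self, path: str | Path) -> None:
        lines = ["metric\tcount"]
        lines += [
            f"records\t{self.n_records}",
            f"lineage_failures\t{self.n_lineage_failures}",
            f"orphan_tsv_ids\t{self.n_orphan_tsv_ids}",
            f"char_replacements\t{self.n_char_replacements}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class RefSet:
    """An ordered collection of :class:`RefSeq` with unique ids."""

    records: tuple[RefSeq, ...]
    provenance: str = ""
    report: ParseReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise ValueError(f"duplicate sequence id {r.id!r}")
            seen.add(r.id)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def _sanitize_sequence(seq: str) -> tuple[str, int]:
    """Upper-case, U->T; anything outside the IUPAC alphabet becomes N.
    Returns the clean sequence and the replacement count."""
    out = []
    replaced = 0
    for ch in seq.upper():
        if ch == "U":
            out.append("T")
        elif ch in IUPAC_CODES:
            out.append(ch)
        else:
            out.append("N")
            replaced += 1
    return "".join(out), replaced


def read_refset(
    fasta_path: str | Path,
    taxonomy: str | Path = "header",
    provenance: str | None = None,
) -> RefSet:
    """Read a FASTA reference set with lineage annotations.

    Parameters
    ----------
    fasta_path:
        Multi-record FASTA.  Duplicate ids are fatal.
    taxonomy:
        ``"header"`` for the RDP header dialect, or the path of a two-column
        sidecar TSV (``seq_id<TAB>rank-prefixed lineage``).  TSV ids absent
        from the FASTA are recorded as orphans, not errors; FASTA records
        without a parsable lineage keep an empty lineage and are counted.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)

    sidecar: dict[str, TaxonomyLineage] | None = None
    n_failures = 0
    if taxonomy != "header":
        tsv_path = Path(taxonomy)
        if not tsv_path.exists():
            raise FileNotFoundError(tsv_path)
        sidecar = {}
        for line in tsv_path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1].strip():
                continue  # malformed: its record falls through to a lineage failure
            lin = TaxonomyLineage.from_prefixed(parts[1])
            if lin.empty:
                continue
            sidecar[parts[0].strip()] = lin

    records: list[RefSeq] = []
    n_replaced = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq, repl = _sanitize_sequence(str(rec.seq))
        n_replaced += repl
        if sidecar is not None:
            lineage = sidecar.get(rec.id)
            if lineage is None:
                lineage = EMPTY_LINEAGE
                n_failures += 1
        else:
            try:
                lineage = TaxonomyLineage.from_rdp_header(rec.description)
            except ValueError:
                lineage = EMPTY_LINEAGE
                n_failures += 1
        records.append(RefSeq(rec.id, seq, lineage))

    n_orphans = 0
    if sidecar is not None:
        fasta_ids = {r.id for r in records}
        n_orphans = sum(1 for sid in sidecar if sid not in fasta_ids)
        if n_orphans:
            logger.warning("%d taxonomy TSV ids not present in FASTA", n_orphans)
    if n_replaced:
        logger.warning("%d non-IUPAC sequence characters replaced by N", n_replaced)

    report = ParseReport(
        n_records=len(records),
        n_lineage_failures=n_failures,
        n_orphan_tsv_ids=n_orphans,
        n_char_replacements=n_replaced,
    )
    return RefSet(
        records=tuple(records),
        provenance=provenance if provenance is not None else str(fasta_path),
        report=report,
    )


def write_refset(
    refset: RefSet,
    fasta_path: str | Path,
    taxonomy_tsv_path: str | Path | None = None,
    line_width: int = 70,
) -> None:
    """Write a reference set as FASTA plus (optionally) the sidecar
    taxonomy TSV, byte-deterministically."""
    with open(fasta_path, "w") as fh:
        for rec in refset:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")
    if taxonomy_tsv_path is not None:
        with open(taxonomy_tsv_path, "w") as fh:
            for rec in refset:
                fh.write(f"{rec.id}\t{rec.lineage.to_prefixed()}\n")


def filter_high_quality(refset: RefSet, min_len: int = 1200) -> RefSet:
    """Keep records strictly longer than ``min_len`` nucleotides."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = tuple(r for r in refset if r.length > min_len)
    return replace(refset, records=kept)


def subset_by_taxon(refset: RefSet, rank: str, name: str) -> RefSet:
    """Records annotated with exactly ``name`` at ``rank`` (exact string
    match after whitespace normalization; case-sensitive)."""
    if rank not in _RANK_INDEX:
        raise ValueError(f"unknown rank {rank!r}; ladder: {RANKS}")
    target = _norm_name(name)
    kept = tuple(r for r in refset if r.lineage.get(rank) == target)
    return replace(refset, records=kept)
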