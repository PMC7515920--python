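"""Degenerate-primer matching and in-silico amplicon simulation.

The matching rule is set-intersection over IUPAC base sets: primer code P
matches subject code S at a position iff base_set(P) and base_set(S) share
at least one base.  A window *hit* is a placement of the primer whose count
of non-intersecting positions does not exceed the mismatch allowance
(0 by default — the strictest, publication-style setting).  Subject
ambiguity codes expand exactly like primer codes; an optional strict mode
instead counts any non-ACGT subject character as a mismatch, for comparison
with tools that do not expand subject ambiguities.

An amplicon forms on a (plus-strand oriented) reference sequence when the
forward primer hits the plus strand and the reverse primer hits the minus
strand strictly downstream.  Amplicon length is measured from the forward
primer's 5' start to the reverse primer's 5' start on the plus strand,
inclusive of both primer footprints — the convention under which the
V3–V4 341F/805R product is ~465 nt.

Coordinates are 0-based half-open internally and 1-based inclusive in
written reports.  Matching is vectorized over 4-bit base masks, so sliding
a 17-mer over a full-length 16S record costs one numpy pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .iupac import IUPAC_CODES, Primer, reverse_complement, _as_primer
from .refdb import RefSeq, RefSet

__all__ = [
    "PrimerPair",
    "PrimerHit",
    "AmpliconHit",
    "encode_sequence",
    "mismatches_at",
    "find_hits",
    "simulate_amplicon",
    "covered",
    "primer_covered",
    "extract_amplicons",
    "write_amplicon_report",
]

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

_LUT_INTERSECT = np.zeros(256, dtype=np.uint8)
_LUT_STRICT = np.zeros(256, dtype=np.uint8)
for _sym, _bases in IUPAC_CODES.items():
    _mask = 0
    for _b in _bases:
        _mask |= _BASE_BIT[_b]
    for _c in (_sym, _sym.lower()):
        _LUT_INTERSECT[ord(_c)] = _mask
        if _sym in "ACGT":
            _LUT_STRICT[ord(_c)] = _mask
for _c in "uU":
    _LUT_INTERSECT[ord(_c)] = _BASE_BIT["T"]
    _LUT_STRICT[ord(_c)] = _BASE_BIT["T"]
# unknown characters: fully permissive in intersection mode (refdb already
# maps them to N), always-mismatch in strict-subject mode
_LUT_INTERSECT[_LUT_INTERSECT == 0] = 15


def encode_sequence(sequence: str, strict_subject: bool = False) -> np.ndarray:
    """Encode a subject sequence as a uint8 array of 4-bit base masks."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    lut = _LUT_STRICT if strict_subject else _LUT_INTERSECT
    return lut[raw]


def _primer_mask(primer: Primer | str) -> np.ndarray:
    p = _as_primer(primer)
    return _LUT_INTERSECT[np.frombuffer(p.sequence.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with amplicon-length bounds.

    Both primers are written 5'->3' as conventionally published; the
    reverse primer anneals to the minus strand.  Length bounds are loose
    guards against pathological self-priming, not a product-size model.
    """

    forward: Primer
    reverse: Primer
    min_amplicon_len: int = 50
    max_amplicon_len: int = 2000

    def __post_init__(self) -> None:
        if not (0 < self.min_amplicon_len <= self.max_amplicon_len):
            raise ValueError(
                f"invalid amplicon bounds [{self.min_amplicon_len}, {self.max_amplicon_len}]"
            )

    @property
    def name(self) -> str:
        return f"{self.forward.name}+{self.reverse.name}"


@dataclass(frozen=True)
class PrimerHit:
    """A primer placement on the plus strand of a subject sequence."""

    seq_id: str
    start: int  # 0-based inclusive, plus-strand coordinates
    end: int  # exclusive
    strand: str  # "+" or "-"
    mismatches: int

    @property
    def five_prime_plus(self) -> int:
        """Plus-strand position of the primer's 5' end (0-based)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class AmpliconHit:
    """A forward/reverse hit combination that would yield a PCR product."""

    seq_id: str
    forward_hit: PrimerHit
    reverse_hit: PrimerHit
    amplicon_len: int


def mismatches_at(
    primer: Primer | str,
    sequence: str | np.ndarray,
    pos: int,
    strict_subject: bool = False,
) -> int:
    """Mismatch count of the primer placed at ``pos`` (0-based) on the plus
    strand: positions where the primer and subject base sets are disjoint."""
    pmask = _primer_mask(primer)
    enc = sequence if isinstance(sequence, np.ndarray) else encode_sequence(sequence, strict_subject)
    if pos < 0 or pos + len(pmask) > len(enc):
        raise ValueError(
            f"window [{pos}, {pos + len(pmask)}) out of bounds for sequence of length {len(enc)}"
        )
    window = enc[pos : pos + len(pmask)]
    return int(np.count_nonzero((window & pmask) == 0))


def find_hits(
    primer: Primer | str,
    sequence: str | np.ndarray,
    max_mismatch: int = 0,
    strand: str = "+",
    strict_subject: bool = False,
    seq_id: str = "",
) -> list[PrimerHit]:
    """All placements of the primer on the given strand with at most
    ``max_mismatch`` mismatches, sorted by plus-strand start.

    For the minus strand the reverse complement of the primer is slid along
    the plus strand, so coordinates always refer to the plus strand.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    p = _as_primer(primer)
    query = reverse_complement(p) if strand == "-" else p
    pmask = _primer_mask(query)
    enc = sequence if isinstance(sequence, np.ndarray) else encode_sequence(sequence, strict_subject)
    L = len(pmask)
    if len(enc) < L:
        return []
    windows = sliding_window_view(enc, L)
    mm = np.count_nonzero((windows & pmask) == 0, axis=1)
    starts = np.nonzero(mm <= max_mismatch)[0]
    return [
        PrimerHit(seq_id=seq_id, start=int(s), end=int(s) + L, strand=strand, mismatches=int(mm[s]))
        for s in starts
    ]


def simulate_amplicon(
    pair: PrimerPair,
    refseq: RefSeq,
    max_mismatch: int = 0,
    strict_subject: bool = False,
) -> list[AmpliconHit]:
    """All forward/reverse hit combinations forming an in-bounds amplicon.

    The reverse site must start strictly downstream of the forward site's
    5' start; amplicon length is ``reverse 5' start − forward 5' start + 1``
    on the plus strand.  A record is *covered* iff this list is nonempty.
    """
    enc = encode_sequence(refseq.sequence, strict_subject)
    fwd_hits = find_hits(pair.forward, enc, max_mismatch, "+", seq_id=refseq.id)
    if not fwd_hits:
        return []
    rev_hits = find_hits(pair.reverse, enc, max_mismatch, "-", seq_id=refseq.id)
    out: list[AmpliconHit] = []
    for fh in fwd_hits:
        for rh in rev_hits:
            if rh.start <= fh.start:
                continue
            amplicon_len = rh.five_prime_plus - fh.start + 1  # == rh.end - fh.start
            if pair.min_amplicon_len <= amplicon_len <= pair.max_amplicon_len:
                out.append(AmpliconHit(refseq.id, fh, rh, amplicon_len))
    return out


def covered(
    pair: PrimerPair,
    refset: RefSet,
    max_mismatch: int = 0,
    mode: str = "pair",
    strict_subject: bool = False,
) -> np.ndarray:
    """Per-record coverage flags, in refset iteration order.

    ``mode`` selects the coverage definition: ``"pair"`` requires amplicon
    formation (the default selection metric), ``"forward"``/``"reverse"``
    require only the corresponding single-primer site.
    """
    if mode not in ("pair", "forward", "reverse"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    flags = np.zeros(len(refset), dtype=bool)
    for i, rec in enumerate(refset):
        if mode == "pair":
            flags[i] = bool(simulate_amplicon(pair, rec, max_mismatch, strict_subject))
        elif mode == "forward":
            flags[i] = bool(
                find_hits(pair.forward, rec.sequence, max_mismatch, "+", strict_subject)
            )
        else:
            flags[i] = bool(
                find_hits(pair.reverse, rec.sequence, max_mismatch, "-", strict_subject)
            )
    return flags


def primer_covered(
    primer: Primer | str,
    refset: RefSet,
    max_mismatch: int = 0,
    strand: str = "+",
    strict_subject: bool = False,
) -> np.ndarray:
    """Per-record single-primer coverage flags on the given strand."""
    return np.array(
        [
            bool(find_hits(primer, rec.sequence, max_mismatch, strand, strict_subject))
            for rec in refset
        ],
        dtype=bool,
    )


def extract_amplicons(hits: list[AmpliconHit], refset: RefSet) -> list[tuple[str, str]]:
    """Amplicon sequences (primer footprints included) as (label, sequence)
    pairs, ready for FASTA output."""
    by_id = {rec.id: rec for rec in refset}
    out = []
    for h in hits:
        rec = by_id[h.seq_id]
        seq = rec.sequence[h.forward_hit.start : h.reverse_hit.end]
        label = f"{h.seq_id}_{h.forward_hit.start + 1}_{h.reverse_hit.end}"
        out.append((label, seq))
    return out


def write_amplicon_report(hits: list[AmpliconHit], path: str | Path, header_lines: list[str] | None = None) -> None:
    """TSV report of amplicon hits, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("seq_id\tfwd_start\tfwd_end\tfwd_mm\trev_start\trev_end\trev_mm\tamplicon_len\n")
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.forward_hit.start + 1}\t{h.forward_hit.end}\t"
                f"{h.forward_hit.mismatches}\t{h.reverse_hit.start + 1}\t{h.reverse_hit.end}\t"
                f"{h.reverse_hit.mismatches}\t{h.amplicon_len}\n"
            )
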