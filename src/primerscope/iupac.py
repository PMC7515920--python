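"""IUPAC nucleotide ambiguity-code algebra.

Universal rRNA primers are written in the IUPAC degenerate alphabet, in
which a single symbol denotes a nonempty subset of {A, C, G, T}: W means
A or T, S means C or G, N means any base, and so on.  A degenerate primer
is therefore a compact notation for a pool of concrete oligonucleotides
(its *expansions*), and its *degeneracy* — the size of that pool — is the
natural parsimony cost when deciding how far to widen a primer.

This module provides the base-set algebra everything else builds on:
symbol expansion, minimal-code lookup (the inverse table), Watson–Crick
complementation, reverse complement, degeneracy, and explicit enumeration
of the expansion pool.  Inputs are case-insensitive and RNA-style ``U`` is
accepted as ``T``; anything else fails loudly with the offending symbol
and position, because a corrupted primer must never be silently repaired.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

__all__ = [
    "IUPAC_CODES",
    "InvalidAlphabetError",
    "TooDegenerateError",
    "Primer",
    "expand_code",
    "code_for",
    "complement_code",
    "reverse_complement",
    "degeneracy",
    "enumerate_expansions",
]

#: symbol -> denoted base set, for all 15 IUPAC nucleotide codes
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_CODE_FOR: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}
_COMPLEMENT_BASE = {"A": "T", "T": "A", "C": "G", "G": "C"}


class InvalidAlphabetError(ValueError):
    """A character outside the IUPAC nucleotide alphabet was encountered."""

    def __init__(self, symbol: str, position: int | None = None, context: str = ""):
        self.symbol = symbol
        self.position = position
        where = f" at position {position}" if position is not None else ""
        src = f" in {context}" if context else ""
        super().__init__(f"invalid IUPAC symbol {symbol!r}{where}{src}")


class TooDegenerateError(ValueError):
    """Expansion was requested for a primer whose pool exceeds the cap."""


def _canonical_symbol(symbol: str, position: int | None = None, context: str = "") -> str:
    s = symbol.upper()
    if s == "U":  # rRNA-derived records
        s = "T"
    if s not in IUPAC_CODES:
        raise InvalidAlphabetError(symbol, position, context)
    return s


def expand_code(symbol: str) -> frozenset[str]:
    """Return the base set denoted by an IUPAC symbol (case-insensitive)."""
    return IUPAC_CODES[_canonical_symbol(symbol)]


def code_for(bases) -> str:
    """Return the unique minimal IUPAC code for a nonempty subset of {A,C,G,T}.

    Inverse of :func:`expand_code`: ``code_for(expand_code(x)) == x`` for
    every canonical code.
    """
    bs = frozenset(b.upper() for b in bases)
    if not bs:
        raise ValueError("code_for: empty base set has no IUPAC code")
    try:
        return _CODE_FOR[bs]
    except KeyError:
        bad = sorted(bs - frozenset("ACGT"))
        raise InvalidAlphabetError(bad[0] if bad else "".join(sorted(bs))) from None


def complement_code(symbol: str) -> str:
    """Watson–Crick complement of a code: the code whose base set is the
    complement of the input's base set.  An involution on all 15 codes."""
    bs = expand_code(symbol)
    return _CODE_FOR[frozenset(_COMPLEMENT_BASE[b] for b in bs)]


@dataclass(frozen=True)
class Primer:
    """A named primer in the IUPAC alphabet, written 5'->3'.

    The sequence is canonicalized on construction (upper case, U->T) and
    validated character by character.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        canon = []
        for i, ch in enumerate(self.sequence):
            canon.append(_canonical_symbol(ch, position=i + 1, context=f"primer {self.name!r}"))
        seq = "".join(canon)
        if not seq:
            raise ValueError(f"primer {self.name!r}: empty sequence")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_sets(self) -> tuple[frozenset[str], ...]:
        """Per-position base sets, 5'->3'."""
        return tuple(IUPAC_CODES[c] for c in self.sequence)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name}:{self.sequence}" if self.name else self.sequence


def _as_primer(p: Primer | str) -> Primer:
    return p if isinstance(p, Primer) else Primer("", p)


def reverse_complement(primer: Primer | str) -> Primer:
    """Positionwise complement in reversed order (an involution).

    The result is the primer as it reads on the opposite strand; sliding it
    along the plus strand finds minus-strand binding sites.
    """
    p = _as_primer(primer)
    seq = "".join(complement_code(c) for c in reversed(p.sequence))
    name = f"{p.name}_rc" if p.name else ""
    return Primer(name, seq)


def degeneracy(primer: Primer | str) -> int:
    """Number of distinct non-degenerate sequences the primer represents:
    the product over positions of the base-set sizes."""
    p = _as_primer(primer)
    n = 1
    for c in p.sequence:
        n *= len(IUPAC_CODES[c])
    return n


def enumerate_expansions(primer: Primer | str, cap: int = 4096) -> list[str]:
    """All distinct ACGT-only sequences matching the primer, in
    lexicographic order.

    Raises :class:`TooDegenerateError` when the pool exceeds ``cap`` —
    enumeration is meant for oracles and small primers, not whole-genome
    degeneracies.
    """
    p = _as_primer(primer)
    d = degeneracy(p)
    if d > cap:
        raise TooDegenerateError(
            f"primer {p.name or p.sequence!r} has degeneracy {d} > cap {cap}"
        )
    pools = [sorted(IUPAC_CODES[c]) for c in p.sequence]
    return ["".join(t) for t in itertools.product(*pools)]
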