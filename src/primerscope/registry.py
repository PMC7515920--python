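"""Built-in registry of the universal 16S primers compared in this package.

The set covers the V1–V3 / V3–V4 / V4 universal pairs commonly benchmarked
on prokaryotic communities: the Pro341F/Pro805R V3–V4 pair, its W-degenerate
forward variant Pro341FB (one extra A/T degeneracy at position 13, raising
the expansion pool from 24 to 48), and the 27F/534R, 341F(A)/805R(A) and
515F/806R pairs.
"""

from __future__ import annotations

from .iupac import Primer

__all__ = ["REGISTRY", "get_primer", "resolve_primer", "UnknownPrimerError"]

REGISTRY: dict[str, Primer] = {
    p.name: p
    for p in (
        Primer("Pro341FB", "CCTACGGGNBGCWSCAG"),
        Primer("Pro341F", "CCTACGGGNBGCASCAG"),
        Primer("Pro805R", "GACTACNVGGGTATCTAATCC"),
        Primer("341F(A)", "CCTACGGGNGGCWGCAG"),
        Primer("805R(A)", "GACTACHVGGGTATCTAATCC"),
        Primer("27F", "AGAGTTTGATCCTGGCTCAG"),
        Primer("534R", "ATTACCGCGGCTGCTGG"),
        Primer("515F", "GTGCCAGCMGCCGCGGTAA"),
        Primer("806R", "GGACTACHVGGGTWTCTAAT"),
    )
}


class UnknownPrimerError(KeyError):
    def __init__(self, name: str):
        super().__init__(
            f"unknown primer {name!r}; registry: {', '.join(sorted(REGISTRY))}"
        )


def get_primer(name: str) -> Primer:
    """Look up a registered primer by name; raises listing the registry."""
    try:
        return REGISTRY[name]
    except KeyError:
        raise UnknownPrimerError(name) from None


def resolve_primer(name_or_sequence: str, name: str = "") -> Primer:
    """Interpret a CLI-style primer argument: a registry name, or a raw
    IUPAC sequence (optionally labelled)."""
    if name_or_sequence in REGISTRY:
        return REGISTRY[name_or_sequence]
    return Primer(name or name_or_sequence, name_or_sequence)
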