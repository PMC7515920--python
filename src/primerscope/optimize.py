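"""Parsimony-constrained degeneration search for a base primer.

Given a base forward primer, its reverse partner, a reference set and a
target clade the base primer under-covers, the optimizer enumerates every
candidate edit that strictly widens the base set at one or more positions
(never narrowing, never repositioning), evaluates each candidate's pair
coverage on the quality-filtered target clade and on the full reference
set at the configured mismatch allowance, and ranks candidates by
completeness first (target coverage gained), then parsimony (smallest
degeneracy growth), then locality (fewest positions changed, 5'-most
first), with a lexicographic final tiebreak so the order is total.

Because every proposal is a positionwise superset of the base primer,
global coverage can only grow: the global delta is reported as a sanity
figure, never used as a constraint.  The 3'-terminal positions are frozen
by default (3' mismatches abolish polymerase extension), which still
leaves interior edits — e.g. an A→W widening five positions from the
3' end — reachable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iupac import IUPAC_CODES, Primer, degeneracy
from .pcr import PrimerPair, encode_sequence, find_hits
from .refdb import RANKS, RefSet, filter_high_quality, subset_by_taxon
from .coverage import CoverageDelta, compare_primer_pairs

__all__ = [
    "NoBindingSiteError",
    "OptimizerConfig",
    "AlleleProfile",
    "DegenerationProposal",
    "ProposalReport",
    "site_allele_profile",
    "propose_degenerations",
    "verify_proposal",
    "proposals_to_frame",
]


class NoBindingSiteError(RuntimeError):
    """No target record carries a locatable binding site for the primer."""


@dataclass(frozen=True)
class OptimizerConfig:
    """Search-space and evaluation settings for the degeneration search.

    ``max_positions_changed`` bounds how many positions one proposal may
    widen (1 keeps edits minimal); ``max_degeneracy`` caps the proposed
    primer's expansion-pool size; ``protect_3prime`` freezes that many
    3'-terminal positions; ``min_len`` is the quality threshold (strict >)
    applied when extracting the target clade; ``mode`` selects pair-level
    (amplicon) or forward-only coverage as the selection metric.
    """

    target_rank: str
    target_name: str
    max_positions_changed: int = 1
    max_degeneracy: int = 96
    protect_3prime: int = 3
    max_mismatch: int = 0
    min_len: int = 1200
    mode: str = "pair"

    def __post_init__(self) -> None:
        if self.target_rank not in RANKS:
            raise ValueError(f"unknown rank {self.target_rank!r}")
        for attr in ("max_positions_changed", "max_degeneracy", "protect_3prime",
                     "max_mismatch", "min_len"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be nonnegative")
        if self.max_positions_changed < 1:
            raise ValueError("max_positions_changed must be >= 1")
        if self.mode not in ("pair", "forward"):
            raise ValueError(f"unknown evaluation mode {self.mode!r}")


@dataclass(frozen=True)
class AlleleProfile:
    """Per-primer-position base counts observed at located binding sites."""

    primer: Primer
    counts: np.ndarray  # shape (len(primer), 4), columns A,C,G,T
    n_located: int
    n_unlocated: int

    BASES = ("A", "C", "G", "T")

    def at(self, position: int) -> dict[str, int]:
        """Base counts at a 1-based primer position (zero counts omitted)."""
        row = self.counts[position - 1]
        return {b: int(c) for b, c in zip(self.BASES, row) if c}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.BASES))
        df.insert(0, "position", np.arange(1, len(self.primer) + 1))
        df.insert(1, "code", list(self.primer.sequence))
        return df


@dataclass(frozen=True)
class DegenerationProposal:
    """A candidate widening of the base primer, with its evaluation.

    ``positions_changed`` lists (1-based position, old code, new code);
    every new code's base set strictly contains the old one's, so the
    proposal can never lose a match the base primer had.
    """

    base_primer: Primer
    proposed_primer: Primer
    positions_changed: tuple[tuple[int, str, str], ...]
    target_coverage_pct: float
    base_target_coverage_pct: float
    target_gain_pct: float
    global_coverage_pct: float
    base_global_coverage_pct: float
    global_delta_pct: float
    degeneracy_multiplier: float
    parsimony_rank: int = 0

    def __post_init__(self) -> None:
        if not self.positions_changed:
            raise ValueError("a proposal must change at least one position")
        for pos, old, new in self.positions_changed:
            if not IUPAC_CODES[new] > IUPAC_CODES[old]:
                raise ValueError(
                    f"position {pos}: {new} does not strictly widen {old}"
                )


@dataclass(frozen=True)
class ProposalReport:
    """Before/after audit of a proposal across taxonomic ranks."""

    proposal: DegenerationProposal
    deltas: dict[str, CoverageDelta]
    base_degeneracy: int
    proposed_degeneracy: int
    monotonic: bool


# ---------------------------------------------------------------------------
# binding-site allele profiling


def site_allele_profile(
    base_primer: Primer,
    target_set: RefSet,
    max_mismatch_for_locating: int = 3,
) -> AlleleProfile:
    """Locate the base primer's plus-strand binding site in each target
    record (best window within a relaxed mismatch allowance, leftmost on
    ties) and tally the observed base at every primer position.

    The relaxed allowance exists precisely to find the site in records the
    base primer *misses* — those records carry the alternative alleles the
    optimizer needs to see.  Sites are located independently per record, so
    insertions or deletions upstream of the site do not misalign the tally.
    Ambiguous subject characters at a site are not counted.
    """
    L = len(base_primer)
    counts = np.zeros((L, 4), dtype=np.int64)
    col = {b: i for i, b in enumerate(AlleleProfile.BASES)}
    n_located = 0
    n_unlocated = 0
    for rec in target_set:
        hits = find_hits(base_primer, rec.sequence, max_mismatch_for_locating, "+")
        if not hits:
            n_unlocated += 1
            continue
        best = min(hits, key=lambda h: (h.mismatches, h.start))
        n_located += 1
        window = rec.sequence[best.start : best.end]
        for i, ch in enumerate(window):
            if ch in col:
                counts[i, col[ch]] += 1
    if n_located == 0:
        raise NoBindingSiteError(
            f"no record in the target set has a binding site for "
            f"{base_primer.name or base_primer.sequence} within "
            f"{max_mismatch_for_locating} mismatches"
        )
    return AlleleProfile(base_primer, counts, n_located, n_unlocated)


# ---------------------------------------------------------------------------
# candidate enumeration and evaluation


def _strict_supersets(code: str) -> list[str]:
    base = IUPAC_CODES[code]
    return [c for c, s in IUPAC_CODES.items() if s > base]


def _enumerate_candidates(base: Primer, config: OptimizerConfig):
    """Yield (positions_changed, proposed sequence) for every strict
    widening of up to ``max_positions_changed`` unprotected positions
    within the degeneracy cap."""
    L = len(base)
    if config.protect_3prime >= L:
        raise ValueError("protect_3prime must be smaller than the primer length")
    editable = range(L - config.protect_3prime)
    base_deg = degeneracy(base)
    for r in range(1, config.max_positions_changed + 1):
        for combo in itertools.combinations(editable, r):
            option_lists = [_strict_supersets(base.sequence[i]) for i in combo]
            if any(not opts for opts in option_lists):
                continue
            for newcodes in itertools.product(*option_lists):
                deg = base_deg
                for i, nc in zip(combo, newcodes):
                    deg = deg // len(IUPAC_CODES[base.sequence[i]]) * len(IUPAC_CODES[nc])
                if deg > config.max_degeneracy:
                    continue
                seq = list(base.sequence)
                changes = []
                for i, nc in zip(combo, newcodes):
                    changes.append((i + 1, base.sequence[i], nc))
                    seq[i] = nc
                yield tuple(changes), "".join(seq)


class _PreparedSet:
    """Encoded records with reverse-primer minus-strand hits precomputed,
    so each forward-primer candidate costs one numpy scan per record."""

    def __init__(self, refset: RefSet, reverse: Primer, pair_template: PrimerPair,
                 max_mismatch: int, mode: str):
        self.mode = mode
        self.min_len = pair_template.min_amplicon_len
        self.max_len = pair_template.max_amplicon_len
        self.encoded: list[np.ndarray] = []
        self.rev_sites: list[list[tuple[int, int]]] = []
        for rec in refset:
            enc = encode_sequence(rec.sequence)
            self.encoded.append(enc)
            if mode == "pair":
                rhits = find_hits(reverse, enc, max_mismatch, "-")
                self.rev_sites.append([(h.start, h.end) for h in rhits])
            else:
                self.rev_sites.append([])
        self.max_mismatch = max_mismatch

    def coverage_pct(self, forward: Primer | str) -> float:
        if not self.encoded:
            return float("nan")
        n_cov = 0
        for enc, rsites in zip(self.encoded, self.rev_sites):
            fhits = find_hits(forward, enc, self.max_mismatch, "+")
            if not fhits:
                continue
            if self.mode == "forward":
                n_cov += 1
                continue
            ok = False
            for fh in fhits:
                for rs, re_ in rsites:
                    if rs > fh.start and self.min_len <= re_ - fh.start <= self.max_len:
                        ok = True
                        break
                if ok:
                    break
            n_cov += int(ok)
        return 100.0 * n_cov / len(self.encoded)


def propose_degenerations(
    base: Primer,
    pair_reverse: Primer,
    global_set: RefSet,
    config: OptimizerConfig,
    min_amplicon_len: int = 50,
    max_amplicon_len: int = 2000,
) -> list[DegenerationProposal]:
    """Rank every positive-gain strict widening of the base primer.

    The target clade is extracted from ``global_set`` by the configured
    rank/name after the quality-length filter; candidates are scored by
    pair coverage on that subset (completeness) and on the full
    ``global_set`` (reported global delta).  Returns all candidates with
    strictly positive target gain, best first; an empty list is a valid
    outcome (the base primer is already as complete as any widening).
    """
    template = PrimerPair(base, pair_reverse, min_amplicon_len, max_amplicon_len)
    target = subset_by_taxon(
        filter_high_quality(global_set, config.min_len),
        config.target_rank,
        config.target_name,
    )
    if not len(target):
        raise NoBindingSiteError(
            f"no record classified as {config.target_name!r} at rank "
            f"{config.target_rank!r} passes the >{config.min_len} nt filter"
        )

    prep_target = _PreparedSet(target, pair_reverse, template, config.max_mismatch, config.mode)
    prep_global = _PreparedSet(global_set, pair_reverse, template, config.max_mismatch, config.mode)
    base_target = prep_target.coverage_pct(base)
    base_global = prep_global.coverage_pct(base)
    base_deg = degeneracy(base)

    proposals: list[DegenerationProposal] = []
    for changes, seq in _enumerate_candidates(base, config):
        cand_target = prep_target.coverage_pct(seq)
        gain = cand_target - base_target
        if gain <= 0:
            continue
        cand_global = prep_global.coverage_pct(seq)
        label = base.name + "*" if base.name else ""
        proposals.append(
            DegenerationProposal(
                base_primer=base,
                proposed_primer=Primer(label, seq),
                positions_changed=changes,
                target_coverage_pct=cand_target,
                base_target_coverage_pct=base_target,
                target_gain_pct=gain,
                global_coverage_pct=cand_global,
                base_global_coverage_pct=base_global,
                global_delta_pct=cand_global - base_global,
                degeneracy_multiplier=degeneracy(seq) / base_deg,
            )
        )

    proposals.sort(
        key=lambda p: (
            -p.target_gain_pct,
            p.degeneracy_multiplier,
            len(p.positions_changed),
            p.positions_changed[0][0],
            p.proposed_primer.sequence,
        )
    )
    return [
        DegenerationProposal(**{**p.__dict__, "parsimony_rank": i + 1})
        for i, p in enumerate(proposals)
    ]


def verify_proposal(
    proposal: DegenerationProposal,
    pair_reverse: Primer,
    global_set: RefSet,
    ranks_to_report: tuple[str, ...] = RANKS[1:],
    max_mismatch: int = 0,
    min_amplicon_len: int = 50,
    max_amplicon_len: int = 2000,
) -> ProposalReport:
    """Full before/after audit of a proposal: per-rank coverage deltas of
    the base vs proposed pair, degeneracy accounting, and a monotonicity
    check that no taxon lost coverage (guaranteed by the superset
    construction; a violation indicates a matcher defect and raises)."""
    pair_a = PrimerPair(proposal.base_primer, pair_reverse, min_amplicon_len, max_amplicon_len)
    pair_b = PrimerPair(proposal.proposed_primer, pair_reverse, min_amplicon_len, max_amplicon_len)
    deltas: dict[str, CoverageDelta] = {}
    monotonic = True
    for rank in ranks_to_report:
        delta = compare_primer_pairs(pair_a, pair_b, global_set, rank, max_mismatch)
        deltas[rank] = delta
        for row in delta.rows:
            if row.defined and row.delta_pct < 0:
                monotonic = False
    if not monotonic:
        raise RuntimeError(
            "coverage decreased for some taxon under a strict widening — "
            "this violates the superset guarantee and indicates a matching bug"
        )
    return ProposalReport(
        proposal=proposal,
        deltas=deltas,
        base_degeneracy=degeneracy(proposal.base_primer),
        proposed_degeneracy=degeneracy(proposal.proposed_primer),
        monotonic=monotonic,
    )


def proposals_to_frame(proposals: list[DegenerationProposal]) -> pd.DataFrame:
    """Ranked proposals as a flat table (TSV-ready)."""
    return pd.DataFrame(
        {
            "parsimony_rank": [p.parsimony_rank for p in proposals],
            "positions_changed": [
                ";".join(f"{pos}:{old}>{new}" for pos, old, new in p.positions_changed)
                for p in proposals
            ],
            "proposed_sequence": [p.proposed_primer.sequence for p in proposals],
            "target_coverage_pct": [p.target_coverage_pct for p in proposals],
            "target_gain_pct": [p.target_gain_pct for p in proposals],
            "global_coverage_pct": [p.global_coverage_pct for p in proposals],
            "global_delta_pct": [p.global_delta_pct for p in proposals],
            "degeneracy_multiplier": [p.degeneracy_multiplier for p in proposals],
        }
    )
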