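"""Shared fixtures: published primers, the planted-allele benchmark, and
independent brute-force oracles for the matching engine."""

from __future__ import annotations

import numpy as np
import pytest

import primerscope as ps


@pytest.fixture(scope="session")
def pro341f() -> ps.Primer:
    return ps.get_primer("Pro341F")


@pytest.fixture(scope="session")
def pro341fb() -> ps.Primer:
    return ps.get_primer("Pro341FB")


@pytest.fixture(scope="session")
def pro805r() -> ps.Primer:
    return ps.get_primer("Pro805R")


@pytest.fixture(scope="session")
def pair_f(pro341f, pro805r) -> ps.PrimerPair:
    return ps.PrimerPair(pro341f, pro805r)


@pytest.fixture(scope="session")
def pair_fb(pro341fb, pro805r) -> ps.PrimerPair:
    return ps.PrimerPair(pro341fb, pro805r)


@pytest.fixture(scope="session")
def benchmark(pair_f, pair_fb):
    """One seeded planted-allele benchmark: (spec, refset, ground truth)."""
    spec = ps.brocadiaceae_benchmark(seed=11)
    refset, truth = ps.generate_refset(
        spec, truth_pairs={"Pro341F": pair_f, "Pro341FB": pair_fb}
    )
    return spec, refset, truth


def brute_force_hit_starts(primer, subject: str, strand: str = "+") -> list[int]:
    """Independent 0-mismatch oracle: exact string search over the full
    expansion pool of the (strand-adjusted) primer."""
    query = ps.reverse_complement(primer) if strand == "-" else primer
    starts: set[int] = set()
    for expansion in ps.enumerate_expansions(query, cap=4096):
        i = subject.find(expansion)
        while i != -1:
            starts.add(i)
            i = subject.find(expansion, i + 1)
    return sorted(starts)


def brute_force_pair_covered(pair: ps.PrimerPair, sequence: str) -> bool:
    """Independent pair-coverage oracle at 0 mismatches via expansion
    search plus the ordering and length constraints."""
    fwd = brute_force_hit_starts(pair.forward, sequence, "+")
    rev = brute_force_hit_starts(pair.reverse, sequence, "-")
    rlen = len(pair.reverse)
    for fs in fwd:
        for rs in rev:
            if rs > fs and pair.min_amplicon_len <= rs + rlen - fs <= pair.max_amplicon_len:
                return True
    return False


def random_degenerate_primer(rng: np.random.Generator, max_degeneracy: int = 64) -> ps.Primer:
    """A random primer of length 12-18 with a few degenerate positions."""
    length = int(rng.integers(12, 19))
    codes = list(ps.IUPAC_CODES)
    seq = [codes[int(i)] for i in rng.integers(0, 4, size=length)]  # ACGT backbone
    while True:
        pos = int(rng.integers(0, length))
        code = codes[int(rng.integers(0, len(codes)))]
        trial = seq.copy()
        trial[pos] = code
        if ps.degeneracy("".join(trial)) <= max_degeneracy:
            seq = trial
        if rng.random() < 0.5:
            break
    return ps.Primer("rand", "".join(seq))


def random_subject(rng: np.random.Generator, length: int, planted: ps.Primer | None = None) -> str:
    """Random ACGT subject, optionally with one expansion of ``planted``
    embedded at a random offset."""
    seq = list("ACGT"[int(i)] for i in rng.integers(0, 4, size=length))
    if planted is not None:
        exps = ps.enumerate_expansions(planted, cap=4096)
        site = exps[int(rng.integers(len(exps)))]
        off = int(rng.integers(0, length - len(site) + 1))
        seq[off : off + len(site)] = site
    return "".join(seq)


@pytest.fixture(scope="session")
def oracles():
    """Bundle of independent brute-force oracles and random generators."""
    return {
        "hit_starts": brute_force_hit_starts,
        "pair_covered": brute_force_pair_covered,
        "random_primer": random_degenerate_primer,
        "random_subject": random_subject,
    }
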