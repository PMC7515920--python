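"""Degeneration search: allele profiling, ranking, soundness, oracle head."""

import numpy as np
import pytest

import primerscope as ps
from primerscope.iupac import IUPAC_CODES
from primerscope.optimize import _strict_supersets
from conftest import brute_force_pair_covered, random_subject


FAMILY = "Candidatus Brocadiaceae"
LIN = (
    "k__Bacteria;p__Planctomycetes;c__Planctomycetia;o__Candidatus Brocadiales;"
    "f__Candidatus Brocadiaceae;g__Candidatus Brocadia"
)


def _target_refset(pro341f, pro805r, pos13_bases, length=1400, seed=0):
    """Target-clade records whose forward site carries the given base at
    position 13 (one record per listed base)."""
    rng = np.random.default_rng(seed)
    rsite_rc = ps.reverse_complement(
        ps.Primer("", ps.enumerate_expansions(pro805r, cap=64)[0])
    ).sequence
    records = []
    for i, b in enumerate(pos13_bases):
        seq = list(random_subject(rng, length))
        site = list(ps.enumerate_expansions(pro341f, cap=64)[0])
        site[12] = b
        seq[100:117] = site
        seq[560 - len(rsite_rc) : 560] = rsite_rc
        records.append(
            ps.RefSeq(f"t{i:02d}", "".join(seq), ps.TaxonomyLineage.from_prefixed(LIN))
        )
    return ps.RefSet(tuple(records))


def test_site_allele_profile_counts(pro341f, pro805r):
    refset = _target_refset(pro341f, pro805r, "T" * 7 + "A" * 3)
    profile = ps.site_allele_profile(pro341f, refset)
    assert profile.at(13) == {"A": 3, "T": 7}
    assert profile.n_located == 10 and profile.n_unlocated == 0


def test_site_allele_profile_matches_exact_expansion(pro341f, pro805r):
    refset = _target_refset(pro341f, pro805r, "A" * 5)
    profile = ps.site_allele_profile(pro341f, refset)
    site = ps.enumerate_expansions(pro341f, cap=64)[0]
    for pos, base in enumerate(site, start=1):
        expected = {base: 5} if pos != 13 else {"A": 5}
        assert profile.at(pos) == expected


def test_site_allele_profile_survives_upstream_indel(pro341f, pro805r):
    refset = _target_refset(pro341f, pro805r, "TTTT")
    shifted = []
    for i, rec in enumerate(refset):
        seq = rec.sequence if i % 2 == 0 else "GG" + rec.sequence  # 2 nt insertion upstream
        shifted.append(ps.RefSeq(rec.id, seq, rec.lineage))
    profile = ps.site_allele_profile(pro341f, ps.RefSet(tuple(shifted)))
    assert profile.at(13) == {"T": 4}


def test_site_allele_profile_no_site_error(pro341f):
    rng = np.random.default_rng(1)
    refset = ps.RefSet(
        (ps.RefSeq("x", random_subject(rng, 200), ps.TaxonomyLineage.from_prefixed(LIN)),)
    )
    with pytest.raises(ps.NoBindingSiteError):
        ps.site_allele_profile(pro341f, refset, max_mismatch_for_locating=0)


def _config(**kw):
    defaults = dict(target_rank="family", target_name=FAMILY)
    defaults.update(kw)
    return ps.OptimizerConfig(**defaults)


def test_top_proposal_is_the_w_degeneration(benchmark, pro341f, pro341fb, pro805r):
    _, refset, _ = benchmark
    props = ps.propose_degenerations(pro341f, pro805r, refset, _config())
    top = props[0]
    assert top.positions_changed == ((13, "A", "W"),)
    assert top.proposed_primer.sequence == pro341fb.sequence
    assert top.target_gain_pct > 0
    assert top.global_delta_pct >= 0
    assert top.degeneracy_multiplier == 2.0
    assert [p.parsimony_rank for p in props] == list(range(1, len(props) + 1))


def test_fully_covered_target_yields_no_proposal(pro341f, pro805r):
    spec = ps.brocadiaceae_benchmark(seed=3, alt_freq=0.0)
    refset, _ = ps.generate_refset(spec)
    assert ps.propose_degenerations(pro341f, pro805r, refset, _config()) == []


def test_empty_target_raises(benchmark, pro341f, pro805r):
    _, refset, _ = benchmark
    with pytest.raises(ps.NoBindingSiteError):
        ps.propose_degenerations(
            pro341f, pro805r, refset, _config(target_name="Missingaceae")
        )


def test_two_allele_target_head_is_minimal_covering_code(pro341f, pro805r):
    """Position 13 carries T and G in equal counts: the minimal single code
    widening A to cover both is D = {A,G,T}; the ranked head must agree
    with exhaustive brute-force evaluation."""
    refset = _target_refset(pro341f, pro805r, "TGTGTGTGTG", seed=7)
    props = ps.propose_degenerations(pro341f, pro805r, refset, _config())
    assert props[0].positions_changed == ((13, "A", "D"),)
    assert props[0].target_coverage_pct == 100.0

    # independent exhaustive oracle over every single-position widening
    best = None
    for pos in range(len(pro341f) - 3):
        for new in _strict_supersets(pro341f.sequence[pos]):
            seq = pro341f.sequence[:pos] + new + pro341f.sequence[pos + 1:]
            pair = ps.PrimerPair(ps.Primer("cand", seq), pro805r)
            cov = 100.0 * sum(brute_force_pair_covered(pair, r.sequence) for r in refset) / len(refset)
            deg_mult = len(IUPAC_CODES[new]) / len(IUPAC_CODES[pro341f.sequence[pos]])
            key = (-cov, deg_mult, 1, pos + 1, seq)
            if best is None or key < best[0]:
                best = (key, pos + 1, new, seq)
    assert (best[1], best[2]) == (13, "D")
    assert props[0].proposed_primer.sequence == best[3]


def test_every_proposal_is_a_strict_widening(benchmark, pro341f, pro805r):
    _, refset, _ = benchmark
    for p in ps.propose_degenerations(pro341f, pro805r, refset, _config()):
        for pos, old, new in p.positions_changed:
            assert IUPAC_CODES[new] > IUPAC_CODES[old]
            assert p.proposed_primer.sequence[pos - 1] == new
        assert p.global_delta_pct >= 0  # superset property, reported not constrained


def test_protect_3prime_freezes_terminal_positions(benchmark, pro341f, pro805r):
    _, refset, _ = benchmark
    for p in ps.propose_degenerations(pro341f, pro805r, refset, _config(protect_3prime=5)):
        assert all(pos <= len(pro341f) - 5 for pos, _, _ in p.positions_changed)
    with pytest.raises(ValueError):
        ps.propose_degenerations(
            pro341f, pro805r, refset, _config(protect_3prime=len(pro341f))
        )


def test_proposals_are_deterministic(benchmark, pro341f, pro805r):
    _, refset, _ = benchmark
    a = ps.propose_degenerations(pro341f, pro805r, refset, _config())
    b = ps.propose_degenerations(pro341f, pro805r, refset, _config())
    assert a == b


def test_degeneration_proposal_rejects_non_widening(pro341f):
    with pytest.raises(ValueError):
        ps.DegenerationProposal(
            base_primer=pro341f,
            proposed_primer=pro341f,
            positions_changed=((13, "A", "A"),),
            target_coverage_pct=0, base_target_coverage_pct=0, target_gain_pct=0,
            global_coverage_pct=0, base_global_coverage_pct=0, global_delta_pct=0,
            degeneracy_multiplier=1.0,
        )


def test_verify_proposal_report(benchmark, pro341f, pro805r):
    _, refset, _ = benchmark
    top = ps.propose_degenerations(pro341f, pro805r, refset, _config())[0]
    report = ps.verify_proposal(top, pro805r, refset)
    assert report.monotonic
    assert report.base_degeneracy == 24 and report.proposed_degeneracy == 48
    # the gain concentrates in the planted clade: at phylum rank only
    # Planctomycetes moves
    phylum = report.deltas["phylum"]
    moved = [r.taxon for r in phylum.rows if r.defined and r.delta_pct > 0]
    assert moved == ["Planctomycetes"]
    # consistency with the drill-down on the same path
    rows = ps.lineage_drilldown(
        ps.PrimerPair(pro341f, pro805r),
        ps.PrimerPair(top.proposed_primer, pro805r),
        refset,
        ps.BENCHMARK_LINEAGE_PATH,
    )
    fam_row = next(r for r in rows if r.rank == "family")
    fam_delta = report.deltas["family"]["Candidatus Brocadiaceae"]
    assert fam_row.delta_pct == pytest.approx(fam_delta.delta_pct)


def test_optimizer_config_validation():
    with pytest.raises(ValueError):
        _config(max_positions_changed=0)
    with pytest.raises(ValueError):
        _config(target_rank="tribe")
    with pytest.raises(ValueError):
        _config(mode="thermodynamic")
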