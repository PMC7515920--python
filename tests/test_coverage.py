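"""Coverage tables, pair comparisons and lineage drill-downs."""

import math

import numpy as np
import pytest

import primerscope as ps
from primerscope.coverage import UNCLASSIFIED
from primerscope.refdb import TaxonomyLineage
from conftest import random_subject


def _make_refset(pair, spec, seed=0):
    """Records from (lineage_prefixed, covered?) tuples: covered records get
    both primer sites planted 300 nt apart."""
    rng = np.random.default_rng(seed)
    fsite = ps.enumerate_expansions(pair.forward, cap=64)[0]
    rsite_rc = ps.reverse_complement(
        ps.Primer("", ps.enumerate_expansions(pair.reverse, cap=64)[0])
    ).sequence
    records = []
    for i, (lin, cov) in enumerate(spec):
        seq = list(random_subject(rng, 500))
        if cov:
            seq[50 : 50 + len(fsite)] = fsite
            seq[350 - len(rsite_rc) : 350] = rsite_rc
        records.append(
            ps.RefSeq(f"r{i:03d}", "".join(seq), TaxonomyLineage.from_prefixed(lin))
        )
    return ps.RefSet(tuple(records))


@pytest.fixture(scope="module")
def pair(pro341fb, pro805r):
    return ps.PrimerPair(pro341fb, pro805r)


def test_coverage_by_rank_counts(pair):
    spec = [("k__Bacteria;p__X", i < 4) for i in range(10)]
    refset = _make_refset(pair, spec)
    table = ps.coverage_by_rank(pair, refset, "phylum", 0)
    row = table["X"]
    assert (row.total, row.matched, row.coverage_pct) == (10, 4, 40.0)


def test_coverage_unclassified_bin_and_totals(pair):
    spec = [("k__Bacteria;p__X", True)] * 3 + [("k__Bacteria", False)] * 2
    refset = _make_refset(pair, spec)
    table = ps.coverage_by_rank(pair, refset, "phylum", 0)
    assert table[UNCLASSIFIED].total == 2
    assert sum(r.total for r in table.rows) == len(refset)


def test_coverage_no_match_and_full_match(pair):
    spec = [("k__Bacteria;p__X", True)] * 4
    refset = _make_refset(pair, spec)
    full = ps.coverage_by_rank(pair, refset, "phylum", 0)
    assert full["X"].coverage_pct == 100.0
    kingdom = ps.coverage_by_rank(pair, refset, "kingdom", 0)
    assert kingdom["Bacteria"].coverage_pct == 100.0
    nowhere = ps.PrimerPair(ps.Primer("none", "TTTTTTTTTTTTTTTTTTTTTTTTT"), pair.reverse)
    empty = ps.coverage_by_rank(nowhere, refset, "phylum", 0)
    assert empty["X"].coverage_pct == 0.0


def test_coverage_kingdom_matched_equals_covered_count(benchmark, pair_fb):
    _, refset, _ = benchmark
    table = ps.coverage_by_rank(pair_fb, refset, "kingdom", 0)
    n_cov = int(ps.covered(pair_fb, refset, 0).sum())
    assert sum(r.matched for r in table.rows) == n_cov


def test_compare_identity_gives_zero_deltas(benchmark, pair_f):
    _, refset, _ = benchmark
    delta = ps.compare_primer_pairs(pair_f, pair_f, refset, "phylum", 0)
    assert all(r.delta_pct == 0 for r in delta.rows)


def test_compare_superset_deltas_nonnegative_and_sorted(benchmark, pair_f, pair_fb):
    _, refset, _ = benchmark
    for rank in ps.RANKS:
        delta = ps.compare_primer_pairs(pair_f, pair_fb, refset, rank, 0)
        assert all(r.delta_pct >= 0 for r in delta.rows if r.defined)
        deltas = [r.delta_pct for r in delta.rows]
        assert deltas == sorted(deltas, reverse=True)


def test_compare_min_delta_display_rule(pair):
    # planted clade T: 3 of 4 records carry an allele only the widened
    # primer matches -> +75 pts; clade U is fully matched by both
    base = ps.PrimerPair(ps.Primer("base", "CCTACGGGNBGCASCAG"), pair.reverse)
    wide = ps.PrimerPair(ps.Primer("wide", "CCTACGGGNBGCWSCAG"), pair.reverse)
    spec_t = [("k__Bacteria;p__T", False)] * 3 + [("k__Bacteria;p__T", True)]
    spec_u = [("k__Bacteria;p__U", True)] * 4
    refset = _make_refset(base, spec_u, seed=1)
    # plant the T-allele site for clade T manually
    rng = np.random.default_rng(2)
    fsite = list(ps.enumerate_expansions(base.forward, cap=64)[0])
    fsite[12] = "T"  # position 13: A -> T, matched by W but not A
    rsite_rc = ps.reverse_complement(
        ps.Primer("", ps.enumerate_expansions(base.reverse, cap=64)[0])
    ).sequence
    extra = []
    for i, (lin, has_t_allele) in enumerate([("k__Bacteria;p__T", True)] * 3 + [("k__Bacteria;p__T", False)]):
        seq = list(random_subject(rng, 500))
        site = fsite if has_t_allele else ps.enumerate_expansions(base.forward, cap=64)[0]
        seq[50 : 50 + 17] = site
        seq[350 - len(rsite_rc) : 350] = rsite_rc
        extra.append(ps.RefSeq(f"t{i}", "".join(seq), TaxonomyLineage.from_prefixed(lin)))
    refset = ps.RefSet(refset.records + tuple(extra))

    delta = ps.compare_primer_pairs(base, wide, refset, "phylum", 0)
    assert delta["T"].delta_pct == 75.0
    assert delta["U"].delta_pct == 0.0
    filtered = ps.compare_primer_pairs(base, wide, refset, "phylum", 0, min_delta_pct=25.0)
    assert [r.taxon for r in filtered.rows] == ["T"]


def test_drilldown_positive_along_planted_path(benchmark, pair_f, pair_fb):
    _, refset, _ = benchmark
    rows = ps.lineage_drilldown(pair_f, pair_fb, refset, ps.BENCHMARK_LINEAGE_PATH, 0)
    assert len(rows) == 5  # phylum .. genus
    assert all(r.defined and r.delta_pct > 0 for r in rows)


def test_drilldown_single_rank_matches_compare(benchmark, pair_f, pair_fb):
    _, refset, _ = benchmark
    rows = ps.lineage_drilldown(pair_f, pair_fb, refset, [("phylum", "Planctomycetes")], 0)
    delta = ps.compare_primer_pairs(pair_f, pair_fb, refset, "phylum", 0)
    row = delta["Planctomycetes"]
    assert rows[0].total == row.total
    assert rows[0].delta_pct == pytest.approx(row.delta_pct)


def test_drilldown_absent_name_and_empty_refset(pair_f, pair_fb):
    empty = ps.RefSet(())
    rows = ps.lineage_drilldown(pair_f, pair_fb, empty, [("phylum", "Nowhere")], 0)
    assert rows[0].total == 0 and not rows[0].defined and math.isnan(rows[0].delta_pct)
    with pytest.raises(ValueError):
        ps.lineage_drilldown(pair_f, pair_fb, empty, [("genus", "A"), ("phylum", "B")], 0)


def test_genus_matched_aggregates_to_family(pair):
    # two genera in one family: genus-level matched counts must sum to the
    # family-level matched count
    fam = "k__B;p__P;c__C;o__O;f__Fam"
    spec = (
        [(fam + ";g__G1", True)] * 3
        + [(fam + ";g__G1", False)] * 1
        + [(fam + ";g__G2", True)] * 2
        + [(fam + ";g__G2", False)] * 4
    )
    refset = _make_refset(pair, spec, seed=5)
    genus_table = ps.coverage_by_rank(pair, refset, "genus", 0)
    family_table = ps.coverage_by_rank(pair, refset, "family", 0)
    assert genus_table["G1"].matched + genus_table["G2"].matched == family_table["Fam"].matched == 5


def test_coverage_undefined_distinct_from_zero(pair):
    spec = [("k__Bacteria;p__X", False)] * 2
    refset = _make_refset(pair, spec)
    table = ps.coverage_by_rank(pair, refset, "phylum", 0)
    assert table["X"].coverage_pct == 0.0  # zero coverage: defined
    assert math.isnan(table[UNCLASSIFIED].coverage_pct)  # empty bin: undefined
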