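# primerscope

In-silico evaluation and degeneracy optimization of universal 16S rRNA
primers, with a focus on communities — such as wastewater treatment
consortia — whose key members (the anammox bacteria of the family
*Candidatus* Brocadiaceae) are under-covered by otherwise excellent
"universal" primer pairs.

## The problem and the method

Amplicon surveys of prokaryotic communities stand or fall with the primer
pair: a taxon whose 16S sequence mismatches a primer is invisible,
regardless of its abundance. Universal primers use the IUPAC degenerate
alphabet (W = A/T, N = any base, ...) so that one oligo pool covers
sequence variants; the *degeneracy* of a primer is the size of that pool
(product of per-position base-set sizes; e.g. `CCTACGGGNBGCASCAG` has
4·3·2 = 24 expansions).

primerscope provides:

- **IUPAC algebra** (`primerscope.iupac`) — expansion, minimal-code lookup,
  reverse complement, degeneracy, expansion enumeration.
- **ProbeMatch-style matching and amplicon simulation**
  (`primerscope.pcr`) — a primer matches a window when every position's
  base sets intersect (0 mismatches by default); a record is *covered* by
  a pair when a forward plus-strand hit and a downstream reverse
  minus-strand hit bracket an in-bounds product. Amplicon length is
  measured 5′ start to 5′ start inclusive (the convention under which the
  V3–V4 341F/805R product is ≈465 nt).
- **Taxonomic coverage statistics** (`primerscope.coverage`) — per-rank
  coverage tables over the six-rank ladder (kingdom…genus), percentage-
  point deltas between pairs, and root-to-genus drill-downs, with an
  explicit `unclassified` bin and undefined-vs-zero coverage kept
  distinct.
- **A parsimony-constrained degeneration search**
  (`primerscope.optimize`) — enumerate every strict base-set widening of
  a base primer (up to a degeneracy cap, 3′ terminus protected), score
  each candidate by pair coverage gained on a target clade, and rank by
  completeness first, parsimony (degeneracy growth) second. Because
  candidates only widen, global coverage can never drop — the search
  improves the target clade *without* sacrificing anything.
- **Profile mining** (`primerscope.profiles`) — genus richness and
  archaea/anammox prevalence across per-sample abundance tables
  (MGnify-download style TSV).
- **Synthetic data with ground truth** (`primerscope.synth`) — seeded,
  byte-reproducible reference sets with planted primer sites and allele
  frequencies, and synthetic survey profiles with planted prevalences.

The registry ships the published universal primers compared here, notably
Pro341F `CCTACGGGNBGCASCAG` (degeneracy 24), its W-widened variant
Pro341FB `CCTACGGGNBGCWSCAG` (degeneracy 48) and the shared reverse
Pro805R `GACTACNVGGGTATCTAATCC`.

## Worked example

Recover the one-position widening that turns Pro341F into Pro341FB, on a
synthetic benchmark where the anammox-like clade carries a T allele (at
70 % frequency) at forward-site position 13, where Pro341F demands A:

```python
import primerscope as ps

spec = ps.brocadiaceae_benchmark(seed=42)          # 65 records, 4 clades
refset, truth = ps.generate_refset(spec)

base, rev = ps.get_primer("Pro341F"), ps.get_primer("Pro805R")
config = ps.OptimizerConfig(target_rank="family",
                            target_name="Candidatus Brocadiaceae")
props = ps.propose_degenerations(base, rev, refset, config)
top = props[0]
```

The ranked proposal table begins:

```
 parsimony_rank positions_changed proposed_sequence  target_coverage_pct  target_gain_pct  global_delta_pct  degeneracy_multiplier
              1            13:A>W CCTACGGGNBGCWSCAG                100.0             65.0              20.0                    2.0
              2            13:A>D CCTACGGGNBGCDSCAG                100.0             65.0              20.0                    3.0
```

The head proposal is exactly the A→W edit at position 13 — the Pro341FB
sequence: it lifts target-family coverage from 35 % to 100 % (+65 points,
the planted alt-allele carriers), and W (degeneracy ×2) beats D and H
(×3) on parsimony at equal gain. Drilling down the planted lineage:

```python
rows = ps.lineage_drilldown(ps.PrimerPair(base, rev),
                            ps.PrimerPair(top.proposed_primer, rev),
                            refset, ps.BENCHMARK_LINEAGE_PATH)
```

```
phylum  Planctomycetes            n= 20   35.0 -> 100.0  (+65.0)
class   Planctomycetia            n= 20   35.0 -> 100.0  (+65.0)
order   Candidatus Brocadiales    n= 20   35.0 -> 100.0  (+65.0)
family  Candidatus Brocadiaceae   n= 20   35.0 -> 100.0  (+65.0)
genus   Candidatus Brocadia       n= 20   35.0 -> 100.0  (+65.0)
```

Every rank on the anammox path gains, and `ps.verify_proposal` audits
that no other taxon lost coverage (guaranteed by the strict-widening
construction). The same run is available from the shell:

```bash
primerscope synth refset --seed 42 --out-dir bench/
primerscope optimize --fasta bench/synthetic.fasta \
    --taxonomy bench/synthetic.taxonomy.tsv \
    --base Pro341F --reverse Pro805R \
    --target-rank family --target-name "Candidatus Brocadiaceae" \
    --out proposals.tsv
```

Real reference sets are read with `ps.read_refset(fasta, taxonomy)`,
where `taxonomy` is either `"header"` (RDP-style `Lineage=` headers) or a
two-column `seq_id → k__…;p__…;…` sidecar TSV; `ps.filter_high_quality`
applies the conventional >1200 bp quality cut.

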