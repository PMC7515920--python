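# Methods

## Matching model

A primer is a string over the 15 IUPAC nucleotide codes, each denoting a
nonempty subset of {A,C,G,T}. Matching is *set intersection*: primer code
P matches subject code S at a position iff their base sets share at least
one base, and a window placement is a hit when the number of
non-intersecting positions is at most the mismatch allowance. The default
allowance is 0 — the strictest setting, under which a hit means "some
expansion of the primer is an exact substring match (up to subject
ambiguity)". Matching is equivalent, at 0 mismatches on ACGT subjects, to
exact string search over the primer's full expansion pool; the test suite
and acceptance script verify this equivalence against a brute-force
expansion-search oracle on randomized fixtures.

Subject ambiguity codes expand like primer codes by default, so an N in a
reference sequence matches anything. This is the permissive choice and the
only one that preserves the monotonicity guarantees below (widening a
primer can never lose a hit). Because public 16S records vary in how they
encode uncertainty, a `strict_subject` mode is exposed in which any
non-ACGT subject character counts as a mismatch; it is a diagnostic, not
the default.

Reverse primers are written 5′→3′ as published; minus-strand search
slides the reverse complement along the plus strand. An amplicon forms
when a forward plus-strand hit is followed, strictly downstream, by a
reverse minus-strand hit with product length within bounds. Amplicon
length is 5′ start of the forward primer to 5′ start of the reverse
primer on the plus strand, inclusive of both footprints — the convention
under which the 341F/805R V3–V4 product is ≈465 nt. The default bounds
(50–2000 nt) only guard against pathological self-priming on long
records; they comfortably include the ≈465 nt product. Coordinates are
0-based half-open internally, 1-based inclusive in every written report.

Implementation: sequences are encoded as 4-bit base masks and windows are
scored with one vectorized numpy pass per primer per record, so sliding a
17-mer over a full-length 16S record is effectively free; this is what
makes the optimizer's exhaustive candidate evaluation cheap.

## Taxonomy and coverage

Lineages live on a fixed six-rank ladder (kingdom, phylum, class, order,
family, genus); unofficial intermediate ranks in RDP-style headers
(subclass, suborder) are dropped on input, and an absent rank truncates
everything deeper. Name matching is case-sensitive after whitespace
normalization, and "Candidatus" is part of the name, as reference
databases print it.

Coverage of a pair at a taxon is the percentage of that taxon's records
forming an amplicon. Three deliberate bookkeeping choices:

- Records unannotated at the queried rank go to an explicit
  `unclassified` bin, excluded from named-taxon denominators but never
  dropped — silently discarding them would corrupt totals invisibly.
- Coverage of an empty taxon is *undefined* (NaN, flagged), distinct from
  0 %: a clade with no qualifying sequences is a different finding from a
  clade the primers miss.
- Pair comparisons report percentage-point differences (B − A), not
  ratios; a `min_delta_pct` display filter (25 is the conventional
  headline threshold) trims the table, and pair-level coverage (amplicon
  formation) is the default metric with per-primer coverage available via
  `mode="forward"`/`"reverse"` since single-primer tabulations are also
  common.

The quality filter keeps records strictly longer than 1200 nt, the
conventional near-full-length cut for 16S reference sets.

## Degeneration search

The optimizer answers: which minimal widening of a base forward primer
recovers an under-covered target clade? The candidate space is *strict
base-set widenings only* — never narrowing, never repositioning — at up
to `max_positions_changed` positions (default 1), with the proposed
degeneracy capped (default 96, i.e. up to 4× the Pro341F pool) and the
3′-terminal `protect_3prime` positions frozen (default 3; 3′ mismatches
abolish extension, and interior edits such as a widening 5 nt from the 3′
end remain reachable; set 0 to disable). Widening-only is what makes the
search safe: every proposal's expansion pool contains the base pool, so
no record, and hence no taxon, can lose coverage. `verify_proposal`
re-audits this on every run and raises if violated.

Each candidate is scored by pair coverage on the target clade (extracted
from the reference set at the configured rank/name after the >1200 nt
quality filter, mirroring how target clades are curated from reference
databases) and on the full reference set as given (the global delta is a
reported sanity figure, not a constraint). Ranking is completeness first,
parsimony second: target gain descending, then degeneracy multiplier
ascending, then fewest positions changed, then 5′-most changed position,
then lexicographic sequence — a total order, so results are
deterministic. For single-position searches the ranked head is verified
against exhaustive brute-force evaluation in the tests.

`site_allele_profile` supports diagnosis: it locates the base primer's
binding site per record under a relaxed allowance (default ≤3
mismatches — deliberately loose, since the interesting records are the
ones the base primer misses), leftmost-best on ties, and tallies the
observed base per primer position. Sites are located independently per
record, so indels upstream of the site do not misalign the tally.

## Synthetic data

The generator emulates a clade-structured 16S reference set: per clade, a
lineage, record lengths uniform in 1300–1600 nt, an i.i.d.-uniform ACGT
background, and planted sites — a concrete forward site drawn uniformly
from the expansions of a degenerate template (default Pro341F) and a
reverse-complemented concrete reverse site (default Pro805R), separated
by a uniform 430–480 nt amplicon span at a per-record random offset.
Alternative alleles are planted at chosen template positions with a
controlled frequency; a decoy fraction leaves records site-free.
Ground-truth coverage flags are computed from the planted site strings by
positionwise base-set membership — independent of the sliding matcher, so
truth-agreement tests are a genuine cross-check. A single integer seed
drives one `numpy.random.default_rng` stream; identical spec and seed
give byte-identical FASTA/TSV output.

The benchmark configuration (`brocadiaceae_benchmark`) plants a
Planctomycetes→*Candidatus* Brocadia clade of 20 records carrying T at
forward position 13 at frequency 0.7, against three neutral background
clades (two bacterial, one archaeal; 15 records each, 10 % decoys). The
0.7 frequency makes the planted signal a clear majority allele while
leaving base-primer coverage visibly nonzero; 20 target records keep
per-record effects at 5-point granularity.

The profile generator emulates a wastewater-biome amplicon survey: 3433
samples across 49 studies by default, each drawing 15–40 genera from a
1465-label pool, with archaea present in a 22.5 % Bernoulli fraction of
samples and one of the five anammox genera (Brocadia, Kuenenia,
Anammoxoglobus, Jettenia, Scalindua) in a 3.7 % fraction; positivity is
recorded in a per-sample truth table, and prevalence recovery by the
miner is exact by construction (presence thresholds agree).

What the synthetic data does *not* model: phylogenetic correlation of the
background (real 16S backgrounds are highly conserved, so off-site
partial matches are more common in real data), indel/chimera artifacts,
length-quality correlation, and study-level clustering of anammox
occurrence (planted positivity is i.i.d. across samples, so the
"studies containing anammox" count runs higher than in real surveys where
positives concentrate in few studies). Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
signals, not field performance on any particular database release.

## Profile mining

Input is a flat TSV (study_id, sample_id, biome, experiment_type,
lineage, count) of already-downloaded per-sample abundance profiles; the
library performs no network access, because reproducibility requires
frozen inputs. Filters are conjunctive: biome substring, experiment type,
and a free-text keyword over biome plus study metadata. A sample is
positive for a genus set when any listed genus reaches `min_count` reads
(default 1 — presence; the threshold is exposed because "evidence of"
conventions differ), and positive for a kingdom set when any lineage
under that kingdom does. Genus matching tolerates the "Candidatus "
prefix being present or absent, since profile pipelines differ in
printing it. Percentages over an empty collection are NaN-flagged, never
reported as 0.

## Numerical and interface choices

- Degeneracy arithmetic is exact integer arithmetic; expansion
  enumeration refuses pools larger than a cap (default 4096) rather than
  risk combinatorial blowup.
- All ranking tie-breaks are total (ending in lexicographic sequence
  order), so every ranked output is deterministic and repeatable.
- The CLI is a thin veneer: subcommand outputs are byte-identical to the
  corresponding library calls, carry a provenance header (tool version +
  parameter echo), and all I/O is plain TSV/FASTA.
- Problem sizes in the test suite and acceptance script (65-record
  benchmark sets, 100 optimizer replicates, 200 matcher-oracle fixtures,
  a 3433-sample synthetic survey) were chosen so the full recomputation
  runs in minutes on one CPU while keeping binomial sampling error on
  recovered prevalences well under a percentage point of their planted
  values.

## Known limitations

- No thermodynamics: melting temperature, dimers and 3′ ΔG are out of
  scope; 3′ protection is the only extension-chemistry concession.
- Coverage is in-silico matching, not amplification efficiency; a
  0-mismatch hit does not guarantee equal PCR yield.
- Whole-database benchmark figures depend on the specific reference
  release and its lineage dialect; this package reproduces the machinery
  and validates it on synthetic ground truth, and reads the standard
  dialects needed to re-run against a downloaded release.
- Reverse-primer co-optimization is structurally possible (the optimizer
  takes any base primer) but untuned; multi-position search is supported
  (`max_positions_changed > 1`) but combinatorially heavier.
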