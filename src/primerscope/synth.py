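"""Deterministic synthetic reference sets and abundance profiles.

Real whole-database coverage runs need multi-gigabyte downloads; this
module generates small clade-structured stand-ins with *planted* primer
binding sites, so matching, coverage and optimization are testable — with
exact ground truth — entirely offline.

A synthetic reference set holds one or more clades.  Each record of a
clade is an i.i.d.-uniform ACGT background into which a concrete forward
site (drawn uniformly from the expansions of a degenerate template, e.g.
a published primer) and the reverse complement of a concrete reverse site
are planted at a per-record random offset with a realistic amplicon span.
Alternative alleles can be planted at chosen template positions with a
controlled frequency — the key knob: a clade carrying a T allele at a
position where the template demands A is the exact situation an A→W
degeneration repairs.  A decoy fraction yields records without sites.

Ground-truth covered-by flags are computed from the construction itself
(positionwise base-set membership of the planted site sequences), never by
running the matcher — so matcher tests against the ground truth are a real
cross-check, not a tautology.

Everything is driven by a single integer seed through one numpy
``default_rng`` stream: identical spec + seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .iupac import IUPAC_CODES, Primer, complement_code, enumerate_expansions
from .pcr import PrimerPair
from .refdb import RANKS, RefSeq, RefSet, TaxonomyLineage, write_refset

__all__ = [
    "CladeSpec",
    "SyntheticRefSpec",
    "generate_refset",
    "write_refset_files",
    "brocadiaceae_benchmark",
    "BENCHMARK_LINEAGE_PATH",
    "generate_profiles",
    "write_profiles_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass(frozen=True)
class CladeSpec:
    """One synthetic clade: lineage, record geometry, planted sites.

    ``alt_alleles`` plants alternatives at forward-template positions:
    each entry is (1-based position, alternative base, frequency).
    ``decoy_fraction`` is the per-record probability of planting no sites
    at all (an off-target record).
    """

    lineage: TaxonomyLineage
    n_records: int
    length_range: tuple[int, int] = (1300, 1600)
    forward_template: str = "CCTACGGGNBGCASCAG"
    reverse_template: str = "GACTACNVGGGTATCTAATCC"
    alt_alleles: tuple[tuple[int, str, float], ...] = ()
    decoy_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")
        if not (0 <= self.decoy_fraction <= 1):
            raise ValueError("decoy_fraction must be in [0, 1]")
        for pos, base, freq in self.alt_alleles:
            if not (1 <= pos <= len(self.forward_template)):
                raise ValueError(f"alt allele position {pos} outside the forward template")
            if base not in "ACGT":
                raise ValueError(f"alt allele base must be concrete, got {base!r}")
            if not (0 <= freq <= 1):
                raise ValueError("alt allele frequency must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticRefSpec:
    """A full synthetic reference set: clades + geometry + mandatory seed."""

    clades: tuple[CladeSpec, ...]
    seed: int
    amplicon_span_range: tuple[int, int] = (430, 480)
    margin: int = 25  # free background kept on both flanks

    def __post_init__(self) -> None:
        lo, hi = self.amplicon_span_range
        for clade in self.clades:
            need = (
                self.margin * 2
                + max(hi, len(clade.forward_template) + len(clade.reverse_template))
            )
            if clade.length_range[0] < need:
                raise ValueError(
                    f"clade records of length >= {clade.length_range[0]} cannot hold "
                    f"both sites plus margins (need >= {need})"
                )
            if lo > hi or lo < len(clade.forward_template) + len(clade.reverse_template):
                raise ValueError("amplicon span range infeasible: sites would overlap")


def _matches_positionwise(site: str, primer: Primer) -> bool:
    if len(site) != len(primer):
        return False
    return all(b in IUPAC_CODES[c] for b, c in zip(site, primer.sequence))


def _revcomp_concrete(seq: str) -> str:
    return "".join(complement_code(c) for c in reversed(seq))


def generate_refset(
    spec: SyntheticRefSpec,
    truth_pairs: dict[str, PrimerPair] | None = None,
) -> tuple[RefSet, pd.DataFrame]:
    """Generate the reference set and its ground-truth table.

    ``truth_pairs`` maps labels to primer pairs; for each, the truth table
    gets a ``covered_<label>`` column computed from the planted site
    sequences by positionwise base-set membership (plus the amplicon-span
    bounds), independently of the sliding matcher.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[RefSeq] = []
    truth_rows: list[dict] = []
    truth_pairs = truth_pairs or {}

    for ci, clade in enumerate(spec.clades):
        fwd_expansions = enumerate_expansions(clade.forward_template, cap=4096)
        rev_expansions = enumerate_expansions(clade.reverse_template, cap=4096)
        for ri in range(clade.n_records):
            length = int(rng.integers(clade.length_range[0], clade.length_range[1] + 1))
            seq = rng.choice(_BASES, size=length)
            decoy = bool(rng.random() < clade.decoy_fraction)

            fwd_site = rev_site = ""
            fwd_start = rev_end = -1
            span = -1
            if not decoy:
                fwd_site = list(fwd_expansions[rng.integers(len(fwd_expansions))])
                for pos, alt, freq in clade.alt_alleles:
                    if rng.random() < freq:
                        fwd_site[pos - 1] = alt
                fwd_site = "".join(fwd_site)
                rev_site = rev_expansions[int(rng.integers(len(rev_expansions)))]

                span_hi = min(spec.amplicon_span_range[1], length - 2 * spec.margin)
                span = int(rng.integers(spec.amplicon_span_range[0], span_hi + 1))
                fwd_start = int(rng.integers(spec.margin, length - span - spec.margin + 1))
                rev_end = fwd_start + span  # exclusive end of the minus-strand site
                seq[fwd_start : fwd_start + len(fwd_site)] = list(fwd_site)
                seq[rev_end - len(rev_site) : rev_end] = list(_revcomp_concrete(rev_site))

            seq_id = f"SYN{ci:02d}_{ri:04d}"
            sequence = "".join(seq)
            records.append(RefSeq(seq_id, sequence, clade.lineage))

            row = {
                "seq_id": seq_id,
                "lineage": clade.lineage.to_prefixed(),
                "length": length,
                "decoy": decoy,
                "fwd_start": fwd_start,
                "rev_end": rev_end,
                "amplicon_len": span,
                "fwd_site": fwd_site,
                "rev_site": rev_site,
            }
            for label, pair in truth_pairs.items():
                cov = (
                    not decoy
                    and _matches_positionwise(fwd_site, pair.forward)
                    and _matches_positionwise(rev_site, pair.reverse)
                    and pair.min_amplicon_len <= span <= pair.max_amplicon_len
                )
                row[f"covered_{label}"] = cov
            truth_rows.append(row)

    refset = RefSet(tuple(records), provenance=f"synthetic(seed={spec.seed})")
    return refset, pd.DataFrame(truth_rows)


def write_refset_files(
    refset: RefSet,
    truth: pd.DataFrame,
    outdir: str | Path,
    stem: str = "synthetic",
) -> dict[str, Path]:
    """Write FASTA + taxonomy sidecar + ground-truth TSV; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{stem}.fasta",
        "taxonomy": outdir / f"{stem}.taxonomy.tsv",
        "truth": outdir / f"{stem}.truth.tsv",
    }
    write_refset(refset, paths["fasta"], paths["taxonomy"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# the planted-allele benchmark


_TARGET_LINEAGE = TaxonomyLineage.from_dict(
    {
        "kingdom": "Bacteria",
        "phylum": "Planctomycetes",
        "class": "Planctomycetia",
        "order": "Candidatus Brocadiales",
        "family": "Candidatus Brocadiaceae",
        "genus": "Candidatus Brocadia",
    }
)

#: root-to-genus path of the benchmark's planted clade
BENCHMARK_LINEAGE_PATH: list[tuple[str, str]] = [
    (rank, name) for rank, name in zip(RANKS[1:], _TARGET_LINEAGE.names[1:])
]

_BACKGROUND_LINEAGES = (
    TaxonomyLineage.from_prefixed(
        "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacterales;"
        "f__Enterobacteriaceae;g__Escherichia"
    ),
    TaxonomyLineage.from_prefixed(
        "k__Bacteria;p__Firmicutes;c__Bacilli;o__Bacillales;f__Bacillaceae;g__Bacillus"
    ),
    TaxonomyLineage.from_prefixed(
        "k__Archaea;p__Euryarchaeota;c__Methanomicrobia;o__Methanosarcinales;"
        "f__Methanosarcinaceae;g__Methanosarcina"
    ),
)


def brocadiaceae_benchmark(
    seed: int,
    alt_freq: float = 0.7,
    n_target: int = 20,
    n_background_per_clade: int = 15,
    alt_position: int = 13,
    alt_base: str = "T",
    decoy_fraction: float = 0.1,
) -> SyntheticRefSpec:
    """The planted-allele optimization benchmark.

    An anammox-like target clade (full Planctomycetes → Candidatus
    Brocadia lineage) carries an alternative ``alt_base`` at forward-site
    position ``alt_position`` (default: T at position 13, where the
    Pro341F template demands A) at frequency ``alt_freq``; three neutral
    background clades (two bacterial, one archaeal) carry the template
    alleles, with a small decoy fraction of site-free records.  On this
    set the single best widening of Pro341F is the position-13 A→W edit
    that defines Pro341FB.
    """
    target = CladeSpec(
        lineage=_TARGET_LINEAGE,
        n_records=n_target,
        alt_alleles=((alt_position, alt_base, alt_freq),),
    )
    background = tuple(
        CladeSpec(
            lineage=lin,
            n_records=n_background_per_clade,
            decoy_fraction=decoy_fraction,
        )
        for lin in _BACKGROUND_LINEAGES
    )
    return SyntheticRefSpec(clades=(target,) + background, seed=seed)


# ---------------------------------------------------------------------------
# synthetic abundance profiles


_ANAMMOX_LINEAGES = tuple(
    "sk__Bacteria;p__Planctomycetes;c__Planctomycetia;o__Candidatus Brocadiales;"
    f"f__Candidatus Brocadiaceae;g__Candidatus {g}"
    for g in ("Brocadia", "Kuenenia", "Anammoxoglobus", "Jettenia", "Scalindua")
)

_BACTERIAL_PHYLA = (
    "Proteobacteria", "Firmicutes", "Bacteroidetes", "Actinobacteria",
    "Chloroflexi", "Acidobacteria", "Nitrospirae", "Verrucomicrobia",
)

_BIOMES = (
    "root:Engineered:Wastewater:Activated Sludge",
    "root:Engineered:Wastewater:Industrial wastewater",
    "root:Engineered:Wastewater:Nutrient removal",
    "root:Engineered:Wastewater",
)


def generate_profiles(
    seed: int,
    n_studies: int = 49,
    n_samples: int = 3433,
    archaea_prevalence: float = 0.225,
    anammox_prevalence: float = 0.037,
    n_bacterial_genera: int = 1448,
    n_archaeal_genera: int = 12,
    genera_per_sample: tuple[int, int] = (15, 40),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a flat profiles table plus per-sample ground truth.

    Defaults emulate a wastewater-biome amplicon survey: ~3.4k samples
    across 49 studies, archaea present in ~22.5% of samples, anammox
    genera in ~3.7%, and a genus pool of 1465 distinct labels (bacterial +
    archaeal + the five anammox genera).  Each sample draws a random genus
    subset with log-uniform-ish counts; archaea/anammox positivity is an
    independent per-sample Bernoulli draw, recorded in the truth table.
    """
    if not (0 <= archaea_prevalence <= 1 and 0 <= anammox_prevalence <= 1):
        raise ValueError("prevalences must be in [0, 1]")
    rng = np.random.default_rng(seed)

    bact_pool = [
        f"sk__Bacteria;p__{_BACTERIAL_PHYLA[i % len(_BACTERIAL_PHYLA)]};g__Genus{i + 1:04d}"
        for i in range(n_bacterial_genera)
    ]
    arch_pool = [
        f"sk__Archaea;p__Euryarchaeota;g__Archgenus{i + 1:02d}"
        for i in range(n_archaeal_genera)
    ]

    rows: list[tuple] = []
    truth_rows: list[dict] = []
    lo, hi = genera_per_sample
    for si in range(n_samples):
        study = f"SYNSTUDY{(si % n_studies) + 1:03d}" if n_studies else "SYNSTUDY000"
        sample = f"SYNSAMPLE{si + 1:05d}"
        biome = _BIOMES[si % len(_BIOMES)]

        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(bact_pool), size=min(k, len(bact_pool)), replace=False)
        counts = rng.integers(1, 2000, size=len(chosen))
        for gi, c in zip(chosen, counts):
            rows.append((study, sample, biome, "amplicon", bact_pool[int(gi)], int(c)))

        archaea_pos = bool(rng.random() < archaea_prevalence)
        if archaea_pos:
            n_arch = int(rng.integers(1, 4))
            arch_idx = rng.choice(len(arch_pool), size=n_arch, replace=False)
            for gi in arch_idx:
                rows.append(
                    (study, sample, biome, "amplicon", arch_pool[int(gi)], int(rng.integers(1, 500)))
                )

        anammox_pos = bool(rng.random() < anammox_prevalence)
        if anammox_pos:
            lin = _ANAMMOX_LINEAGES[int(rng.integers(len(_ANAMMOX_LINEAGES)))]
            rows.append((study, sample, biome, "amplicon", lin, int(rng.integers(1, 200))))

        truth_rows.append(
            {
                "sample_id": sample,
                "study_id": study,
                "archaea_positive": archaea_pos,
                "anammox_positive": anammox_pos,
            }
        )

    profiles = pd.DataFrame(
        rows, columns=["study_id", "sample_id", "biome", "experiment_type", "lineage", "count"]
    )
    return profiles, pd.DataFrame(truth_rows)


def write_profiles_tsv(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, sep="\t", index=False)
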