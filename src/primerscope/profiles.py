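"""Prevalence mining of per-sample taxonomic abundance profiles.

Consumes flat, already-downloaded abundance tables (one row per sample ×
lineage, MGnify-download style) and summarizes them into genus richness,
per-kingdom prevalence and the prevalence of named genus sets across
samples and studies.  The built-in ``anammox`` set holds the five known
anaerobic-ammonium-oxidising genera of the family Candidatus Brocadiaceae:
Brocadia, Kuenenia, Anammoxoglobus, Jettenia and Scalindua.  Genus matching
tolerates the "Candidatus " prefix being present or absent, since profile
pipelines differ in printing it.

No network access: reproducibility requires frozen inputs, so the library
only ever reads local TSV files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "ANAMMOX_GENERA",
    "TaxonSet",
    "ANAMMOX",
    "ARCHAEA",
    "AbundanceProfile",
    "PrevalenceSummary",
    "read_profiles",
    "summarize_prevalence",
]

REQUIRED_COLUMNS = ("study_id", "sample_id", "biome", "experiment_type", "lineage", "count")

ANAMMOX_GENERA = (
    "Candidatus Brocadia",
    "Candidatus Kuenenia",
    "Candidatus Anammoxoglobus",
    "Candidatus Jettenia",
    "Candidatus Scalindua",
)

_KINGDOM_PREFIXES = ("sk__", "k__", "d__")


def _norm_genus(name: str) -> str:
    """Fold case and the optional 'Candidatus ' prefix for matching."""
    n = " ".join(name.split())
    low = n.casefold()
    if low.startswith("candidatus "):
        low = low[len("candidatus "):]
    return low


@dataclass(frozen=True)
class TaxonSet:
    """A named query set: either a list of genera or a whole kingdom."""

    name: str
    genera: frozenset[str] = frozenset()
    kingdom: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genera", frozenset(_norm_genus(g) for g in self.genera))
        if not self.genera and self.kingdom is None:
            raise ValueError(f"taxon set {self.name!r} is empty")


ANAMMOX = TaxonSet("anammox", genera=frozenset(ANAMMOX_GENERA))
ARCHAEA = TaxonSet("archaea", kingdom="Archaea")


def _parse_lineage_fields(lineage: str) -> tuple[str | None, str | None]:
    """Extract (kingdom, genus) from a rank-prefixed lineage string."""
    kingdom = None
    genus = None
    for token in lineage.split(";"):
        token = token.strip()
        low = token.lower()
        for p in _KINGDOM_PREFIXES:
            if low.startswith(p) and token[len(p):].strip():
                kingdom = token[len(p):].strip()
                break
        if low.startswith("g__") and token[3:].strip():
            genus = token[3:].strip()
    return kingdom, genus


@dataclass(frozen=True)
class AbundanceProfile:
    """One sample's lineage -> read-count table plus its metadata."""

    sample_id: str
    study_id: str
    biome: str = ""
    experiment_type: str = ""
    counts: dict[str, int] = field(default_factory=dict)

    def genera(self, min_count: int = 1) -> set[str]:
        """Normalized genus names with count >= min_count."""
        out = set()
        for lineage, count in self.counts.items():
            if count < min_count:
                continue
            _, genus = _parse_lineage_fields(lineage)
            if genus:
                out.add(_norm_genus(genus))
        return out

    def positive_for(self, taxon_set: TaxonSet, min_count: int = 1) -> bool:
        if taxon_set.kingdom is not None:
            want = taxon_set.kingdom.casefold()
            for lineage, count in self.counts.items():
                if count < min_count:
                    continue
                kingdom, _ = _parse_lineage_fields(lineage)
                if kingdom is not None and kingdom.casefold() == want:
                    return True
            return False
        return bool(self.genera(min_count) & taxon_set.genera)


def read_profiles(
    tsv_path: str | Path,
    biome_substring: str | None = None,
    experiment_type: str | None = None,
    keyword: str | None = None,
) -> list[AbundanceProfile]:
    """Read a flat profiles TSV and assemble one profile per sample.

    Filters are conjunctive: ``biome_substring`` is a case-insensitive
    substring of the biome field, ``experiment_type`` a case-insensitive
    exact match, and ``keyword`` a case-insensitive substring of the
    concatenated biome and study metadata (the "further filtered by the
    term" style of a portal free-text search).
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"profiles TSV {tsv_path} is missing columns {missing}; found {list(df.columns)}"
        )
    if len(df):
        df["count"] = df["count"].astype(int)

    profiles: dict[str, AbundanceProfile] = {}
    for row in df.itertuples(index=False):
        biome = row.biome or ""
        if biome_substring is not None and biome_substring.casefold() not in biome.casefold():
            continue
        if experiment_type is not None and (
            (row.experiment_type or "").casefold() != experiment_type.casefold()
        ):
            continue
        if keyword is not None:
            haystack = f"{biome} {row.study_id}".casefold()
            if keyword.casefold() not in haystack:
                continue
        prof = profiles.get(row.sample_id)
        if prof is None:
            prof = AbundanceProfile(
                sample_id=row.sample_id,
                study_id=row.study_id,
                biome=biome,
                experiment_type=row.experiment_type or "",
            )
            profiles[row.sample_id] = prof
        prof.counts[row.lineage] = prof.counts.get(row.lineage, 0) + int(row.count)
    return list(profiles.values())


@dataclass(frozen=True)
class PrevalenceSummary:
    """Cross-sample summary: richness, per-set positives and prevalences."""

    n_studies: int
    n_samples: int
    n_genera: int
    positives: dict[str, int]
    prevalence_pct: dict[str, float]
    n_positive_studies: dict[str, int]
    per_study: pd.DataFrame

    @property
    def defined(self) -> bool:
        return self.n_samples > 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "n_studies", "value": self.n_studies},
            {"metric": "n_samples", "value": self.n_samples},
            {"metric": "n_genera", "value": self.n_genera},
        ]
        for name in self.positives:
            rows.append({"metric": f"samples_with_{name}", "value": self.positives[name]})
            rows.append({"metric": f"pct_samples_with_{name}", "value": self.prevalence_pct[name]})
            rows.append({"metric": f"studies_with_{name}", "value": self.n_positive_studies[name]})
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path, per_study_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if per_study_path is not None:
            self.per_study.to_csv(per_study_path, sep="\t", index=False)


def summarize_prevalence(
    profiles: list[AbundanceProfile],
    taxa_of_interest: tuple[TaxonSet, ...] = (ARCHAEA, ANAMMOX),
    min_count: int = 1,
) -> PrevalenceSummary:
    """Summarize a profile collection.

    A sample is positive for a taxon set iff any of its genera (or any
    lineage under the set's kingdom) reaches ``min_count`` reads — presence
    by default.  Percentages over an empty collection are NaN-flagged, not
    zero.
    """
    n_samples = len(profiles)
    studies = sorted({p.study_id for p in profiles})
    all_genera: set[str] = set()
    positives = {t.name: 0 for t in taxa_of_interest}
    pos_studies: dict[str, set[str]] = {t.name: set() for t in taxa_of_interest}
    per_study_counts: dict[str, dict[str, int]] = {
        s: {"n_samples": 0, **{t.name: 0 for t in taxa_of_interest}} for s in studies
    }

    for p in profiles:
        all_genera |= p.genera(min_count)
        per_study_counts[p.study_id]["n_samples"] += 1
        for t in taxa_of_interest:
            if p.positive_for(t, min_count):
                positives[t.name] += 1
                pos_studies[t.name].add(p.study_id)
                per_study_counts[p.study_id][t.name] += 1

    prevalence = {
        name: (100.0 * n / n_samples if n_samples else math.nan)
        for name, n in positives.items()
    }
    per_study_rows = []
    for s in studies:
        row = {"study_id": s, "n_samples": per_study_counts[s]["n_samples"]}
        for t in taxa_of_interest:
            n_pos = per_study_counts[s][t.name]
            row[f"samples_with_{t.name}"] = n_pos
            row[f"pct_samples_with_{t.name}"] = (
                100.0 * n_pos / row["n_samples"] if row["n_samples"] else math.nan
            )
        per_study_rows.append(row)

    return PrevalenceSummary(
        n_studies=len(studies),
        n_samples=n_samples,
        n_genera=len(all_genera),
        positives=positives,
        prevalence_pct=prevalence,
        n_positive_studies={name: len(s) for name, s in pos_studies.items()},
        per_study=pd.DataFrame(per_study_rows),
    )
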