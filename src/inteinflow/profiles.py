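"""Catalog summaries, taxonomic tallies, density profiles and headline statistics.

The halobacterial intein survey's printed result tables are shipped as TSV
transcriptions in ``inteinflow/data`` so the summary statistics can be
recomputed without any external download:

* ``table1_catalog.tsv`` — the allele catalog (host gene annotations plus
  novelty flags for alleles and host proteins first reported by the survey);
* ``table2_distribution.tsv`` — per-allele tree-topology classification and
  sequence counts in Halobacteria / Bacteria / other Euryarchaeota;
* ``table3_nonhalo.tsv`` — non-halobacterial carriers of halobacterial
  intein alleles, with mini-intein and within-Halobacteria grouping flags.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


def _data_path(name: str):
    return resources.files("inteinflow.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    with resources.as_file(_data_path("table1_catalog.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_table2() -> pd.DataFrame:
    with resources.as_file(_data_path("table2_distribution.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_table3() -> pd.DataFrame:
    with resources.as_file(_data_path("table3_nonhalo.tsv")) as p:
        return pd.read_csv(p, sep="\t")


# ---------------------------------------------------------------------------
# Taxon annotation
# ---------------------------------------------------------------------------

GROUPS = ("Halobacteria", "Bacteria", "OtherEuryarchaeota", "Other")


@dataclass
class TaxonAnnotation:
    """Maps a genome/sequence id to its genus and coarse taxonomic group."""

    genus: dict[str, str]
    group: dict[str, str]

    def __post_init__(self):
        if set(self.genus) != set(self.group):
            raise ValueError("genus and group annotations cover different ids")

    def __contains__(self, sid: str) -> bool:
        return sid in self.genus

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonAnnotation":
        df = pd.read_csv(path, sep="\t")
        for col in ("id", "genus", "group"):
            if col not in df.columns:
                raise ValueError(f"annotation table missing column {col!r}")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"ids annotated more than once: {dups}")
        return cls(genus=dict(zip(df["id"], df["genus"])),
                   group=dict(zip(df["id"], df["group"])))


# ---------------------------------------------------------------------------
# Allele catalog
# ---------------------------------------------------------------------------

@dataclass
class CatalogEntry:
    allele: str
    host_gene: str
    annotation: str = ""
    new_allele: bool = False
    new_host_gene: bool = False
    members: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.new_host_gene and not self.new_allele:
            raise ValueError(
                f"{self.allele}: a new host gene implies a new allele")


@dataclass
class AlleleCatalog:
    entries: list[CatalogEntry]

    def __post_init__(self):
        ids = [e.allele for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate allele ids in catalog")

    @classmethod
    def from_table1(cls, df: pd.DataFrame | None = None) -> "AlleleCatalog":
        if df is None:
            df = load_table1()
        return cls(entries=[
            CatalogEntry(allele=r.allele, host_gene=r.host_gene,
                         annotation=r.extein_annotation,
                         new_allele=bool(r.new_allele),
                         new_host_gene=bool(r.new_host_gene))
            for r in df.itertuples()
        ])


@dataclass
class CatalogSummary:
    n_alleles: int
    n_host_genes: int
    n_new_alleles: int
    n_new_host_genes: int


def catalog_summary(catalog: AlleleCatalog) -> CatalogSummary:
    """Tally the survey-level counts from an allele catalog."""
    if not catalog.entries:
        raise ValueError("empty catalog")
    return CatalogSummary(
        n_alleles=len(catalog.entries),
        n_host_genes=len({e.host_gene for e in catalog.entries}),
        n_new_alleles=sum(e.new_allele for e in catalog.entries),
        n_new_host_genes=sum(e.new_host_gene for e in catalog.entries),
    )


# ---------------------------------------------------------------------------
# Group tallies and density profiles
# ---------------------------------------------------------------------------

def group_tally(member_ids: Iterable[str],
                annotation: TaxonAnnotation) -> dict[str, int]:
    """Per-taxonomic-group sequence counts for one allele's membership."""
    counts = {g: 0 for g in GROUPS}
    for sid in member_ids:
        if sid not in annotation:
            raise ValueError(f"unannotated sequence id: {sid!r}")
        grp = annotation.group[sid]
        counts[grp] = counts.get(grp, 0) + 1
    return counts


@dataclass
class DensityProfile:
    proportions: dict[str, float]
    n_genera: int


def density_profile(member_ids: Iterable[str],
                    annotation: TaxonAnnotation) -> DensityProfile:
    """Per-genus proportion of an allele's sequences (sums to 1).

    The genus count corresponds to the number of column breaks in a
    stacked-density chart of the allele.
    """
    member_ids = list(member_ids)
    if not member_ids:
        raise ValueError("empty allele membership")
    for sid in member_ids:
        if sid not in annotation:
            raise ValueError(f"unannotated sequence id: {sid!r}")
    counts = Counter(annotation.genus[sid] for sid in member_ids)
    total = sum(counts.values())
    props = {g: c / total for g, c in sorted(counts.items())}
    return DensityProfile(proportions=props, n_genera=len(counts))


# ---------------------------------------------------------------------------
# Headline statistics
# ---------------------------------------------------------------------------

@dataclass
class HeadlineStats:
    pct_monophyletic: int
    n_polyphyletic: int
    polyphyletic_by_group: dict[str, int]
    pct_multi_allele_genomes: float | None = None


def headline_stats(monophyly_labels: Mapping[str, str],
                   profile=None) -> HeadlineStats:
    """Survey-level summary of monophyly calls and multi-allele genomes.

    ``monophyly_labels`` maps allele -> "Monophyletic" or
    "Polyphyletic-<group>".  The monophyletic percentage is rounded to the
    nearest integer (the precision the survey reports).  When an
    AlleleProfile is supplied, also reports the percentage of genomes
    carrying two or more intein alleles (mini and large alike count;
    missing cells are ignored).
    """
    if not monophyly_labels:
        raise ValueError("no monophyly labels supplied")
    labels = dict(monophyly_labels)
    n = len(labels)
    mono = sum(1 for v in labels.values() if v.lower().startswith("mono"))
    poly_groups = Counter(
        v.split("-", 1)[1] if "-" in v else "unspecified"
        for v in labels.values() if v.lower().startswith("poly")
    )
    pct_multi = None
    if profile is not None:
        multi = sum(1 for g in profile.genomes if len(profile.carried_alleles(g)) >= 2)
        pct_multi = 100.0 * multi / len(profile.genomes)
    return HeadlineStats(
        pct_monophyletic=int(round(100.0 * mono / n)),
        n_polyphyletic=n - mono,
        polyphyletic_by_group=dict(poly_groups),
        pct_multi_allele_genomes=pct_multi,
    )


def interrupting_state_counts(table3: pd.DataFrame | None = None) -> dict[str, int]:
    """Mini/large tallies of non-halobacterial taxa interrupting polyphyletic clades.

    Counts rows of the Table-3 transcription for the four polyphyletic
    alleles whose taxa are outside the Halobacteria.  The printed flags do
    not pin down the survey's own "5 of 11 large" count under any single
    counting rule, so this tally is reported for inspection, not asserted.
    """
    df = table3 if table3 is not None else load_table3()
    t2 = load_table2()
    poly = set(t2.loc[t2.tree_topology.str.startswith("Poly"), "allele"])
    sub = df[(df.allele.isin(poly)) & (df.phylum != "Halobacteria")]
    return {"mini": int(sub["mini"].sum()),
            "large": int((1 - sub["mini"]).sum()),
            "total": int(len(sub))}


# ---------------------------------------------------------------------------
# Genome-survey summary (requires the supplementary genome table)
# ---------------------------------------------------------------------------

@dataclass
class GenomeSurveySummary:
    n_genomes: int
    n_genera: int
    pct_by_genus: dict[str, float]


def sm1_summary(path: str | Path) -> GenomeSurveySummary:
    """Genome-level survey numbers from a supplementary genome table.

    The survey's genome list (genome id, genus) is not distributed with
    this package; callers who have it can supply it as a TSV with columns
    ``genome`` and ``genus``.  Without the file this summary — and every
    claim depending on it — is simply unavailable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"supplementary genome table not found: {path}; "
            "genome-level survey statistics require it")
    df = pd.read_csv(path, sep="\t")
    for col in ("genome", "genus"):
        if col not in df.columns:
            raise ValueError(f"genome table missing column {col!r}")
    counts = df["genus"].value_counts()
    n = len(df)
    return GenomeSurveySummary(
        n_genomes=n,
        n_genera=int(counts.size),
        pct_by_genus={g: 100.0 * c / n for g, c in counts.items()},
    )
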