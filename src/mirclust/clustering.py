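"""Cluster calling by the inter-precursor distance rule, and composition stats.

A cluster is a maximal chain of >= 2 precursors on the same chromosome and
strand in which consecutive precursors are separated by less than ``max_gap``
nucleotides of intervening sequence (strict inequality).  The gap is measured
edge-to-edge; overlapping precursors count as gap 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import MicroRNALocus

DEFAULT_MAX_GAP = 10_000


@dataclass
class Cluster:
    """An ordered run of clustered precursor loci on one strand."""

    cluster_id: str
    species_id: str
    chrom: str
    strand: str
    members: list[str]          # mirna_id, sorted by start coordinate
    start: int                  # min start over members (1-based)
    end: int                    # max end over members

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least 2 members")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def pairwise_gap(a: MicroRNALocus, b: MicroRNALocus) -> int | None:
    """Nucleotides of intervening sequence between two precursors.

    Returns ``None`` ("incomparable") for loci from different species,
    chromosomes or strands; 0 for overlapping precursors; otherwise
    ``start(downstream) - end(upstream) - 1``.
    """
    if a.species_id != b.species_id or a.chrom != b.chrom or a.strand != b.strand:
        return None
    up, down = (a, b) if a.start <= b.start else (b, a)
    if down.start <= up.end:  # overlap
        return 0
    return down.start - up.end - 1


def call_clusters(
    loci: Iterable[MicroRNALocus],
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[Cluster]:
    """Single-linkage chaining of same-strand loci at gap < ``max_gap``.

    Singletons are not clusters; every locus is assigned to at most one
    cluster.  Loci must come from a single species.
    """
    loci = list(loci)
    species = {l.species_id for l in loci}
    if len(species) > 1:
        raise ValueError(f"loci from multiple species: {sorted(species)}")
    by_group: dict[tuple[str, str], list[MicroRNALocus]] = {}
    for locus in loci:
        by_group.setdefault((locus.chrom, locus.strand), []).append(locus)

    clusters: list[Cluster] = []
    for (chrom, strand) in sorted(by_group):
        group = sorted(by_group[(chrom, strand)], key=lambda l: (l.start, l.end))
        run: list[MicroRNALocus] = []
        for locus in group:
            if run and pairwise_gap(run[-1], locus) < max_gap:  # type: ignore[operator]
                run.append(locus)
            else:
                if len(run) >= 2:
                    clusters.append(_make_cluster(run, len(clusters)))
                run = [locus]
        if len(run) >= 2:
            clusters.append(_make_cluster(run, len(clusters)))
    return clusters


def _make_cluster(run: Sequence[MicroRNALocus], index: int) -> Cluster:
    first = run[0]
    return Cluster(
        cluster_id=f"{first.species_id}_cl{index + 1:03d}",
        species_id=first.species_id,
        chrom=first.chrom,
        strand=first.strand,
        members=[l.mirna_id for l in run],
        start=min(l.start for l in run),
        end=max(l.end for l in run),
    )


@dataclass
class CompositionStats:
    """Per-cluster size/family counts plus the derived frequency tables."""

    per_cluster: pd.DataFrame      # cluster_id, size, n_annotation_families
    size_freq: "pd.Series[int]"    # size -> number of clusters
    family_freq: "pd.Series[int]"  # n families -> number of clusters
    bubble: pd.DataFrame           # rows = size, cols = n families, cells = counts

    @property
    def n_single_family(self) -> int:
        return int((self.per_cluster["n_annotation_families"] == 1).sum())


def composition_stats(
    clusters: Sequence[Cluster],
    loci: Iterable[MicroRNALocus],
) -> CompositionStats:
    """Member counts and distinct annotation-family counts per cluster."""
    fam_of = {l.mirna_id: l.annotation_family for l in loci}
    rows = []
    for c in clusters:
        families = {fam_of[m] for m in c.members}
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "size": c.size,
                "n_annotation_families": len(families),
            }
        )
    per_cluster = pd.DataFrame(
        rows, columns=["cluster_id", "size", "n_annotation_families"]
    )
    size_freq = per_cluster["size"].value_counts().sort_index()
    family_freq = per_cluster["n_annotation_families"].value_counts().sort_index()
    if len(per_cluster):
        bubble = (
            per_cluster.groupby(["size", "n_annotation_families"])
            .size()
            .unstack(fill_value=0)
        )
    else:
        bubble = pd.DataFrame()
    return CompositionStats(per_cluster, size_freq, family_freq, bubble)


def clustered_fraction_by_age(
    loci: Iterable[MicroRNALocus],
    ages: Mapping[str, str],
    max_gap: int = DEFAULT_MAX_GAP,
) -> pd.DataFrame:
    """Fraction of loci of each origin lineage that sit inside a cluster.

    ``ages`` maps mirna_id -> origin lineage name.  Lineages with zero loci
    are omitted.  Returns a DataFrame indexed by lineage with columns
    n_clustered, n_total, fraction.
    """
    loci = list(loci)
    clustered = {m for c in call_clusters(loci, max_gap=max_gap) for m in c.members}
    totals: Counter[str] = Counter()
    hits: Counter[str] = Counter()
    for locus in loci:
        lineage = ages[locus.mirna_id]
        totals[lineage] += 1
        if locus.mirna_id in clustered:
            hits[lineage] += 1
    rows = {
        lineage: {
            "n_clustered": hits[lineage],
            "n_total": totals[lineage],
            "fraction": hits[lineage] / totals[lineage],
        }
        for lineage in totals
    }
    return pd.DataFrame.from_dict(rows, orient="index")
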