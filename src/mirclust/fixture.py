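"""Packaged fixture: 21 curated Drosophila microRNA clusters.

The fixture encodes, per cluster, the member microRNAs in genomic order,
their annotation and phylogenetic family labels, the recorded founding
event, the origin lineage and (where curated) the original microRNA.  A
per-family presence/absence table over an eight-species tree is synthesized
so that single-gain parsimony reproduces each member's recorded age, and
per-species homolog coordinates are laid out deterministically so the
linkage tests see every family pair co-located ancestrally.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import FixtureError
from .model import HomologyMap, MicroRNALocus, SpeciesPhylogeny
from .origin import Source

FOCAL_SPECIES = "dme"
LEAF_LINEAGES = {"dme": "Melanogaster"}

_CHROMS = ("2L", "2R", "3L", "3R", "X")
_SOURCE_NAMES = {
    "NewHairpin": Source.NEW_HAIRPIN,
    "Duplication": Source.DUPLICATION,
    "Unknown": Source.UNKNOWN,
    "Fusion": Source.FUSION,
}


@dataclass(frozen=True)
class Table1Member:
    mirna_id: str
    annotation_family: str
    phylo_family: str
    origin_lineage: str


@dataclass(frozen=True)
class Table1Record:
    cluster_id: str
    name: str
    members: tuple[Table1Member, ...]
    source: Source
    lineage: str
    original_mirna: str | None
    notes: str

    @property
    def member_ids(self) -> list[str]:
        return [m.mirna_id for m in self.members]

    @property
    def n_annotation_families(self) -> int:
        return len({m.annotation_family for m in self.members})


@dataclass
class Table1Fixture:
    records: list[Table1Record]
    tree: SpeciesPhylogeny
    presence: dict[str, list[str]]          # phylo_family -> species with it
    loci: dict[str, MicroRNALocus]          # focal-species loci by mirna_id
    homology: HomologyMap                   # loci for all fixture species

    @property
    def focal_species(self) -> str:
        return FOCAL_SPECIES

    def focal_loci(self) -> list[MicroRNALocus]:
        return sorted(self.loci.values(), key=lambda l: (l.chrom, l.start))

    def record_by_members(self, member_ids) -> Table1Record | None:
        wanted = set(member_ids)
        for rec in self.records:
            if set(rec.member_ids) == wanted:
                return rec
        return None

    def source_counts(self) -> dict[Source, int]:
        counts = {s: 0 for s in Source}
        for rec in self.records:
            counts[rec.source] += 1
        return counts

    def lineage_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.lineage] = counts.get(rec.lineage, 0) + 1
        return counts


def _data_path(name: str):
    return resources.files("mirclust.data").joinpath(name)


def _member_layout(cluster_index: int, n: int) -> list[tuple[int, int]]:
    """Deterministic (start, end) coordinates for n adjacent precursors."""
    coords = []
    cursor = 50_000 + cluster_index * 37_000
    for i in range(n):
        length = 80 + (i % 3) * 8
        coords.append((cursor, cursor + length - 1))
        cursor += length + 90 + ((cluster_index * 53 + i * 37) % 160)
    return coords


def _cluster_placement(cluster_index: int) -> tuple[str, str]:
    chrom = _CHROMS[cluster_index % len(_CHROMS)]
    strand = "+" if cluster_index % 2 == 0 else "-"
    return chrom, strand


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged 21-cluster fixture and check its invariants."""
    clusters_df = pd.read_csv(_data_path("table1_clusters.tsv"), sep="\t")
    members_df = pd.read_csv(_data_path("table1_members.tsv"), sep="\t")
    presence_df = pd.read_csv(_data_path("table1_presence.tsv"), sep="\t")

    with _data_path("fixture_tree.nwk").open() as fh:
        tree = SpeciesPhylogeny.from_newick(fh.read(), leaf_lineages=LEAF_LINEAGES)

    presence = {
        str(row.phylo_family): str(row.species).split(",")
        for row in presence_df.itertuples(index=False)
    }

    members_by_cluster: dict[str, list[Table1Member]] = {}
    for row in members_df.sort_values(["cluster_id", "member_index"]).itertuples(
        index=False
    ):
        members_by_cluster.setdefault(str(row.cluster_id), []).append(
            Table1Member(
                mirna_id=str(row.mirna_id),
                annotation_family=str(row.annotation_family),
                phylo_family=str(row.phylo_family),
                origin_lineage=str(row.origin_lineage),
            )
        )

    records: list[Table1Record] = []
    for row in clusters_df.itertuples(index=False):
        cid = str(row.cluster_id)
        original = row.original_mirna if isinstance(row.original_mirna, str) else None
        notes = row.notes if isinstance(row.notes, str) else ""
        records.append(
            Table1Record(
                cluster_id=cid,
                name=str(row.name),
                members=tuple(members_by_cluster[cid]),
                source=_SOURCE_NAMES[str(row.source)],
                lineage=str(row.lineage),
                original_mirna=original,
                notes=notes,
            )
        )

    loci, homology = _build_loci(records, presence, tree)
    fixture = Table1Fixture(records, tree, presence, loci, homology)
    _validate(fixture)
    return fixture


def _build_loci(
    records: list[Table1Record],
    presence: dict[str, list[str]],
    tree: SpeciesPhylogeny,
) -> tuple[dict[str, MicroRNALocus], HomologyMap]:
    homology = HomologyMap(tree.species)
    focal: dict[str, MicroRNALocus] = {}
    for k, rec in enumerate(records):
        chrom, strand = _cluster_placement(k)
        for species in tree.species:
            present = [m for m in rec.members if species in presence[m.phylo_family]]
            if not present:
                continue
            coords = _member_layout(k, len(present))
            for member, (start, end) in zip(present, coords):
                base_name = member.mirna_id.removeprefix(f"{FOCAL_SPECIES}-")
                mirna_id = (
                    member.mirna_id
                    if species == FOCAL_SPECIES
                    else f"{species}-{base_name}"
                )
                locus = MicroRNALocus(
                    mirna_id=mirna_id,
                    species_id=species,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    annotation_family=member.annotation_family,
                    phylo_family=member.phylo_family,
                )
                homology.add(locus)
                if species == FOCAL_SPECIES:
                    focal[mirna_id] = locus
    return focal, homology


def _validate(fixture: Table1Fixture) -> None:
    if len(fixture.records) != 21:
        raise FixtureError(f"expected 21 records, found {len(fixture.records)}")
    sources = fixture.source_counts()
    expected_sources = {
        Source.NEW_HAIRPIN: 13,
        Source.DUPLICATION: 6,
        Source.UNKNOWN: 2,
        Source.FUSION: 0,
    }
    if sources != expected_sources:
        raise FixtureError(f"source tally {sources} != {expected_sources}")
    lineages = fixture.lineage_counts()
    expected_lineages = {
        "Melanogaster": 2,
        "Drosophila": 7,
        "Insects": 5,
        "Protostomes": 5,
        "Metazoans": 2,
    }
    if lineages != expected_lineages:
        raise FixtureError(f"lineage tally {lineages} != {expected_lineages}")
    n_single = sum(1 for rec in fixture.records if rec.n_annotation_families == 1)
    if n_single != 4:
        raise FixtureError(f"expected 4 single-family clusters, found {n_single}")
    for rec in fixture.records:
        for member in rec.members:
            if member.phylo_family not in fixture.presence:
                raise FixtureError(
                    f"{member.mirna_id}: no presence row for {member.phylo_family}"
                )
            node = fixture.tree.mrca(fixture.presence[member.phylo_family])
            if fixture.tree.lineage_name(node) != member.origin_lineage:
                raise FixtureError(
                    f"{member.mirna_id}: presence implies origin "
                    f"{fixture.tree.lineage_name(node)}, recorded "
                    f"{member.origin_lineage}"
                )
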