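"""End-to-end fixture report: re-derive every summary number from scratch.

Loads the packaged 21-cluster fixture, re-calls clusters from the focal
species' coordinates, classifies every cluster's founding event against the
fixture homology and species tree, and tallies the results.  Any
disagreement between a re-derived call and the fixture's recorded source is
reported as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .clustering import DEFAULT_MAX_GAP, call_clusters, composition_stats
from .fixture import Table1Fixture, load_table1_fixture
from .origin import OriginCall, Source, classify_cluster_origin, summarize_origins

INSECT_OR_YOUNGER = ("Melanogaster", "Drosophila", "Insects")


@dataclass
class FixtureReport:
    n_clusters: int
    source_counts: dict[str, int]
    lineage_counts: dict[str, int]
    n_single_family: int
    n_insect_or_younger: int
    calls: list[OriginCall]
    mismatches: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.mismatches

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "source_counts": self.source_counts,
            "lineage_counts": self.lineage_counts,
            "n_single_family": self.n_single_family,
            "n_insect_or_younger": self.n_insect_or_younger,
            "mismatches": self.mismatches,
        }


def report_fixture(
    fixture: Table1Fixture | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
) -> FixtureReport:
    """Run the full pipeline over the packaged fixture and tally results."""
    fixture = fixture or load_table1_fixture()
    loci = fixture.focal_loci()
    clusters = call_clusters(loci, max_gap=max_gap)
    loci_by_id = {l.mirna_id: l for l in loci}

    calls: list[OriginCall] = []
    mismatches: list[str] = []
    for cluster in clusters:
        call = classify_cluster_origin(
            cluster, loci_by_id, fixture.homology, fixture.tree, max_gap=max_gap
        )
        calls.append(call)
        record = fixture.record_by_members(cluster.members)
        if record is None:
            mismatches.append(
                f"{cluster.cluster_id}: membership {cluster.members} matches no "
                "fixture record"
            )
            continue
        if call.source != record.source:
            mismatches.append(
                f"{record.name}: called {call.source.value}, "
                f"recorded {record.source.value}"
            )
        if call.origin_lineage != record.lineage:
            mismatches.append(
                f"{record.name}: origin lineage {call.origin_lineage}, "
                f"recorded {record.lineage}"
            )
        if record.original_mirna and call.original_mirna != record.original_mirna:
            mismatches.append(
                f"{record.name}: original {call.original_mirna}, "
                f"recorded {record.original_mirna}"
            )

    summary = summarize_origins(calls)
    stats = composition_stats(clusters, loci)
    return FixtureReport(
        n_clusters=len(clusters),
        source_counts={s.value: summary.by_source[s] for s in Source},
        lineage_counts=dict(summary.by_lineage),
        n_single_family=stats.n_single_family,
        n_insect_or_younger=sum(
            summary.by_lineage.get(l, 0) for l in INSECT_OR_YOUNGER
        ),
        calls=calls,
        mismatches=mismatches,
    )
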