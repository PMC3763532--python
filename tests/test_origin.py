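"""Age inference, founding-event classification, cross-species calls."""

import numpy as np
import pytest

from mirclust import (
    HomologyMap,
    MicroRNALocus,
    Source,
    CrossSpeciesCategory,
    call_clusters,
    classify_cluster_origin,
    classify_cross_species_pair,
    infer_origin_node,
    summarize_origins,
)
from mirclust.clustering import Cluster
from mirclust.errors import HomologyError

from conftest import dollo_minimal_gain, random_binary_tree


class TestInferOriginNode:
    def test_single_focal_leaf(self, fixture_tree):
        node = infer_origin_node({"dme"}, fixture_tree)
        assert node == "dme"
        assert fixture_tree.lineage_name(node) == "Melanogaster"

    def test_all_leaves_root(self, fixture_tree):
        assert infer_origin_node(fixture_tree.species, fixture_tree) == "Metazoans"

    def test_dme_aga_is_insects(self, fixture_tree):
        assert infer_origin_node({"dme", "aga"}, fixture_tree) == "Insects"
        nodes, losses = dollo_minimal_gain(fixture_tree, {"dme", "aga"})
        assert "Insects" in nodes

    def test_empty_set_rejected(self, fixture_tree):
        with pytest.raises(HomologyError, match="no homologs"):
            infer_origin_node(set(), fixture_tree)

    def test_matches_exhaustive_dollo_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            tree = random_binary_tree(rng, int(rng.integers(3, 13)))
            leaves = tree.species
            k = int(rng.integers(1, len(leaves) + 1))
            present = set(rng.choice(leaves, size=k, replace=False))
            mrca = infer_origin_node(present, tree)
            nodes, _losses = dollo_minimal_gain(tree, present)
            assert mrca in nodes


def _hom_pair(tree, entries):
    """Build a HomologyMap from (mirna_id, species, chrom, start, strand, family)."""
    hom = HomologyMap(tree.species)
    for mid, sp, chrom, start, strand, fam in entries:
        hom.add(
            MicroRNALocus(
                mid, sp, chrom, start, start + 89, strand, phylo_family=fam
            )
        )
    return hom


class TestClassifyClusterOrigin:
    def _call(self, table1, name, **kwargs):
        rec = next(r for r in table1.records if r.name == name)
        loci = [table1.loci[m] for m in rec.member_ids]
        cluster = call_clusters(loci)[0]
        return classify_cluster_origin(
            cluster, table1.loci, table1.homology, table1.tree, **kwargs
        )

    def test_new_hairpin_999_4969(self, table1):
        call = self._call(table1, "999/4969")
        assert call.source == Source.NEW_HAIRPIN
        assert call.original_mirna == "dme-mir-999"
        assert call.origin_lineage == "Melanogaster"

    def test_duplication_281(self, table1):
        call = self._call(table1, "281-2/281-1")
        assert call.source == Source.DUPLICATION
        assert call.origin_lineage == "Drosophila"

    def test_unknown_9c_306_79_9b(self, table1):
        call = self._call(table1, "9c/306/79/9b")
        assert call.source == Source.UNKNOWN
        assert call.origin_lineage == "Insects"

    def test_original_mir_34_despite_genomic_order(self, table1):
        # the oldest founder is the last member in genomic order
        call = self._call(table1, "317/277/34")
        assert call.source == Source.NEW_HAIRPIN
        assert call.original_mirna == "dme-mir-34"
        assert call.origin_lineage == "Protostomes"

    def test_constructed_fusion(self, fixture_tree):
        # two ancient families co-located in dme but on different
        # chromosomes in the outgroup -> disparate loci -> FUSION
        entries = [
            ("dme-a", "dme", "2L", 1000, "+", "famA"),
            ("dme-b", "dme", "2L", 1400, "+", "famB"),
            ("hsa-a", "hsa", "1", 1000, "+", "famA"),
            ("hsa-b", "hsa", "9", 1000, "+", "famB"),
        ]
        hom = _hom_pair(fixture_tree, entries)
        loci = {l.mirna_id: l for l in hom.all_loci() if l.species_id == "dme"}
        cluster = call_clusters(list(loci.values()))[0]
        call = classify_cluster_origin(cluster, loci, hom, fixture_tree)
        assert call.source == Source.FUSION

    def test_member_without_homology_named(self, table1, fixture_tree):
        hom = HomologyMap(fixture_tree.species)
        rec = table1.records[0]
        loci = [table1.loci[m] for m in rec.member_ids]
        cluster = call_clusters(loci)[0]
        with pytest.raises(HomologyError, match=rec.member_ids[0]):
            classify_cluster_origin(cluster, table1.loci, hom, fixture_tree)

    def test_permutation_invariance(self, table1):
        rec = next(r for r in table1.records if r.name == "6-3/6-2/6-1/5/4/286/3/309")
        loci = [table1.loci[m] for m in rec.member_ids]
        base = call_clusters(loci)[0]
        reference = classify_cluster_origin(
            base, table1.loci, table1.homology, table1.tree
        )
        rng = np.random.default_rng(0)
        members = list(base.members)
        for _ in range(20):
            rng.shuffle(members)
            shuffled = Cluster(
                base.cluster_id, base.species_id, base.chrom, base.strand,
                list(members), base.start, base.end,
            )
            call = classify_cluster_origin(
                shuffled, table1.loci, table1.homology, table1.tree
            )
            assert (call.source, call.origin_lineage, call.original_mirna) == (
                reference.source, reference.origin_lineage, reference.original_mirna,
            )

    def test_all_21_fixture_calls_match_records(self, table1):
        for rec in table1.records:
            call = self._call(table1, rec.name)
            assert call.source == rec.source, rec.name
            assert call.origin_lineage == rec.lineage, rec.name
            if rec.original_mirna:
                assert call.original_mirna == rec.original_mirna, rec.name

    def test_masked_duplication_caveat_in_evidence(self, fixture_tree):
        # a duplication whose family is single-copy in an outgroup: the call
        # stands, but the loss-masking caveat is recorded in the evidence
        entries = [
            ("dme-a1", "dme", "2L", 1000, "+", "famA"),
            ("dme-a2", "dme", "2L", 1400, "+", "famA"),
            ("cel-a1", "cel", "I", 1000, "+", "famA"),
        ]
        hom = _hom_pair(fixture_tree, entries)
        loci = {l.mirna_id: l for l in hom.all_loci() if l.species_id == "dme"}
        cluster = call_clusters(list(loci.values()))[0]
        call = classify_cluster_origin(cluster, loci, hom, fixture_tree)
        assert call.source == Source.DUPLICATION
        assert "masked by loss" in call.evidence


class TestSummarizeOrigins:
    def test_fixture_tallies(self, table1):
        loci = table1.focal_loci()
        clusters = call_clusters(loci)
        calls = [
            classify_cluster_origin(c, table1.loci, table1.homology, table1.tree)
            for c in clusters
        ]
        summary = summarize_origins(calls)
        assert summary.by_source[Source.NEW_HAIRPIN] == 13
        assert summary.by_source[Source.DUPLICATION] == 6
        assert summary.by_source[Source.UNKNOWN] == 2
        assert summary.by_source[Source.FUSION] == 0
        assert summary.by_lineage["Drosophila"] == 7

    def test_empty(self):
        summary = summarize_origins([])
        assert summary.n_calls == 0
        assert all(v == 0 for v in summary.by_source.values())

    def test_tallies_sum_to_calls(self, table1):
        loci = table1.focal_loci()
        clusters = call_clusters(loci)
        calls = [
            classify_cluster_origin(c, table1.loci, table1.homology, table1.tree)
            for c in clusters
        ]
        summary = summarize_origins(calls)
        assert summary.n_calls == len(calls)
        assert sum(summary.by_lineage.values()) == len(calls)


class TestCrossSpeciesPair:
    def test_independent_new_hairpin(self, fixture_tree):
        # an ancient family clustered, in mammals only, with a
        # mammal-restricted partner
        entries = [
            ("dme-7", "dme", "2L", 1000, "+", "mir-7"),
            ("hsa-7", "hsa", "9", 1000, "+", "mir-7"),
            ("hsa-1179", "hsa", "9", 1300, "+", "mir-1179"),
        ]
        hom = _hom_pair(fixture_tree, entries)
        call = classify_cross_species_pair(
            "mir-7", "mir-1179", hom, fixture_tree, ref_species="dme"
        )
        assert call.category == CrossSpeciesCategory.INDEPENDENT_NEW_HAIRPIN
        assert call.clustered_in == ["hsa"]

    def test_independent_duplication(self, fixture_tree):
        # tandem copies restricted to a non-reference lineage
        entries = [
            ("dme-31a", "dme", "2L", 1000, "+", "mir-31"),
            ("hsa-31a", "hsa", "9", 1000, "+", "mir-31"),
            ("hsa-31b", "hsa", "9", 1400, "+", "mir-31"),
        ]
        hom = _hom_pair(fixture_tree, entries)
        call = classify_cross_species_pair(
            "mir-31", "mir-31", hom, fixture_tree, ref_species="dme"
        )
        assert call.category == CrossSpeciesCategory.INDEPENDENT_DUPLICATION

    def test_linked_beyond_threshold(self, fixture_tree):
        # clustered together in outgroups; same chrom/strand but >10 kb in ref
        entries = [
            ("dme-1", "dme", "2L", 1000, "+", "mir-1"),
            ("dme-133", "dme", "2L", 60_000, "+", "mir-133"),
            ("hsa-1", "hsa", "18", 1000, "+", "mir-1"),
            ("hsa-133", "hsa", "18", 1300, "+", "mir-133"),
        ]
        hom = _hom_pair(fixture_tree, entries)
        call = classify_cross_species_pair(
            "mir-1", "mir-133", hom, fixture_tree, ref_species="dme"
        )
        assert call.category == CrossSpeciesCategory.LINKED_BEYOND_THRESHOLD

    def test_cluster_split(self, fixture_tree):
        # both ancient, clustered ancestrally, on different chromosomes in ref
        entries = [
            ("dme-9", "dme", "2L", 1000, "+", "mir-9"),
            ("dme-279", "dme", "3R", 1000, "+", "mir-279"),
            ("hsa-9", "hsa", "1", 1000, "+", "mir-9"),
            ("hsa-279", "hsa", "1", 1300, "+", "mir-279"),
        ]
        hom = _hom_pair(fixture_tree, entries)
        call = classify_cross_species_pair(
            "mir-9", "mir-279", hom, fixture_tree, ref_species="dme"
        )
        assert call.category == CrossSpeciesCategory.CLUSTER_SPLIT

    def test_pair_clustered_nowhere_rejected(self, fixture_tree):
        entries = [
            ("dme-x", "dme", "2L", 1000, "+", "famX"),
            ("hsa-x", "hsa", "1", 1000, "+", "famX"),
            ("hsa-y", "hsa", "2", 1000, "+", "famY"),
        ]
        hom = _hom_pair(fixture_tree, entries)
        with pytest.raises(HomologyError, match="not clustered"):
            classify_cross_species_pair(
                "famX", "famY", hom, fixture_tree, ref_species="dme"
            )
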