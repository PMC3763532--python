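"""Age inference and cluster founding-event classification.

The age of a microRNA family is the most recent common ancestor of the
species in which the family is found (single-gain, any-losses parsimony).
A cluster's founding event is decided from its two oldest members:

1. rank members by the age of their ``phylo_family`` (more ancestral =
   older; ties broken by genomic order, which never changes the verdict);
2. if two equally oldest members share a family -> DUPLICATION;
3. else, if some sufficiently old species carries homologs of both founder
   families and none shows them linked -> FUSION;
4. else, founders of equal age but different families -> UNKNOWN;
5. else -> NEW_HAIRPIN: the younger founder arose inside the transcript of
   the strictly older one, which is reported as the original microRNA.

A cluster's origin lineage is the age of the younger founder (the time of
the cluster-forming event); for DUPLICATION and UNKNOWN both founders have
the same age, which is reported directly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .clustering import DEFAULT_MAX_GAP, Cluster, pairwise_gap
from .errors import HomologyError, TreeError
from .model import HomologyMap, MicroRNALocus, SpeciesPhylogeny


class Source(str, Enum):
    DUPLICATION = "DUPLICATION"
    NEW_HAIRPIN = "NEW_HAIRPIN"
    FUSION = "FUSION"
    UNKNOWN = "UNKNOWN"


class CrossSpeciesCategory(str, Enum):
    INDEPENDENT_DUPLICATION = "INDEPENDENT_DUPLICATION"
    INDEPENDENT_NEW_HAIRPIN = "INDEPENDENT_NEW_HAIRPIN"
    LINKED_BEYOND_THRESHOLD = "LINKED_BEYOND_THRESHOLD"
    CLUSTER_SPLIT = "CLUSTER_SPLIT"


@dataclass
class OriginCall:
    """Verdict on the event that founded one cluster."""

    cluster_id: str
    source: Source
    origin_lineage: str
    original_mirna: str | None = None
    evidence: str = ""


@dataclass
class CrossSpeciesCall:
    """Verdict on a focal-species-unclustered pair clustered elsewhere."""

    families: tuple[str, str]
    category: CrossSpeciesCategory
    clustered_in: list[str]


def infer_origin_node(
    present_in: Iterable[str],
    tree: SpeciesPhylogeny,
) -> str:
    """Origin node of a character under single-gain parsimony: the MRCA of
    the species that carry it."""
    species = list(present_in)
    if not species:
        raise HomologyError("no homologs: cannot infer an origin")
    for s in species:
        if not tree.has_node(s):
            raise TreeError(f"species {s!r} not in the tree")
    return tree.mrca(species)


def _family_origin(family: str, hom: HomologyMap, tree: SpeciesPhylogeny) -> str:
    species = hom.species_with(family)
    if not species:
        raise HomologyError(f"family {family!r} has no homologs in any species")
    return infer_origin_node(species, tree)


def _linked_in_species(
    fam_a: str,
    fam_b: str,
    species: str,
    hom: HomologyMap,
    max_gap: int,
) -> bool:
    """True if some famA locus lies within max_gap of some famB locus."""
    for la in hom.loci(fam_a, species):
        for lb in hom.loci(fam_b, species):
            if la.mirna_id == lb.mirna_id:
                continue
            gap = pairwise_gap(la, lb)
            if gap is not None and gap < max_gap:
                return True
    return False


def classify_cluster_origin(
    cluster: Cluster,
    loci: Mapping[str, MicroRNALocus],
    hom: HomologyMap,
    tree: SpeciesPhylogeny,
    max_gap: int = DEFAULT_MAX_GAP,
) -> OriginCall:
    """Classify the founding event of one cluster.

    ``loci`` maps mirna_id -> locus for the cluster's (focal) species.
    Raises :class:`HomologyError` naming the member if any member's family
    is absent from the homology map.
    """
    focal = cluster.species_id
    evidence: list[str] = []

    member_loci: list[MicroRNALocus] = []
    for m in cluster.members:
        if m not in loci:
            raise HomologyError(f"member {m!r} has no locus record")
        member_loci.append(loci[m])
    member_loci.sort(key=lambda l: (l.start, l.end))

    ages: dict[str, str] = {}
    for locus in member_loci:
        if not hom.has_family(locus.phylo_family):
            raise HomologyError(
                f"member {locus.mirna_id!r}: family {locus.phylo_family!r} "
                "missing from the homology map"
            )
        ages[locus.mirna_id] = _family_origin(locus.phylo_family, hom, tree)
        evidence.append(
            f"{locus.mirna_id} ({locus.phylo_family}) origin="
            f"{tree.lineage_name(ages[locus.mirna_id])}"
        )

    # all origin nodes lie on the root->focal path, so depth totally orders ages
    oldest_depth = min(tree.depth(ages[l.mirna_id]) for l in member_loci)
    oldest = [l for l in member_loci if tree.depth(ages[l.mirna_id]) == oldest_depth]

    if len(oldest) >= 2:
        fams = [l.phylo_family for l in oldest]
        dup_fams = sorted({f for f in fams if fams.count(f) >= 2})
        node = ages[oldest[0].mirna_id]
        if dup_fams:
            evidence.append(
                f"oldest members share family {dup_fams[0]} -> tandem duplication"
            )
            call = OriginCall(
                cluster.cluster_id,
                Source.DUPLICATION,
                tree.lineage_name(node),
                evidence="; ".join(evidence),
            )
            _maybe_warn_masked_duplication(call, dup_fams[0], hom)
            return call
        founder_a, founder_b = oldest[0], oldest[1]
        if _is_fusion(founder_a, founder_b, node, focal, hom, tree, max_gap):
            evidence.append("founder families unlinked in all equally old species")
            return OriginCall(
                cluster.cluster_id,
                Source.FUSION,
                tree.lineage_name(node),
                evidence="; ".join(evidence),
            )
        evidence.append(
            "two oldest members have different families but equal ages -> "
            "cannot distinguish duplication from new hairpin"
        )
        return OriginCall(
            cluster.cluster_id,
            Source.UNKNOWN,
            tree.lineage_name(node),
            evidence="; ".join(evidence),
        )

    founder_a = oldest[0]
    second_depth = min(
        tree.depth(ages[l.mirna_id])
        for l in member_loci
        if l.mirna_id != founder_a.mirna_id
    )
    founder_b = next(
        l
        for l in member_loci
        if l.mirna_id != founder_a.mirna_id
        and tree.depth(ages[l.mirna_id]) == second_depth
    )
    origin_node = ages[founder_b.mirna_id]
    if _is_fusion(founder_a, founder_b, origin_node, focal, hom, tree, max_gap):
        evidence.append("founder families unlinked in all equally old species")
        return OriginCall(
            cluster.cluster_id,
            Source.FUSION,
            tree.lineage_name(origin_node),
            evidence="; ".join(evidence),
        )
    evidence.append(
        f"{founder_b.mirna_id} emerged within the transcript of the older "
        f"{founder_a.mirna_id}"
    )
    return OriginCall(
        cluster.cluster_id,
        Source.NEW_HAIRPIN,
        tree.lineage_name(origin_node),
        original_mirna=founder_a.mirna_id,
        evidence="; ".join(evidence),
    )


def _is_fusion(
    founder_a: MicroRNALocus,
    founder_b: MicroRNALocus,
    origin_node: str,
    focal: str,
    hom: HomologyMap,
    tree: SpeciesPhylogeny,
    max_gap: int,
) -> bool:
    """Founder families derive from disparate loci in old genomes?

    Only species that diverged from the focal lineage at or before the
    putative cluster origin are informative: a lineage inside the cluster's
    clade that lost linkage reflects a later translocation, not a fusion.
    FUSION requires at least one informative species and no informative
    species showing the two families linked.
    """
    fam_a, fam_b = founder_a.phylo_family, founder_b.phylo_family
    informative = []
    for s in tree.species:
        if s == focal:
            continue
        if not hom.loci(fam_a, s) or not hom.loci(fam_b, s):
            continue
        if tree.is_ancestor_or_equal(tree.mrca([s, focal]), origin_node):
            informative.append(s)
    if not informative:
        return False
    return not any(
        _linked_in_species(fam_a, fam_b, s, hom, max_gap) for s in informative
    )


def _maybe_warn_masked_duplication(
    call: OriginCall, family: str, hom: HomologyMap
) -> None:
    """Flag duplications whose family is single-copy in some species.

    A deeper single-copy distribution is compatible with an ancestral new
    hairpin event masked by later losses; the call stands but the caveat is
    recorded in the evidence trace.
    """
    singles = [s for s in hom.species_with(family) if len(hom.loci(family, s)) == 1]
    if singles:
        call.evidence += (
            f"; caveat: {family} is single-copy in {','.join(singles)} -- an "
            "older new-hairpin origin masked by loss cannot be excluded"
        )


@dataclass
class OriginSummary:
    by_source: Counter
    by_lineage: Counter
    by_branch: dict[str, list[str]]  # lineage -> cluster ids (per-branch listing)

    @property
    def n_calls(self) -> int:
        return sum(self.by_source.values())


def summarize_origins(calls: Iterable[OriginCall]) -> OriginSummary:
    """Tally calls by source and by origin lineage."""
    by_source: Counter = Counter({s: 0 for s in Source})
    by_lineage: Counter = Counter()
    by_branch: dict[str, list[str]] = {}
    for call in calls:
        by_source[call.source] += 1
        by_lineage[call.origin_lineage] += 1
        by_branch.setdefault(call.origin_lineage, []).append(call.cluster_id)
    return OriginSummary(by_source, by_lineage, by_branch)


def classify_cross_species_pair(
    fam_a: str,
    fam_b: str,
    hom: HomologyMap,
    tree: SpeciesPhylogeny,
    ref_species: str,
    max_gap: int = DEFAULT_MAX_GAP,
) -> CrossSpeciesCall:
    """Explain why a pair unclustered in the reference is clustered elsewhere.

    For ``fam_a == fam_b`` the pair means two copies of the family.
    """
    same_family = fam_a == fam_b

    def clustered_in(species: str) -> bool:
        if same_family:
            loci = hom.loci(fam_a, species)
            return any(
                (g := pairwise_gap(la, lb)) is not None and g < max_gap
                for i, la in enumerate(loci)
                for lb in loci[i + 1:]
            )
        return _linked_in_species(fam_a, fam_b, species, hom, max_gap)

    where = [s for s in tree.species if s != ref_species and clustered_in(s)]
    if not where:
        raise HomologyError(
            f"pair ({fam_a}, {fam_b}) is not clustered in any non-reference species"
        )
    if clustered_in(ref_species):
        raise HomologyError(
            f"pair ({fam_a}, {fam_b}) is already clustered in {ref_species}"
        )

    clade = tree.mrca(where)
    if same_family:
        if ref_species not in tree.leaves_under(clade):
            return CrossSpeciesCall(
                (fam_a, fam_b), CrossSpeciesCategory.INDEPENDENT_DUPLICATION, where
            )
    else:
        origin_a = _family_origin(fam_a, hom, tree)
        origin_b = _family_origin(fam_b, hom, tree)
        younger = max((origin_a, origin_b), key=tree.depth)
        if (
            tree.is_ancestor_or_equal(clade, younger)
            and ref_species not in tree.leaves_under(younger)
        ):
            return CrossSpeciesCall(
                (fam_a, fam_b), CrossSpeciesCategory.INDEPENDENT_NEW_HAIRPIN, where
            )
    # linked in the reference genome, only beyond the distance threshold?
    loci_a = hom.loci(fam_a, ref_species)
    loci_b = hom.loci(fam_b, ref_species)
    for i, la in enumerate(loci_a):
        lb_iter = loci_b if not same_family else loci_a[i + 1:]
        for lb in lb_iter:
            if la.mirna_id == lb.mirna_id:
                continue
            if la.chrom == lb.chrom and la.strand == lb.strand:
                return CrossSpeciesCall(
                    (fam_a, fam_b),
                    CrossSpeciesCategory.LINKED_BEYOND_THRESHOLD,
                    where,
                )
    return CrossSpeciesCall(
        (fam_a, fam_b), CrossSpeciesCategory.CLUSTER_SPLIT, where
    )
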