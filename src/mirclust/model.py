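"""Core domain types: loci, species phylogeny, homology map, expression matrix.

Coordinates are 1-based inclusive throughout (GFF3 convention); conversion to
0-based half-open happens only at BED export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import pandas as pd

from .errors import HomologyError, TreeError

VALID_STRANDS = ("+", "-")


@dataclass
class MicroRNALocus:
    """One microRNA precursor's genomic placement and family labels.

    ``annotation_family`` groups loci the way a curated database would
    (used for composition statistics); ``phylo_family`` groups loci by
    phylogenetic homology (used by the origin classifier) and may merge
    annotation families.  Both default to ``mirna_id`` when not supplied.
    """

    mirna_id: str
    species_id: str
    chrom: str
    start: int
    end: int
    strand: str
    annotation_family: str = ""
    phylo_family: str = ""
    host_transcript: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.mirna_id}: start ({self.start}) > end ({self.end})"
            )
        if self.start < 1:
            raise ValueError(f"{self.mirna_id}: coordinates are 1-based, got start={self.start}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"{self.mirna_id}: strand must be one of {VALID_STRANDS}")
        if not self.annotation_family:
            self.annotation_family = self.mirna_id
        if not self.phylo_family:
            self.phylo_family = self.mirna_id

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class SpeciesPhylogeny:
    """Rooted species tree whose internal nodes are named lineages.

    Leaves carry species identifiers; every internal node carries a unique
    lineage name.  A leaf may additionally be aliased to a lineage name via
    ``leaf_lineages`` (e.g. the focal species' terminal branch), so that
    single-species origins report a lineage rather than a species code.
    """

    def __init__(
        self,
        parent: Mapping[str, str | None],
        children: Mapping[str, Sequence[str]],
        edge_length: Mapping[str, float],
        root: str,
        leaf_lineages: Mapping[str, str] | None = None,
    ):
        self._parent = dict(parent)
        self._children = {k: list(v) for k, v in children.items()}
        self._edge_length = dict(edge_length)
        self.root = root
        self.leaf_lineages = dict(leaf_lineages or {})
        self._depth: dict[str, int] = {}
        self._compute_depths()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        newick: str,
        auto_name: bool = False,
        allow_multifurcating_root: bool = False,
        leaf_lineages: Mapping[str, str] | None = None,
    ) -> "SpeciesPhylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise TreeError(f"duplicate leaf labels: {exc}") from exc
        except Exception as exc:
            raise TreeError(f"invalid newick: {exc}") from exc
        root = tree.seed_node
        if len(root.child_nodes()) > 2 and not allow_multifurcating_root:
            raise TreeError(
                "root is multifurcating (unrooted tree?); "
                "pass allow_multifurcating_root=True to accept"
            )
        parent: dict[str, str | None] = {}
        children: dict[str, list[str]] = {}
        edge_length: dict[str, float] = {}
        names: dict[int, str] = {}
        counter = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                name = node.taxon.label if node.taxon else node.label
                if not name:
                    raise TreeError("leaf without a label")
            else:
                name = node.label
                if not name:
                    if not auto_name:
                        raise TreeError(
                            "unnamed internal node (use auto_name=True to accept)"
                        )
                    counter += 1
                    name = f"node{counter}"
            if name in parent:
                raise TreeError(f"duplicate node name: {name!r}")
            names[id(node)] = name
            pnode = node.parent_node
            parent[name] = names[id(pnode)] if pnode is not None else None
            children[name] = []
            if pnode is not None:
                children[names[id(pnode)]].append(name)
            edge_length[name] = node.edge.length if node.edge.length is not None else 0.0
        root_name = names[id(tree.seed_node)]
        return cls(parent, children, edge_length, root_name, leaf_lineages)

    @classmethod
    def from_newick_file(cls, path, **kwargs) -> "SpeciesPhylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read(), **kwargs)

    # -- basic queries -----------------------------------------------------

    def _compute_depths(self) -> None:
        self._depth[self.root] = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child in self._children[node]:
                self._depth[child] = self._depth[node] + 1
                stack.append(child)

    @property
    def nodes(self) -> list[str]:
        return list(self._parent)

    @property
    def species(self) -> list[str]:
        """Leaf labels in a stable (preorder) order."""
        return [n for n in self._parent if not self._children[n]]

    def is_leaf(self, name: str) -> bool:
        return not self._children[name]

    def has_node(self, name: str) -> bool:
        return name in self._parent

    def parent_of(self, name: str) -> str | None:
        return self._parent[name]

    def children_of(self, name: str) -> list[str]:
        return list(self._children[name])

    def depth(self, name: str) -> int:
        """Number of edges between the root and ``name``."""
        return self._depth[name]

    def branch_length(self, name: str) -> float:
        return self._edge_length[name]

    def path_to_root(self, name: str) -> list[str]:
        """Nodes from ``name`` (inclusive) up to the root (inclusive)."""
        if name not in self._parent:
            raise TreeError(f"unknown node: {name!r}")
        path = [name]
        while self._parent[path[-1]] is not None:
            path.append(self._parent[path[-1]])
        return path

    def mrca(self, names: Iterable[str]) -> str:
        """Most recent common ancestor of a non-empty set of nodes."""
        names = list(names)
        if not names:
            raise TreeError("mrca of an empty set is undefined")
        common: set[str] | None = None
        for n in names:
            anc = set(self.path_to_root(n))
            common = anc if common is None else common & anc
        assert common
        return max(common, key=lambda n: self._depth[n])

    def is_ancestor_or_equal(self, ancestor: str, node: str) -> bool:
        return ancestor in self.path_to_root(node)

    def leaves_under(self, name: str) -> list[str]:
        """Leaf labels in the subtree rooted at ``name``."""
        out: list[str] = []
        stack = [name]
        while stack:
            node = stack.pop()
            kids = self._children[node]
            if not kids:
                out.append(node)
            else:
                stack.extend(reversed(kids))
        return out

    def lineage_name(self, node: str) -> str:
        """Lineage label for a node: its name, or the leaf alias if any."""
        if self.is_leaf(node):
            return self.leaf_lineages.get(node, node)
        return node

    def branches(self) -> Iterator[tuple[str, str, float]]:
        """Preorder (parent, child, length) over all edges."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child in reversed(self._children[node]):
                stack.append(child)
            if self._parent[node] is not None:
                yield self._parent[node], node, self._edge_length[node]

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesPhylogeny(root={self.root!r}, n_species={len(self.species)})"


class HomologyMap:
    """phylo_family -> species -> loci of that family in that species.

    Every species known to the map resolves for every family: a family
    absent from a species yields an empty list, never a missing entry.
    """

    def __init__(self, species: Iterable[str]):
        self._species = list(species)
        self._fam: dict[str, dict[str, list[MicroRNALocus]]] = {}

    @classmethod
    def from_loci(
        cls, loci: Iterable[MicroRNALocus], species: Iterable[str]
    ) -> "HomologyMap":
        hom = cls(species)
        for locus in loci:
            hom.add(locus)
        return hom

    @property
    def species(self) -> list[str]:
        return list(self._species)

    @property
    def families(self) -> list[str]:
        return list(self._fam)

    def add(self, locus: MicroRNALocus) -> None:
        if locus.species_id not in self._species:
            raise HomologyError(
                f"species {locus.species_id!r} not declared in the homology map"
            )
        fam = self._fam.setdefault(
            locus.phylo_family, {s: [] for s in self._species}
        )
        fam[locus.species_id].append(locus)

    def has_family(self, family: str) -> bool:
        return family in self._fam

    def loci(self, family: str, species: str) -> list[MicroRNALocus]:
        if species not in self._species:
            raise HomologyError(f"unknown species {species!r}")
        if family not in self._fam:
            raise HomologyError(f"unknown family {family!r}")
        return list(self._fam[family][species])

    def species_with(self, family: str) -> list[str]:
        """Species in which the family has at least one locus."""
        if family not in self._fam:
            raise HomologyError(f"unknown family {family!r}")
        return [s for s in self._species if self._fam[family][s]]

    def all_loci(self) -> Iterator[MicroRNALocus]:
        for fam in self._fam.values():
            for loci in fam.values():
                yield from loci


class ExpressionMatrix:
    """Read counts, rows = mirna_id, columns = sample_id."""

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            raise ValueError("duplicate mirna_id rows")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample columns")
        if (df.values < 0).any():
            raise ValueError("negative read counts")
        self.df = df

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="mirna_id")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def counts(self, mirna_id: str):
        return self.df.loc[mirna_id].to_numpy()

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self.df.index
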