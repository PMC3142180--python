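"""Taxonomy-guided reference-genome selection.

Reference genomes for homology-based annotation transfer are chosen on a
rooted taxonomy tree whose leaves are organism names.  The *taxonomic
distance* from a query organism to a reference is the number of nodes on
the path from the query leaf up to their lowest common ancestor, excluding
the query leaf itself and including the ancestor (so siblings are at
distance 1 and distance(query, query) = 0).  Only the *ordering* of
distances matters to the selection strategies, and that ordering is
invariant to whether the ancestor is counted.

Three strategies are provided:

* ``single``   — one reference at an exact distance;
* ``nearest``  — up to K references, walking distance classes outward from
  the query;
* ``farthest`` — the mirror image, walking inward from the most distant
  class.

Within a distance class, the representative is the candidate whose genome
size is most similar to the query's (remaining ties broken by organism
name), which favours comparably-sized, comparably-annotated genomes.  Each
class contributes one representative before any class contributes a second,
preserving taxonomic diversity when K exceeds the number of classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy

from .annotation import AnnotationDatabase, AnnotationFormatError

__all__ = [
    "TaxonomyTree",
    "ReferenceSelection",
    "taxonomic_distance",
    "select_single",
    "select_multi_nearest",
    "select_multi_farthest",
]


class TaxonomyTree:
    """A rooted taxonomy as a child -> parent map; leaves are organisms."""

    def __init__(self, parent: Mapping[str, str]) -> None:
        self.parent: dict[str, str] = dict(parent)
        roots = [n for n, p in self.parent.items() if n == p]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {sorted(roots)}")
        self.root = roots[0]
        parents = {p for n, p in self.parent.items() if n != p}
        self.nodes: set[str] = set(self.parent)
        self.leaves: set[str] = self.nodes - parents
        for node in self.nodes:  # every chain must reach the root
            self.ancestors(node)

    def ancestors(self, node: str) -> list[str]:
        """Ancestors from the node's parent up to and including the root."""
        if node not in self.parent:
            raise KeyError(f"node {node!r} is not in the tree")
        chain: list[str] = []
        seen = {node}
        while node != self.parent[node]:
            node = self.parent[node]
            if node in seen:
                raise ValueError(f"cycle detected at node {node!r}")
            seen.add(node)
            chain.append(node)
        return chain

    @classmethod
    def from_newick(cls, source: str | Path) -> "TaxonomyTree":
        """Build from a Newick string or file (leaf labels = organisms)."""
        text = source
        if isinstance(source, Path) or (isinstance(source, str) and Path(source).is_file()):
            text = Path(source).read_text(encoding="utf-8")
        tree = dendropy.Tree.get(
            data=str(text),
            schema="newick",
            suppress_internal_node_taxa=False,
        )
        parent: dict[str, str] = {}
        counter = [0]

        def label_of(node: dendropy.Node) -> str:
            if node.taxon is not None and node.taxon.label:
                return node.taxon.label
            if node.label:
                return node.label
            if not hasattr(node, "_seedpath_label"):
                counter[0] += 1
                node._seedpath_label = f"_internal{counter[0]}"
            return node._seedpath_label

        for node in tree.preorder_node_iter():
            name = label_of(node)
            if node.parent_node is None:
                parent[name] = name
            else:
                parent[name] = label_of(node.parent_node)
        return cls(parent)

    @classmethod
    def from_parent_child_tsv(cls, path: str | Path) -> "TaxonomyTree":
        """Build from a two-column ``child <TAB> parent`` table.

        The root may be given as a self-parented row or left implicit (a
        parent that never appears as a child).
        """
        parent: dict[str, str] = {}
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise AnnotationFormatError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, found {len(fields)}"
                    )
                child, par = fields
                parent[child] = par
        for par in set(parent.values()) - set(parent):
            parent[par] = par  # implicit root
        return cls(parent)


@dataclass(frozen=True)
class ReferenceSelection:
    """An ordered pick of reference genomes under one strategy."""

    ordered_genomes: tuple[str, ...]
    strategy: str  # one of {single, multi-nearest, multi-farthest}
    K: int

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be positive, got {self.K}")
        if len(self.ordered_genomes) > self.K:
            raise ValueError("selection longer than K")
        if len(set(self.ordered_genomes)) != len(self.ordered_genomes):
            raise ValueError("selection contains duplicates")


def taxonomic_distance(tree: TaxonomyTree, query: str, ref: str) -> int:
    """Nodes on the path from the query leaf to its lowest common ancestor
    with the reference, excluding the query leaf and including the LCA."""
    for org in (query, ref):
        if org not in tree.leaves:
            raise KeyError(f"organism {org!r} is not a leaf of the taxonomy tree")
    if query == ref:
        return 0
    ref_side = {ref, *tree.ancestors(ref)}
    for i, node in enumerate(tree.ancestors(query)):
        if node in ref_side:
            return i + 1
    raise ValueError(f"no common ancestor of {query!r} and {ref!r}")  # unreachable on a rooted tree


def _candidates(
    tree: TaxonomyTree, db: AnnotationDatabase, query: str
) -> dict[str, int]:
    """Distance of every selectable organism (in db and on the tree)."""
    orgs = sorted((db.organisms & tree.leaves) - {query})
    return {org: taxonomic_distance(tree, query, org) for org in orgs}


def _class_order(
    members: Sequence[str], db: AnnotationDatabase, query_count: int
) -> list[str]:
    """Order within a distance class: genome size closest to the query's,
    then organism name."""
    return sorted(members, key=lambda o: (abs(db.gene_count(o, total=True) - query_count), o))


def _query_count(
    db: AnnotationDatabase, query: str, query_gene_count: int | None
) -> int:
    if query_gene_count is not None:
        return query_gene_count
    if query in db.organisms:
        return db.gene_count(query, total=True)
    raise KeyError(
        f"query organism {query!r} is not in the database; "
        "pass query_gene_count= for the genome-size tie-break"
    )


def select_single(
    tree: TaxonomyTree,
    db: AnnotationDatabase,
    query: str,
    distance: int,
    query_gene_count: int | None = None,
) -> str:
    """The representative reference genome at exactly the given distance."""
    cand = _candidates(tree, db, query)
    members = [o for o, d in cand.items() if d == distance]
    if not members:
        available = sorted(set(cand.values()))
        raise ValueError(
            f"no candidate at distance {distance} from {query!r}; "
            f"occupied distances: {available}"
        )
    return _class_order(members, db, _query_count(db, query, query_gene_count))[0]


def _select_multi(
    tree: TaxonomyTree,
    db: AnnotationDatabase,
    query: str,
    K: int,
    descending: bool,
    query_gene_count: int | None,
) -> ReferenceSelection:
    if K < 1:
        raise ValueError(f"K must be positive, got {K}")
    qcount = _query_count(db, query, query_gene_count)
    cand = _candidates(tree, db, query)
    by_distance: dict[int, list[str]] = {}
    for org, d in cand.items():
        by_distance.setdefault(d, []).append(org)
    classes = sorted(by_distance, reverse=descending)
    ordered_classes = [
        _class_order(by_distance[d], db, qcount) for d in classes
    ]
    picked: list[str] = []
    depth = 0
    while len(picked) < K:
        progressed = False
        for members in ordered_classes:
            if depth < len(members):
                picked.append(members[depth])
                progressed = True
                if len(picked) == K:
                    break
        if not progressed:
            break  # candidates exhausted
        depth += 1
    strategy = "multi-farthest" if descending else "multi-nearest"
    return ReferenceSelection(ordered_genomes=tuple(picked), strategy=strategy, K=K)


def select_multi_nearest(
    tree: TaxonomyTree,
    db: AnnotationDatabase,
    query: str,
    K: int = 10,
    query_gene_count: int | None = None,
) -> ReferenceSelection:
    """Up to K references walking distance classes outward from the query."""
    return _select_multi(tree, db, query, K, descending=False, query_gene_count=query_gene_count)


def select_multi_farthest(
    tree: TaxonomyTree,
    db: AnnotationDatabase,
    query: str,
    K: int = 10,
    query_gene_count: int | None = None,
) -> ReferenceSelection:
    """Up to K references walking distance classes inward from the farthest."""
    return _select_multi(tree, db, query, K, descending=True, query_gene_count=query_gene_count)
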