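"""Subsystem-annotation database: loading, indexing, ID mapping, backgrounds.

The database plays the role of a curated bacterial pathway resource in the
SEED style: each record states that a gene of a particular organism is a
member of a named *subsystem* (SEED's term for a curated pathway / functional
module).  The database is both the search space for annotation transfer and
the background universe for enrichment statistics.

The on-disk dialect is a plain TSV, one membership per row::

    organism <TAB> gene_id <TAB> id_namespace <TAB> subsystem

with ``#``-prefixed comment lines ignored.  Two optional sidecars exist: a
two-column alias table mapping GI numbers to database-native gene ids, and a
two-column per-organism total gene count (annotated + unannotated genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

NAMESPACES = ("db-native", "gi", "query-local")

__all__ = [
    "NAMESPACES",
    "GeneId",
    "SubsystemAssignment",
    "AnnotationDatabase",
    "AnnotationSet",
    "AnnotationFormatError",
    "load_database",
    "write_database",
    "map_by_id",
    "IdMapping",
    "background_for",
]


class AnnotationFormatError(ValueError):
    """A database / sidecar file violates the TSV dialect."""


@dataclass(frozen=True, order=True)
class GeneId:
    """A namespaced gene identifier.

    ``db-native`` ids are the database's own accessions, ``gi`` ids are
    NCBI GI numbers usable as a universal cross-reference, and
    ``query-local`` ids name genes of the user's query set (e.g. FASTA
    headers) that have no standing in the database.
    """

    value: str
    namespace: str = "db-native"

    def __post_init__(self) -> None:
        if not self.value or any(c.isspace() for c in self.value):
            raise ValueError(f"gene id must be non-empty without whitespace: {self.value!r}")
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown gene-id namespace {self.namespace!r}; expected one of {NAMESPACES}")


@dataclass(frozen=True, order=True)
class SubsystemAssignment:
    """Membership of one gene of one organism in one subsystem."""

    organism: str
    gene: GeneId
    subsystem: str

    def __post_init__(self) -> None:
        if not self.organism:
            raise ValueError("organism name must be non-empty")
        if not self.subsystem:
            raise ValueError("subsystem name must be non-empty")


@dataclass
class AnnotationSet:
    """A gene -> subsystem-set mapping over a stated universe.

    ``universe_size`` is the number of genes the set is considered to be
    drawn from.  By default that is the number of *annotated* genes (genes
    with at least one subsystem), which is the convention that keeps the
    enrichment background meaningful: unannotated genes can never contribute
    to subsystem counts.
    """

    mapping: dict[str, frozenset[str]]
    universe_size: int

    def __post_init__(self) -> None:
        for gene, subs in self.mapping.items():
            if not subs:
                raise ValueError(f"gene {gene!r} mapped with empty subsystem set")
        if self.universe_size < len(self.mapping):
            raise ValueError(
                f"universe_size {self.universe_size} < number of mapped genes {len(self.mapping)}"
            )

    @property
    def genes(self) -> set[str]:
        return set(self.mapping)

    @property
    def subsystems(self) -> set[str]:
        out: set[str] = set()
        for subs in self.mapping.values():
            out |= subs
        return out


class AnnotationDatabase:
    """Indexed collection of subsystem assignments across organisms.

    Duplicate (organism, gene, subsystem) rows are collapsed; assignments are
    kept in sorted order so equal inputs produce byte-identical write-backs.
    """

    def __init__(
        self,
        assignments: Iterable[SubsystemAssignment],
        organism_gene_counts: Mapping[str, int] | None = None,
        aliases: Mapping[str, str] | None = None,
    ) -> None:
        self._assignments: tuple[SubsystemAssignment, ...] = tuple(sorted(set(assignments)))
        self.organisms: set[str] = {a.organism for a in self._assignments}
        self._index: dict[GeneId, list[SubsystemAssignment]] = {}
        for a in self._assignments:
            self._index.setdefault(a.gene, []).append(a)
        # gi value -> db-native value
        self._aliases: dict[str, str] = dict(aliases or {})
        annotated = {o: 0 for o in self.organisms}
        for org, genes in self._genes_by_organism().items():
            annotated[org] = len(genes)
        self._annotated_counts = annotated
        self._total_counts: dict[str, int] = dict(organism_gene_counts or {})
        for org, total in self._total_counts.items():
            if total < annotated.get(org, 0):
                raise ValueError(
                    f"total gene count {total} for {org!r} is below its "
                    f"{annotated.get(org, 0)} annotated genes"
                )

    def _genes_by_organism(self) -> dict[str, set[GeneId]]:
        out: dict[str, set[GeneId]] = {}
        for a in self._assignments:
            out.setdefault(a.organism, set()).add(a.gene)
        return out

    @property
    def assignments(self) -> tuple[SubsystemAssignment, ...]:
        return self._assignments

    @property
    def genes(self) -> set[GeneId]:
        return set(self._index)

    def __len__(self) -> int:
        return len(self._assignments)

    def resolve(self, gene: GeneId) -> GeneId | None:
        """Resolve a query id to an indexed gene id, following gi aliases."""
        if gene in self._index:
            return gene
        if gene.namespace == "gi" and gene.value in self._aliases:
            native = GeneId(self._aliases[gene.value], "db-native")
            if native in self._index:
                return native
        return None

    def subsystems_of(self, gene: GeneId) -> frozenset[str]:
        resolved = self.resolve(gene)
        if resolved is None:
            return frozenset()
        return frozenset(a.subsystem for a in self._index[resolved])

    def organism_of(self, gene: GeneId) -> str | None:
        resolved = self.resolve(gene)
        if resolved is None:
            return None
        return self._index[resolved][0].organism

    def annotated_genes(self, organism: str) -> set[GeneId]:
        if organism not in self.organisms:
            raise KeyError(
                f"unknown organism {organism!r}; available: {sorted(self.organisms)}"
            )
        return {a.gene for a in self._assignments if a.organism == organism}

    def gene_count(self, organism: str, total: bool = False) -> int:
        """Number of genes of an organism: annotated by default, or the
        sidecar-declared total when ``total=True`` (falls back to annotated)."""
        if organism not in self.organisms:
            raise KeyError(
                f"unknown organism {organism!r}; available: {sorted(self.organisms)}"
            )
        if total and organism in self._total_counts:
            return self._total_counts[organism]
        return self._annotated_counts[organism]

    def restrict(self, organisms: Sequence[str]) -> "AnnotationDatabase":
        """Sub-database containing only the given organisms' assignments."""
        keep = set(organisms)
        missing = keep - self.organisms
        if missing:
            raise KeyError(
                f"unknown organism(s) {sorted(missing)}; available: {sorted(self.organisms)}"
            )
        return AnnotationDatabase(
            (a for a in self._assignments if a.organism in keep),
            organism_gene_counts={o: c for o, c in self._total_counts.items() if o in keep},
            aliases=self._aliases,
        )

    def merged_with(self, other: "AnnotationDatabase") -> "AnnotationDatabase":
        counts = dict(self._total_counts)
        counts.update(other._total_counts)
        aliases = dict(self._aliases)
        aliases.update(other._aliases)
        return AnnotationDatabase(
            self._assignments + other._assignments,
            organism_gene_counts=counts,
            aliases=aliases,
        )


def _read_rows(path: Path, n_columns: int) -> Iterable[tuple[int, list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != n_columns:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: expected {n_columns} tab-separated columns, "
                    f"found {len(fields)}"
                )
            yield lineno, fields


def load_database(
    paths: Sequence[str | Path],
    format: str = "tsv-dump",
    alias_path: str | Path | None = None,
    gene_counts_path: str | Path | None = None,
) -> AnnotationDatabase:
    """Load and index an annotation database from one or more TSV dumps.

    Duplicate rows (within or across files) collapse to a single assignment.
    """
    if format != "tsv-dump":
        raise ValueError(f"unknown database format {format!r}; supported: 'tsv-dump'")
    assignments: list[SubsystemAssignment] = []
    for p in paths:
        p = Path(p)
        for lineno, (organism, gene, namespace, subsystem) in _read_rows(p, 4):
            try:
                gid = GeneId(gene, namespace)
            except ValueError as exc:
                raise AnnotationFormatError(f"{p}:{lineno}: {exc}") from exc
            assignments.append(SubsystemAssignment(organism, gid, subsystem))
    aliases: dict[str, str] = {}
    if alias_path is not None:
        for _, (gi_value, native_value) in _read_rows(Path(alias_path), 2):
            aliases[gi_value] = native_value
    counts: dict[str, int] = {}
    if gene_counts_path is not None:
        p = Path(gene_counts_path)
        for lineno, (organism, count) in _read_rows(p, 2):
            try:
                counts[organism] = int(count)
            except ValueError as exc:
                raise AnnotationFormatError(
                    f"{p}:{lineno}: gene count must be an integer, got {count!r}"
                ) from exc
    return AnnotationDatabase(assignments, organism_gene_counts=counts, aliases=aliases)


def write_database(db: AnnotationDatabase, path: str | Path) -> None:
    """Write the de-duplicated, sorted row set back to the TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for a in db.assignments:
            fh.write(f"{a.organism}\t{a.gene.value}\t{a.gene.namespace}\t{a.subsystem}\n")


@dataclass
class IdMapping:
    """Outcome of ID-based mapping: per-query results plus unmapped queries."""

    results: list  # list[MappingResult]; typed loosely to avoid a cycle
    unmapped: list[GeneId] = field(default_factory=list)


def map_by_id(queries: Sequence[GeneId], db: AnnotationDatabase) -> IdMapping:
    """Map query ids directly against the database index (gi aliases honoured).

    Absence is data, not an error: queries not found are collected in
    ``unmapped`` rather than dropped.
    """
    from .homology import MappingResult  # local import to avoid module cycle

    if not queries:
        raise ValueError("queries must be non-empty")
    results: list[MappingResult] = []
    unmapped: list[GeneId] = []
    for q in queries:
        resolved = db.resolve(q)
        if resolved is None:
            unmapped.append(q)
            continue
        results.append(
            MappingResult(
                query=q,
                mapped_gene=resolved,
                subsystems=db.subsystems_of(resolved),
                provenance="id",
                organism=db.organism_of(resolved),
            )
        )
    return IdMapping(results=results, unmapped=unmapped)


def background_for(
    db: AnnotationDatabase, organism: str, use_total_genes: bool = False
) -> AnnotationSet:
    """Background annotation set of one organism: all its annotated genes.

    The universe size is the organism's annotated gene count; pass
    ``use_total_genes=True`` to use the sidecar-declared total genome size
    instead.
    """
    if organism not in db.organisms:
        raise KeyError(
            f"unknown organism {organism!r}; available: {sorted(db.organisms)}"
        )
    mapping = {
        g.value: db.subsystems_of(g) for g in db.annotated_genes(organism)
    }
    return AnnotationSet(
        mapping=mapping,
        universe_size=db.gene_count(organism, total=use_total_genes),
    )
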