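"""Reading and writing .ann files — the interface between the two stages.

An .ann file records per-gene subsystem annotations, one row per
(query, subsystem)::

    query_id <TAB> mapped_gene_id <TAB> organism <TAB> subsystem

with ``#`` header lines carrying provenance metadata.  The annotate stage
writes one; the pathfind stage consumes them as sample and background sets.
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import IO, Sequence

from .annotation import AnnotationFormatError, AnnotationSet, GeneId
from .homology import MappingResult

__all__ = ["write_ann", "read_ann", "annotation_set_to_results", "results_to_annotation_set"]


def write_ann(
    results: Sequence[MappingResult],
    stream: IO[str],
    provenance: str | None = None,
    timestamp: bool = True,
) -> int:
    """Write mapped results as .ann rows; returns the unmapped-query count.

    Rows are emitted in sorted order so equal inputs give identical bytes;
    pass ``timestamp=False`` for fully reproducible output.
    """
    mapped = [r for r in results if r.mapped]
    unmapped = len(results) - len(mapped)
    provs = sorted({r.provenance for r in results}) if provenance is None else [provenance]
    stream.write("# seedpath annotation file\n")
    stream.write(f"# provenance: {','.join(provs) if provs else 'none'}\n")
    stream.write(f"# queries: {len(results)}\tmapped: {len(mapped)}\tunmapped: {unmapped}\n")
    if timestamp:
        stream.write(f"# generated: {datetime.datetime.now().isoformat(timespec='seconds')}\n")
    rows = sorted(
        (r.query.value, r.mapped_gene.value, r.organism or "-", s)
        for r in mapped
        for s in r.subsystems
    )
    for row in rows:
        stream.write("\t".join(row) + "\n")
    return unmapped


def read_ann(path: str | Path) -> tuple[list[MappingResult], dict[str, str]]:
    """Read an .ann file back into mapping results plus header metadata.

    Homology evidence (E-value, rank) is not serialised in the row dialect,
    so re-read results carry provenance but no evidence.
    """
    meta: dict[str, str] = {}
    grouped: dict[str, tuple[str, str, set[str]]] = {}
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, found {len(fields)}"
                )
            query, mapped_gene, organism, subsystem = fields
            if query not in grouped:
                grouped[query] = (mapped_gene, organism, set())
            grouped[query][2].add(subsystem)
    provenance = meta.get("provenance", "precomputed-ortholog")
    if provenance not in ("id", "homology", "precomputed-ortholog"):
        provenance = "precomputed-ortholog"
    results = [
        MappingResult(
            query=GeneId(q, "query-local"),
            mapped_gene=GeneId(mapped, "db-native"),
            subsystems=frozenset(subs),
            provenance=provenance,
            organism=None if organism == "-" else organism,
        )
        for q, (mapped, organism, subs) in sorted(grouped.items())
    ]
    return results, meta


def results_to_annotation_set(
    results: Sequence[MappingResult],
    key: str = "mapped",
    universe_size: int | None = None,
) -> AnnotationSet:
    """Collapse mapping results into an AnnotationSet for enrichment.

    ``key='mapped'`` keys genes by the database gene id they mapped to —
    the natural choice when the background is also database genes, and it
    makes the sample a subset of the background for homology-derived
    samples.  ``key='query'`` keys by the query's own id.
    """
    if key not in ("mapped", "query"):
        raise ValueError(f"key must be 'mapped' or 'query', got {key!r}")
    mapping: dict[str, frozenset[str]] = {}
    for r in results:
        if not r.mapped:
            continue
        g = r.mapped_gene.value if key == "mapped" else r.query.value
        mapping[g] = mapping.get(g, frozenset()) | r.subsystems
    return AnnotationSet(
        mapping=mapping,
        universe_size=len(mapping) if universe_size is None else universe_size,
    )


def annotation_set_to_results(
    aset: AnnotationSet, organism: str | None = None
) -> list[MappingResult]:
    """View an annotation set (e.g. an organism background) as id-mapped
    results, so it can be written to the .ann dialect."""
    return [
        MappingResult(
            query=GeneId(g, "query-local"),
            mapped_gene=GeneId(g, "db-native"),
            subsystems=subs,
            provenance="id",
            organism=organism,
        )
        for g, subs in sorted(aset.mapping.items())
    ]
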