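"""Homology-based annotation transfer from filtered BLAST tabular output.

A query gene inherits the subsystem memberships of its best homolog in one
or more reference genomes, where "best" is constrained by three predicates:
the hit's E-value must pass the cutoff (default 1e-5), its per-query rank
must be within the top hits (default 5), and the subject must carry at
least one subsystem annotation.  Among hits passing all three, the
minimum-rank one wins — a rank-1 hit without annotation does not disqualify
the query, it simply yields to the best annotated hit.

Ranks are assigned per query over distinct query-subject gene pairs (tabular
BLAST emits one row per HSP; only the lowest-E-value row per pair is kept),
ordered by (E-value ascending, bit score descending, subject id) so that the
ordering — and therefore every downstream transfer — is a pure function of
the input's content, not of its row order.
"""

from __future__ import annotations

import shutil
import subprocess
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

from .annotation import AnnotationDatabase, GeneId

__all__ = [
    "BlastHit",
    "MappingResult",
    "BlastFormatError",
    "parse_blast_tabular",
    "filter_and_transfer",
    "merge_reference_spaces",
    "load_precomputed_orthologs",
    "run_blast",
]

BLAST_COLUMNS = 12  # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore


class BlastFormatError(ValueError):
    """A tabular homology file violates the 12-column format."""


@dataclass(frozen=True)
class BlastHit:
    """One query-subject homology hit with its per-query rank (1 = best)."""

    query: GeneId
    subject: GeneId
    evalue: float
    bitscore: float
    rank: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"E-value must be non-negative, got {self.evalue}")
        if self.rank < 1:
            raise ValueError(f"rank must be positive, got {self.rank}")


@dataclass(frozen=True)
class MappingResult:
    """A query gene's transferred subsystem set with provenance.

    ``mapped_gene`` is absent when no database gene could be assigned, in
    which case the subsystem set is empty.  ``evidence`` carries the winning
    hit's (E-value, rank) for homology transfers.
    """

    query: GeneId
    mapped_gene: GeneId | None
    subsystems: frozenset[str]
    provenance: str  # one of {id, homology, precomputed-ortholog}
    organism: str | None = None
    evidence: tuple[float, int] | None = None

    def __post_init__(self) -> None:
        if self.provenance not in ("id", "homology", "precomputed-ortholog"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if (self.mapped_gene is not None) != bool(self.subsystems):
            raise ValueError("subsystems must be non-empty iff a gene was mapped")
        if self.evidence is not None and self.provenance != "homology":
            raise ValueError("evidence is carried only by homology transfers")

    @property
    def mapped(self) -> bool:
        return self.mapped_gene is not None


def _iter_lines(source: str | Path | IO[str] | Iterable[str]) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def parse_blast_tabular(source: str | Path | IO[str] | Iterable[str]) -> list[BlastHit]:
    """Parse standard 12-column tabular BLAST output into ranked hits.

    Multiple HSP rows for the same query-subject pair collapse to the
    lowest-E-value one (ties to the higher bit score).  Self-hits are
    retained; excluding them is a policy applied downstream.  The returned
    list is sorted by (query id, rank).
    """
    best: dict[tuple[str, str], tuple[float, float]] = {}
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < BLAST_COLUMNS:
            raise BlastFormatError(
                f"line {lineno}: expected {BLAST_COLUMNS} tab-separated columns, found {len(fields)}"
            )
        qseqid, sseqid = fields[0], fields[1]
        try:
            evalue = float(fields[10])
            bitscore = float(fields[11])
        except ValueError as exc:
            raise BlastFormatError(
                f"line {lineno}: non-numeric evalue/bitscore: {fields[10]!r}, {fields[11]!r}"
            ) from exc
        if evalue < 0:
            raise BlastFormatError(f"line {lineno}: negative E-value {evalue}")
        key = (qseqid, sseqid)
        cand = (evalue, -bitscore)
        if key not in best or cand < best[key]:
            best[key] = cand
    by_query: dict[str, list[tuple[float, float, str]]] = {}
    for (q, s), (evalue, neg_bits) in best.items():
        by_query.setdefault(q, []).append((evalue, neg_bits, s))
    hits: list[BlastHit] = []
    for q in sorted(by_query):
        rows = sorted(by_query[q])  # (evalue asc, bitscore desc, subject lex)
        for rank, (evalue, neg_bits, s) in enumerate(rows, start=1):
            hits.append(
                BlastHit(
                    query=GeneId(q, "query-local"),
                    subject=GeneId(s, "db-native"),
                    evalue=evalue,
                    bitscore=-neg_bits,
                    rank=rank,
                )
            )
    return hits


def filter_and_transfer(
    hits: Sequence[BlastHit],
    db: AnnotationDatabase,
    e_cutoff: float = 1e-5,
    max_rank: int = 5,
    exclude_self: bool = False,
) -> list[MappingResult]:
    """Transfer subsystems from each query's best hit passing all filters.

    A hit survives when its E-value is at most ``e_cutoff``, its rank is at
    most ``max_rank``, and the subject has at least one subsystem in ``db``.
    The minimum-rank survivor wins and all of its subsystems transfer.
    Queries with no survivor yield an unmapped result (never dropped).

    ``exclude_self`` drops hits whose subject id equals the query id; use it
    in re-annotation experiments where the query organism is also in the
    reference set.
    """
    by_query: dict[str, list[BlastHit]] = {}
    for h in hits:
        by_query.setdefault(h.query.value, []).append(h)
    results: list[MappingResult] = []
    for q in sorted(by_query):
        winner: BlastHit | None = None
        for h in by_query[q]:
            if exclude_self and h.subject.value == h.query.value:
                continue
            if h.evalue > e_cutoff or h.rank > max_rank:
                continue
            if not db.subsystems_of(h.subject):
                continue
            if winner is None or h.rank < winner.rank:
                winner = h
        query = by_query[q][0].query
        if winner is None:
            results.append(
                MappingResult(
                    query=query,
                    mapped_gene=None,
                    subsystems=frozenset(),
                    provenance="homology",
                )
            )
        else:
            results.append(
                MappingResult(
                    query=query,
                    mapped_gene=winner.subject,
                    subsystems=db.subsystems_of(winner.subject),
                    provenance="homology",
                    organism=db.organism_of(winner.subject),
                    evidence=(winner.evalue, winner.rank),
                )
            )
    return results


def merge_reference_spaces(
    dbs_or_organisms: Sequence[AnnotationDatabase | str],
    db: AnnotationDatabase | None = None,
) -> AnnotationDatabase:
    """Merge reference genomes into a single annotation search space.

    Accepts either whole databases (merged by union) or organism names
    selected out of ``db``.  Subject gene ids stay organism-qualified in the
    underlying assignments, so per-hit provenance remains recoverable.
    """
    items = list(dbs_or_organisms)
    if not items:
        raise ValueError("at least one reference genome is required")
    if all(isinstance(x, AnnotationDatabase) for x in items):
        merged = items[0]
        for other in items[1:]:
            merged = merged.merged_with(other)  # type: ignore[arg-type]
        return merged  # type: ignore[return-value]
    if all(isinstance(x, str) for x in items):
        if db is None:
            raise ValueError("organism names require the source database via db=")
        return db.restrict([str(x) for x in items])
    raise TypeError("pass either databases or organism names, not a mixture")


def load_precomputed_orthologs(
    path: str | Path, db: AnnotationDatabase
) -> list[MappingResult]:
    """Load a two-column query->subject ortholog table (e.g. from a
    bi-directional-best-hit pipeline) and transfer the subjects' subsystems.

    Subjects absent from the database (or without subsystems) produce an
    unmapped result with a warning rather than an error.
    """
    results: list[MappingResult] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise BlastFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, found {len(fields)}"
                )
            q_value, s_value = fields
            query = GeneId(q_value, "query-local")
            subject = GeneId(s_value, "db-native")
            subsystems = db.subsystems_of(subject)
            if not subsystems:
                warnings.warn(
                    f"{path}:{lineno}: subject {s_value!r} has no subsystem "
                    "annotation in the database; query left unmapped",
                    stacklevel=2,
                )
                results.append(
                    MappingResult(
                        query=query,
                        mapped_gene=None,
                        subsystems=frozenset(),
                        provenance="precomputed-ortholog",
                    )
                )
            else:
                results.append(
                    MappingResult(
                        query=query,
                        mapped_gene=subject,
                        subsystems=subsystems,
                        provenance="precomputed-ortholog",
                        organism=db.organism_of(subject),
                    )
                )
    return results


def run_blast(
    fasta: str | Path,
    blast_db: str | Path,
    program: str = "blastp",
    extra_args: Sequence[str] = (),
) -> list[BlastHit]:
    """Optional convenience wrapper that shells out to NCBI BLAST.

    Untested plumbing by design: the core pipeline consumes precomputed
    tabular output, keeping results reproducible and free of an external
    binary dependency.
    """
    if program not in ("blastp", "blastx"):
        raise ValueError(f"unsupported BLAST program {program!r}")
    if shutil.which(program) is None:
        raise RuntimeError(f"{program} is not on PATH; supply tabular output instead")
    cmd = [program, "-query", str(fasta), "-db", str(blast_db), "-outfmt", "6", *extra_args]
    proc = subprocess.run(cmd, check=True, capture_output=True, text=True)
    return parse_blast_tabular(proc.stdout.splitlines())
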