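"""Synthetic input generators with planted, ledgered ground truth.

Every stage of the pipeline can be exercised without downloading any real
database: these generators emit the exact on-disk dialects the pipeline
consumes (annotation TSV, 12-column tabular BLAST, Newick taxonomy, .ann)
together with a :class:`FixtureLedger` recording the planted structure —
true orthologs, the enriched subsystem, expected contingency counts,
pairwise taxonomic distances — so downstream results can be checked against
ground truth instead of against the implementation itself.

All generators are pure functions of their parameters and a seed
(numpy's PCG64 generator), so reruns are byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import AnnotationDatabase, AnnotationSet, GeneId, SubsystemAssignment
from .homology import MappingResult
from .refselect import TaxonomyTree

__all__ = [
    "FixtureLedger",
    "gen_database",
    "gen_background",
    "gen_enriched_sample",
    "gen_blast_table",
    "gen_taxonomy",
    "gen_noisy_predictions",
]


@dataclass
class FixtureLedger:
    """Ground-truth record that determines every downstream expectation."""

    seed: int
    composition: dict = field(default_factory=dict)
    subsystem_sizes: dict = field(default_factory=dict)
    true_orthologs: dict = field(default_factory=dict)
    true_enriched_subsystems: list = field(default_factory=list)
    planted_error_rate: float = 0.0
    expected_table: tuple | None = None
    distances: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        """Human-readable key-value sidecar (values JSON-encoded)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# fixture ledger (seed={self.seed})\n")
            for key in (
                "seed",
                "composition",
                "subsystem_sizes",
                "true_orthologs",
                "true_enriched_subsystems",
                "planted_error_rate",
                "expected_table",
                "distances",
                "extra",
            ):
                value = getattr(self, key)
                if isinstance(value, dict) and value and isinstance(next(iter(value)), tuple):
                    value = {"|".join(k): v for k, v in value.items()}
                fh.write(f"{key}\t{json.dumps(value, sort_keys=True)}\n")


def _organism_names(n: int) -> list[str]:
    return [f"org{i + 1:02d}" for i in range(n)]


def _subsystem_names(n: int) -> list[str]:
    return [f"SS{i + 1:02d}" for i in range(n)]


def gen_database(
    n_organisms: int = 3,
    genes_per_organism: int = 200,
    n_subsystems: int = 20,
    mean_subsystem_size: float = 8.0,
    seed: int = 0,
    ensure_coverage: bool = False,
) -> tuple[AnnotationDatabase, FixtureLedger]:
    """A multi-organism annotation database with ledgered composition.

    Per organism, each subsystem's size is drawn from a Poisson with the
    given mean, truncated below at 1, and its members are sampled without
    replacement from that organism's genes.  ``ensure_coverage`` assigns
    every otherwise-unannotated gene to one random subsystem, making the
    annotated universe equal to the whole gene set.
    """
    if min(n_organisms, genes_per_organism, n_subsystems) < 1 or mean_subsystem_size < 1:
        raise ValueError("all fixture sizes must be at least 1")
    if mean_subsystem_size > genes_per_organism:
        raise ValueError(
            f"mean subsystem size {mean_subsystem_size} exceeds genes per organism "
            f"{genes_per_organism}: infeasible membership counts"
        )
    rng = np.random.default_rng(seed)
    organisms = _organism_names(n_organisms)
    subsystems = _subsystem_names(n_subsystems)
    ledger = FixtureLedger(seed=seed)
    assignments: list[SubsystemAssignment] = []
    counts: dict[str, int] = {}
    for org in organisms:
        genes = [f"{org}.g{j + 1:04d}" for j in range(genes_per_organism)]
        counts[org] = genes_per_organism
        annotated: set[str] = set()
        sizes: dict[str, int] = {}
        for ss in subsystems:
            size = int(rng.poisson(mean_subsystem_size))
            size = min(max(size, 1), genes_per_organism)
            members = rng.choice(genes, size=size, replace=False)
            sizes[ss] = size
            for g in members:
                annotated.add(str(g))
                assignments.append(SubsystemAssignment(org, GeneId(str(g)), ss))
        if ensure_coverage:
            orphans = [g for g in genes if g not in annotated]
            if orphans:
                picks = rng.choice(subsystems, size=len(orphans), replace=True)
                for g, ss in zip(orphans, picks):
                    sizes[str(ss)] += 1
                    annotated.add(g)
                    assignments.append(SubsystemAssignment(org, GeneId(g), str(ss)))
        ledger.subsystem_sizes[org] = sizes
        ledger.composition[org] = {
            "genes": genes_per_organism,
            "annotated": len(annotated),
            "subsystems": n_subsystems,
        }
    db = AnnotationDatabase(assignments, organism_gene_counts=counts)
    return db, ledger


def gen_background(
    n_genes: int = 2000,
    n_subsystems: int = 40,
    target_subsystem: str = "SS01",
    target_size: int = 100,
    seed: int = 0,
    organism: str = "queryorg",
) -> tuple[AnnotationSet, FixtureLedger]:
    """A single-organism background for enrichment studies.

    Exactly ``target_size`` genes belong to the target subsystem and every
    remaining gene is assigned uniformly to one of the other subsystems, so
    the whole universe is annotated and the target's background frequency
    is exactly ``target_size / n_genes``.
    """
    if target_size >= n_genes:
        raise ValueError("target subsystem cannot cover the whole universe")
    if n_subsystems < 2:
        raise ValueError("need at least two subsystems (target + rest)")
    rng = np.random.default_rng(seed)
    genes = [f"{organism}.g{j + 1:05d}" for j in range(n_genes)]
    others = [s for s in _subsystem_names(n_subsystems) if s != target_subsystem]
    if len(others) == n_subsystems:
        raise ValueError(f"target subsystem {target_subsystem!r} must be one of the generated names")
    target_members = set(map(str, rng.choice(genes, size=target_size, replace=False)))
    mapping: dict[str, frozenset[str]] = {}
    rest = [g for g in genes if g not in target_members]
    picks = rng.choice(others, size=len(rest), replace=True)
    for g in sorted(target_members):
        mapping[g] = frozenset({target_subsystem})
    for g, ss in zip(rest, picks):
        mapping[g] = frozenset({str(ss)})
    ledger = FixtureLedger(
        seed=seed,
        composition={organism: {"genes": n_genes, "annotated": n_genes, "subsystems": n_subsystems}},
        subsystem_sizes={organism: {target_subsystem: target_size}},
        true_enriched_subsystems=[target_subsystem],
    )
    return AnnotationSet(mapping=mapping, universe_size=n_genes), ledger


def gen_enriched_sample(
    background: AnnotationSet,
    target_subsystem: str,
    sample_size: int = 40,
    enrichment_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[str], FixtureLedger]:
    """Draw a gene sample with a planted enriched subsystem.

    ``ceil(enrichment_fraction * sample_size)`` genes come from the target
    subsystem and the remainder uniformly from the non-target genes.  With
    ``enrichment_fraction=0`` the whole sample is drawn uniformly from the
    background — the null draw used for type-I-error studies.  The ledger
    records the expected contingency counts (k, n, M, N).
    """
    if not 0.0 <= enrichment_fraction <= 1.0:
        raise ValueError("enrichment_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = sorted(background.mapping)
    target_members = [g for g in genes if target_subsystem in background.mapping[g]]
    if not target_members:
        raise ValueError(f"subsystem {target_subsystem!r} has no genes in the background")
    if sample_size > len(genes):
        raise ValueError(f"sample_size {sample_size} exceeds the {len(genes)}-gene background")
    M = len(target_members)
    N = background.universe_size
    if enrichment_fraction == 0.0:
        sample = sorted(map(str, rng.choice(genes, size=sample_size, replace=False)))
        k_expected = None  # a null draw has no planted count
    else:
        k = math.ceil(enrichment_fraction * sample_size)
        rest = [g for g in genes if target_subsystem not in background.mapping[g]]
        if k > M or sample_size - k > len(rest):
            raise ValueError("not enough genes to satisfy the requested composition")
        inside = rng.choice(target_members, size=k, replace=False)
        outside = rng.choice(rest, size=sample_size - k, replace=False)
        sample = sorted(map(str, np.concatenate([inside, outside])))
        k_expected = k
    ledger = FixtureLedger(
        seed=seed,
        true_enriched_subsystems=[target_subsystem] if enrichment_fraction > 0 else [],
        expected_table=(k_expected, sample_size, M, N),
    )
    return sample, ledger


def _sci(value: float) -> str:
    return format(value, ".2e")


def gen_blast_table(
    db: AnnotationDatabase,
    n_queries: int = 30,
    noise_hits_per_query: int = 4,
    decoy_evalue_range: tuple[float, float] = (1e-4, 10.0),
    seed: int = 0,
    organisms: list[str] | None = None,
    unannotated_rank1: bool = False,
    hsp_duplicates: bool = False,
) -> tuple[list[str], FixtureLedger]:
    """Tabular BLAST output with planted true orthologs plus decoy hits.

    Each query's true ortholog (an annotated database gene) gets an E-value
    at or below 1e-20 and the highest bit score, so it is rank-1-eligible.
    Decoy subjects are unannotated ids with E-values drawn log-uniformly
    from ``decoy_evalue_range`` (by default entirely above the 1e-5
    transfer cutoff).  ``unannotated_rank1`` additionally plants an
    unannotated hit *better* than the true ortholog, which exercises the
    best-annotated-hit rule; ``hsp_duplicates`` emits a second, weaker HSP
    row for each true pair.
    """
    rng = np.random.default_rng(seed)
    space = db if organisms is None else db.restrict(organisms)
    pool = sorted(g.value for g in space.genes if space.subsystems_of(g))
    if n_queries > len(pool):
        raise ValueError(f"requested {n_queries} queries but only {len(pool)} annotated subjects")
    subjects = [str(s) for s in rng.choice(pool, size=n_queries, replace=False)]
    lo, hi = (math.log10(decoy_evalue_range[0]), math.log10(decoy_evalue_range[1]))
    lines: list[str] = []
    true_orthologs: dict[str, str] = {}

    def row(q: str, s: str, evalue: float, bitscore: float) -> str:
        pident = f"{rng.uniform(35, 99):.2f}"
        length = int(rng.integers(100, 400))
        mismatch = int(rng.integers(0, 50))
        gapopen = int(rng.integers(0, 5))
        return "\t".join(
            [q, s, pident, str(length), str(mismatch), str(gapopen),
             "1", str(length), "1", str(length), _sci(evalue), f"{bitscore:.1f}"]
        )

    for i, subject in enumerate(subjects, start=1):
        q = f"q{i:04d}"
        true_orthologs[q] = subject
        true_e = 10.0 ** rng.uniform(-120, -20)
        true_bits = float(rng.uniform(500, 1500))
        if unannotated_rank1:
            lines.append(row(q, f"unann.{q}", true_e / 10.0, true_bits + 50.0))
        lines.append(row(q, subject, true_e, true_bits))
        if hsp_duplicates:
            lines.append(row(q, subject, min(true_e * 1e5, 1.0), true_bits / 3.0))
        for j in range(noise_hits_per_query):
            decoy_e = 10.0 ** rng.uniform(lo, hi)
            lines.append(row(q, f"decoy.{q}x{j}", decoy_e, float(rng.uniform(30, 120))))
    ledger = FixtureLedger(seed=seed, true_orthologs=true_orthologs)
    return lines, ledger


def _path_distance(parent: dict[str, str], a: str, b: str) -> int:
    """Oracle taxonomic distance by explicit path enumeration."""
    if a == b:
        return 0
    chain_b = {b}
    node = b
    while parent[node] != node:
        node = parent[node]
        chain_b.add(node)
    count = 0
    node = a
    while True:
        node = parent[node]
        count += 1
        if node in chain_b:
            return count


def gen_taxonomy(
    n_leaves: int = 12,
    seed: int = 0,
    names: list[str] | None = None,
) -> tuple[str, TaxonomyTree, FixtureLedger]:
    """A random rooted taxonomy over the given leaves, as Newick + tree.

    The tree is grown by repeatedly merging 2-3 random subtrees under a new
    named internal node.  The ledger records all ordered pairwise leaf
    distances computed by path enumeration.
    """
    if names is None:
        names = _organism_names(n_leaves)
    if len(names) < 2:
        raise ValueError("a taxonomy needs at least two leaves")
    rng = np.random.default_rng(seed)
    parent: dict[str, str] = {}
    children: dict[str, list[str]] = {}
    items = list(names)
    n_internal = 0
    while len(items) > 1:
        size = int(rng.integers(2, min(3, len(items)) + 1))
        idx = sorted(map(int, rng.choice(len(items), size=size, replace=False)))
        group = [items[i] for i in idx]
        n_internal += 1
        new = f"node{n_internal:03d}"
        children[new] = group
        for c in group:
            parent[c] = new
        items = [x for i, x in enumerate(items) if i not in idx] + [new]
    root = items[0]
    parent[root] = root

    def newick(node: str) -> str:
        if node not in children:
            return node
        return "(" + ",".join(newick(c) for c in children[node]) + ")" + node

    text = newick(root) + ";"
    tree = TaxonomyTree(parent)
    ledger = FixtureLedger(seed=seed)
    for a in names:
        for b in names:
            ledger.distances[(a, b)] = _path_distance(parent, a, b)
    return text, tree, ledger


def gen_noisy_predictions(
    reference: AnnotationSet,
    wrong_rate: float = 0.2,
    miss_rate: float = 0.1,
    seed: int = 0,
) -> tuple[list[MappingResult], FixtureLedger]:
    """Predictions with planted errors against a reference annotation.

    Each reference gene is left unpredicted with probability ``miss_rate``;
    each predicted gene is given a deliberately wrong (disjoint) subsystem
    set with probability ``wrong_rate``, otherwise its reference set is
    copied.  The ledger records the realised planted counts.
    """
    if not 0 <= wrong_rate <= 1 or not 0 <= miss_rate < 1:
        raise ValueError("rates must lie in [0, 1] (miss_rate < 1)")
    rng = np.random.default_rng(seed)
    results: list[MappingResult] = []
    n_missed = n_wrong = n_correct = 0
    for gene in sorted(reference.mapping):
        if rng.uniform() < miss_rate:
            n_missed += 1
            continue
        if rng.uniform() < wrong_rate:
            n_wrong += 1
            subs = frozenset({f"planted-wrong-subsystem-{gene}"})
        else:
            n_correct += 1
            subs = reference.mapping[gene]
        results.append(
            MappingResult(
                query=GeneId(gene, "query-local"),
                mapped_gene=GeneId(gene, "db-native"),
                subsystems=subs,
                provenance="precomputed-ortholog",
            )
        )
    ledger = FixtureLedger(
        seed=seed,
        planted_error_rate=wrong_rate,
        extra={"missed": n_missed, "wrong": n_wrong, "correct": n_correct},
    )
    return results, ledger
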