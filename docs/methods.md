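# Methods

## The enrichment model

For one subsystem S, the data reduce to a 2×2 contingency table

|              | in S  | not in S        |
|--------------|-------|-----------------|
| sample       | k     | n − k           |
| rest of bg   | M − k | (N − M) − (n − k) |

where n is the number of sample genes retained in the background, N the
background universe size, M the subsystem's background membership and k its
sample membership. Under the null hypothesis that the sample is an
exchangeable draw from the background, k is hypergeometric HG(N, M, n); the
reported p-value is always the one-sided (enrichment) upper tail
P(X ≥ k). Depletion is deliberately not tested — the tool's question is
over-representation only, which keeps all four offered tests directed and
mutually comparable.

The four tests relate as follows. The hypergeometric tail is exact under
sampling without replacement. The one-sided Fisher exact test on a 2×2
table with fixed margins is the same tail, and the two options are computed
identically (they are two field idioms for one test); the test suite checks
the identity exhaustively for N ≤ 25 and additionally cross-checks against
`scipy.stats.fisher_exact` and an exact `Fraction`-arithmetic summation.
The binomial test replaces sampling without replacement by with-replacement
draws at rate p = M/N; it errs in either direction for finite N but
converges to the hypergeometric tail as N → ∞ with M/N fixed (asserted on a
grid). The Pearson χ² statistic Σ(O−E)²/E with 1 df (no Yates continuity
correction) is the large-sample approximation; following Cochran's rule it
is treated as unreliable when any of the four expected cell counts
E = (row margin × column margin)/N is below 5, in which case the
implementation silently substitutes the Fisher exact p-value and records
`method_used = fisher` in the output. A zero margin (e.g. M = N or k = n
forced) makes the statistic undefined; such tables are signalled unreliable
with a NaN p-value and likewise fall back.

Multiple testing is corrected across the m subsystems tested in the run —
exactly those with at least one sample gene, recorded in the output header
— with the Benjamini–Hochberg step-up procedure
q\_(i) = min\_{j ≥ i} min(1, m·p\_(j)/j) (via
`statsmodels.stats.multitest.multipletests`); Bonferroni and
Benjamini–Yekutieli are selectable. Computed q-values below 10⁻³⁰⁰ are
*displayed* as 0 in formatted output (a display convention only; the full
value is kept in memory).

### The background universe

The background of an organism is its set of annotated genes — genes with at
least one subsystem membership — and N defaults to the count of those
genes. Unannotated genes can never contribute to k or M, so including them
in N would only dilute N − M without information; the annotated-universe
convention keeps every cell of the table meaningful. Users who prefer the
whole-genome convention can pass `use_total_genes=True` (CLI
`--use-total-genes`), which takes N from the per-organism gene-count
sidecar.

Sample genes must be drawn from the background universe: genes absent from
the background are dropped with a warning (an empty intersection is an
error). When a sample comes from an `.ann` file, its genes are keyed by the
*mapped database gene id* rather than the query's own id, so
homology-derived samples are automatically commensurate with an organism
background; counting k from the background's annotation of the retained
genes guarantees k ≤ M structurally. Keying by query id is available
(`--key query`) for samples that are already in background coordinates.

## Homology transfer

Tabular 12-column BLAST output is reduced to gene-level hits: multiple HSP
rows for one query–subject pair collapse to the lowest-E-value row (ties to
the higher bit score). Per query, hits are ranked 1..h by (E-value
ascending, bit score descending, subject id lexicographic) — the last key
makes ranking, and hence every downstream transfer, a total order
independent of input row order. A transfer happens from the minimum-rank
hit satisfying all of: E-value ≤ 1e-5, rank ≤ 5, subject annotated. The
rank window is counted over *all* hits (annotated or not), matching the
order in which the three predicates are stated; an unannotated rank-1 hit
therefore does not disqualify a query — the best annotated hit within the
window wins. Self-hits are kept by default and removed only under
`--exclude-self`, the re-annotation setting where the query organism is
itself in the reference set. Relaxing either cutoff can only add transfers
or move an existing transfer to a better-ranked subject (asserted as a
monotonicity property).

Multiple reference genomes are merged into a single search space by
unioning their assignments; gene ids remain organism-qualified so each
transfer's source genome is recoverable.

## Reference-genome selection

Taxonomic distance from query to reference is the number of nodes on the
path from the query leaf up to their lowest common ancestor, excluding the
leaf and including the ancestor (siblings are at distance 1). The count is
directional by construction and is *not* a metric; only the ordering of
distances from the fixed query matters to the strategies, and that ordering
is invariant to whether the ancestor is counted — which is why the
include-the-LCA convention is safe to fix arbitrarily.

Candidates (organisms present in both database and tree, minus the query)
are grouped into distance classes. Within a class the representative is the
organism whose genome size is closest to the query's — a proxy for
comparable gene complement — with remaining ties broken lexicographically
by name so selection is deterministic. The `nearest` strategy takes one
representative per class in ascending class order, then (if K exceeds the
number of classes) a second representative per class in the same order, and
so on until K genomes are selected or candidates are exhausted; `farthest`
mirrors this in descending order; `single` returns the representative of
one exact distance. Taking one representative per class before revisiting
any class preserves taxonomic diversity, which is the point of
distance-aware selection. The default K is 10. The round-robin construction
makes the K-selection a prefix of the (K+1)-selection, which the tests
assert.

## Evaluation of annotation transfer

Re-annotation experiments score predictions per gene over the evaluation
universe of genes with at least one reference subsystem: TP when the
predicted subsystem set matches the reference set, FP when a prediction
exists but does not match, FN when no prediction exists. Because a gene can
carry several subsystems, "matches" is ambiguous; both readings are
implemented and reported. The lenient rule (default) counts any non-empty
intersection as a match; the strict rule requires exact set equality. A
zero denominator makes precision or coverage *undefined*, which is raised
as a distinct condition (rendered `NA` in the CLI) rather than conflated
with 0.

## Synthetic data

The generators in `seedpath.fixtures` produce every input dialect with
planted ground truth recorded in a ledger, so correctness is checked
against construction, not against the implementation:

- `gen_database` — per organism and subsystem, membership counts are drawn
  Poisson(mean 8 by default) truncated below at 1 and filled by sampling
  genes without replacement; with `ensure_coverage` every gene gets at
  least one membership. Default shape: 3 organisms × 200 genes × 20
  subsystems.
- `gen_background` / `gen_enriched_sample` — the enrichment study design: a
  2,000-gene universe, 40 subsystems, one target subsystem of exactly 100
  genes (5% background frequency); samples of 40 genes drawn 80% from the
  target (planted case) or uniformly (null case). Each gene carries exactly
  one subsystem, so the planted contingency table (k, n, M, N) is known
  exactly.
- `gen_blast_table` — true orthologs get E-values ≤ 10⁻²⁰ and dominant bit
  scores; decoy hits are unannotated subjects with E-values log-uniform in
  (10⁻⁴, 10), i.e. entirely outside the transfer cutoff; options plant an
  unannotated better-than-true hit (exercising the best-annotated rule) or
  duplicate HSP rows (exercising pair collapse).
- `gen_taxonomy` — random rooted trees grown by repeated 2–3-way merges;
  ledger distances come from independent path enumeration.
- `gen_noisy_predictions` — per reference gene: unpredicted with
  probability 0.1, else wrong (disjoint subsystem set) with probability
  0.2, else correct; realised counts are ledgered.

All generators are pure functions of their parameters and a seed (numpy
PCG64), so reruns are byte-identical.

What the fixtures do *not* emulate: realistic sequence evolution, E-value
distributions correlated with taxonomic distance, paralog structure,
multi-membership correlation between subsystems, or partially annotated
backgrounds with structured bias. Passing tests therefore demonstrate
correctness of the mapping/filter/test machinery on inputs with known
truth, not the field accuracy of homology transfer on real genomes — the
latter depends on database coverage and evolutionary distance in ways no
synthetic fixture certifies.

## Numerical and interface choices

- Tails are computed by `scipy.stats` survival functions (`sf(k-1, ...)`),
  never by `1 − cdf`, avoiding cancellation in small upper tails; test
  oracles use exact rational arithmetic.
- Problem sizes in the test and acceptance runs (N = 2,000 universes, 200
  power replicates, 1,000 null replicates, exhaustive tables to N = 25)
  were chosen to give stable Monte-Carlo estimates (3·SE bands) while
  keeping the whole suite interactive-fast.
- Fixed output ordering everywhere (sorted assignment rows, sorted queries,
  q/p/name-sorted enrichment results) plus `--no-timestamp` give
  byte-identical end-to-end reruns.
- Errors name their context (file and line for parse errors, available
  organisms or occupied distances for lookup errors); absence of a mapping
  is data (an unmapped result), never an exception.

## Known limitations

- The χ² fallback substitutes the Fisher p-value but the FDR correction
  then mixes exact and asymptotic p-values within one run; this mirrors the
  described behaviour and is recorded per row in `method_used`.
- Gene-id aliasing covers GI ↔ database-native pairs via an explicit
  two-column table only; without it, namespaces are disjoint by design and
  no fuzzy or transitive resolution is attempted.
- The optional `run_blast` wrapper shells out to NCBI BLAST for FASTA input
  but is deliberately untested plumbing; the supported, reproducible path
  is precomputed tabular output.
- Ranked-list (GSEA-class) and module-aware enrichment are out of scope;
  the statistics here are per-subsystem tests on a pre-selected gene list.
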