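"""Per-subsystem enrichment statistics on 2x2 contingency counts.

For each subsystem touched by the sample, the question is whether the sample
over-represents the subsystem relative to a background universe.  The counts
are

    k : sample genes in the subsystem
    n : sample genes (annotated, retained in the background)
    M : background genes in the subsystem
    N : background universe size

Four tests are offered, all one-sided in the enrichment direction:

* ``hyper``  — exact upper tail P(X >= k), X ~ Hypergeometric(N, M, n);
* ``binom``  — upper tail P(Y >= k), Y ~ Binomial(n, M/N), the fast
  approximation for large inputs;
* ``chisq``  — Pearson chi-square on the 2x2 table, 1 df, no continuity
  correction; unreliable (any expected cell < 5, Cochran's rule) tables
  automatically fall back to Fisher's exact test;
* ``fisher`` — one-sided Fisher exact test, mathematically identical to the
  hypergeometric upper tail.

Multiple testing across subsystems is corrected by Benjamini-Hochberg FDR
(Bonferroni and Benjamini-Yekutieli available), with m equal to the number
of subsystems tested in the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationSet

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "METHODS",
    "build_tables",
    "hypergeom_pvalue",
    "binomial_pvalue",
    "chisq_pvalue",
    "fisher_pvalue",
    "adjust_fdr",
    "pathfind",
]

METHODS = ("hyper", "binom", "chisq", "fisher")

FDR_METHODS = {"BH": "fdr_bh", "bonferroni": "bonferroni", "BY": "fdr_by"}

#: below this, a q-value is displayed as exactly 0 in formatted output
UNDERFLOW_DISPLAY = 1e-300


@dataclass(frozen=True)
class ContingencyTable:
    """Counts (k, n, M, N) for one subsystem against one background."""

    k: int
    n: int
    M: int
    N: int

    def __post_init__(self) -> None:
        k, n, M, N = self.k, self.n, self.M, self.N
        if min(k, n, M, N) < 0:
            raise ValueError(f"counts must be non-negative: {self}")
        if n > N or M > N:
            raise ValueError(f"sample/subsystem cannot exceed the universe: {self}")
        if k > min(n, M):
            raise ValueError(f"k must not exceed min(n, M): {self}")
        if k < n + M - N:
            raise ValueError(f"k must be at least n + M - N: {self}")

    def as_2x2(self) -> np.ndarray:
        """Observed 2x2 layout [[k, M-k], [n-k, (N-M)-(n-k)]]."""
        return np.array(
            [[self.k, self.M - self.k], [self.n - self.k, (self.N - self.M) - (self.n - self.k)]]
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """One subsystem's enrichment outcome."""

    subsystem: str
    table: ContingencyTable
    pvalue: float
    qvalue: float
    method_used: str  # records chi-square -> Fisher fallback
    significant: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0 or not 0.0 <= self.qvalue <= 1.0:
            raise ValueError(f"p/q-values must lie in [0, 1]: {self}")
        if self.method_used not in METHODS:
            raise ValueError(f"unknown method {self.method_used!r}")


def build_tables(
    sample: AnnotationSet, background: AnnotationSet
) -> list[tuple[str, ContingencyTable]]:
    """Contingency tables for every subsystem represented in the sample.

    Sample genes must come from the background universe; genes absent from
    the background are dropped with a warning (the hypergeometric model
    requires the sample to be a subset of the background).  Counts for
    retained genes use the background's annotation, so k <= M always holds.
    """
    retained = sorted(g for g in sample.mapping if g in background.mapping)
    dropped = len(sample.mapping) - len(retained)
    if dropped:
        warnings.warn(
            f"{dropped} sample gene(s) absent from the background were dropped",
            stacklevel=2,
        )
    if not retained:
        raise ValueError("no sample gene is present in the background")
    n = len(retained)
    N = background.universe_size
    subsys_k: dict[str, int] = {}
    for g in retained:
        for s in background.mapping[g]:
            subsys_k[s] = subsys_k.get(s, 0) + 1
    subsys_M: dict[str, int] = {}
    for subs in background.mapping.values():
        for s in subs:
            subsys_M[s] = subsys_M.get(s, 0) + 1
    return [
        (s, ContingencyTable(k=subsys_k[s], n=n, M=subsys_M[s], N=N))
        for s in sorted(subsys_k)
    ]


def hypergeom_pvalue(t: ContingencyTable) -> float:
    """Exact upper tail P(X >= k) under Hypergeometric(N, M, n)."""
    return float(sps.hypergeom.sf(t.k - 1, t.N, t.M, t.n))


def binomial_pvalue(t: ContingencyTable) -> float:
    """Upper tail P(Y >= k) under Binomial(n, M/N)."""
    if t.N == 0:
        raise ValueError("binomial test requires a non-empty universe")
    return float(sps.binom.sf(t.k - 1, t.n, t.M / t.N))


def chisq_pvalue(t: ContingencyTable) -> tuple[float, bool]:
    """Pearson chi-square p-value on the 2x2 table, with a reliability flag.

    ``reliable`` is False when any expected cell count is below 5
    (Cochran's rule) or when a zero margin makes the statistic undefined;
    in the latter case the p-value is NaN.
    """
    obs = t.as_2x2().astype(float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if t.N == 0 or (row == 0).any() or (col == 0).any():
        return float("nan"), False
    expected = np.outer(row, col) / t.N
    statistic = float(((obs - expected) ** 2 / expected).sum())
    pvalue = float(sps.chi2.sf(statistic, df=1))
    reliable = bool((expected >= 5).all())
    return pvalue, reliable


def fisher_pvalue(t: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher exact p-value on the 2x2 table.

    The one-sided Fisher test on a 2x2 table *is* the hypergeometric upper
    tail, and the two options are kept bit-identical so the four methods
    stay commensurable; both names are exposed because the field uses both.
    """
    return float(sps.hypergeom.sf(t.k - 1, t.N, t.M, t.n))


def adjust_fdr(pvalues: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjusted q-values, in the input order.

    BH is the step-up false-discovery-rate procedure
    q_(i) = min_{j >= i} min(1, m p_(j) / j) over the sorted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in FDR_METHODS:
        raise ValueError(f"unknown FDR method {method!r}; choose from {sorted(FDR_METHODS)}")
    return multipletests(p, method=FDR_METHODS[method])[1]


def _raw_pvalue(table: ContingencyTable, method: str) -> tuple[float, str]:
    if method == "hyper":
        return hypergeom_pvalue(table), "hyper"
    if method == "binom":
        return binomial_pvalue(table), "binom"
    if method == "fisher":
        return fisher_pvalue(table), "fisher"
    if method == "chisq":
        pvalue, reliable = chisq_pvalue(table)
        if not reliable:
            return fisher_pvalue(table), "fisher"
        return pvalue, "chisq"
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def pathfind(
    sample: AnnotationSet,
    background: AnnotationSet,
    method: str = "hyper",
    fdr_cutoff: float = 0.05,
    fdr_method: str = "BH",
) -> list[EnrichmentResult]:
    """Enrichment results for every subsystem touched by the sample.

    FDR is corrected across all tested subsystems (m = number of tables),
    and results are sorted by (q-value, p-value, subsystem name).
    Subsystems at or below ``fdr_cutoff`` are flagged significant.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    tables = build_tables(sample, background)
    raw: list[tuple[str, ContingencyTable, float, str]] = []
    for name, table in tables:
        pvalue, used = _raw_pvalue(table, method)
        raw.append((name, table, pvalue, used))
    qvalues = adjust_fdr([r[2] for r in raw], method=fdr_method)
    results = [
        EnrichmentResult(
            subsystem=name,
            table=table,
            pvalue=pvalue,
            qvalue=float(q),
            method_used=used,
            significant=bool(q <= fdr_cutoff),
        )
        for (name, table, pvalue, used), q in zip(raw, qvalues)
    ]
    results.sort(key=lambda r: (r.qvalue, r.pvalue, r.subsystem))
    return results


def format_pvalue(value: float) -> str:
    """Render a p/q-value for tabular output; underflow displays as 0."""
    if value < UNDERFLOW_DISPLAY:
        return "0"
    return format(value, ".6g")
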