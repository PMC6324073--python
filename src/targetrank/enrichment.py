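"""Batch target-list analytics: term enrichment and pathway-alteration tests.

A batch query is a list of up to 200 target identifiers.  For each
annotation category (diseases, pathways, GO terms) every term with at
least one query member is tested for over-representation with the
hypergeometric upper tail

    P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the universe size, K the term's set size, n the query size and
k the overlap, then Benjamini-Hochberg adjusted within the category and
ranked by p-value.  Drugs are reported by direct lookup (query targets ->
known modulating drugs), not tested.

For somatic-mutation pathway analysis the module also provides the
Poisson-binomial tail used to ask whether more samples than expected
carry an alteration in a pathway: a pathway is altered in a sample if at
least one of its genes is mutated there, so the per-sample alteration
probability is 1 - prod_g (1 - q_g), and the count of altered samples
across a cohort is Poisson-binomial with those per-sample probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import BatchSizeError, EmptyQueryError, ScoringDomainError

__all__ = [
    "AnnotationTable",
    "BatchQuery",
    "EnrichmentResult",
    "DrugHit",
    "hypergeom_tail",
    "poisson_binomial_tail",
    "pathway_alteration_probability",
    "bh_adjust",
    "batch_search",
    "BATCH_LIMIT",
]

#: Maximum number of identifiers accepted by a batch query.
BATCH_LIMIT = 200


@dataclass(frozen=True)
class AnnotationTable:
    """Term -> gene-set membership for one annotation category."""

    category: str  # disease | pathway | go | drug
    sets: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self):
        for term, members in self.sets.items():
            stray = members - self.universe
            if stray:
                raise ScoringDomainError(
                    f"term {term!r} has members outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    @classmethod
    def from_pairs(
        cls,
        category: str,
        pairs: Sequence[tuple[str, str]],
        universe: Optional[set[str]] = None,
    ) -> "AnnotationTable":
        sets: dict[str, set[str]] = {}
        for term, gene in pairs:
            sets.setdefault(term, set()).add(gene)
        members = {g for s in sets.values() for g in s}
        uni = frozenset(universe) if universe is not None else frozenset(members)
        return cls(
            category=category,
            sets={t: frozenset(s) for t, s in sets.items()},
            universe=uni,
        )

    @classmethod
    def from_tsv(
        cls,
        path: Union[str, Path],
        category: str,
        universe: Optional[set[str]] = None,
    ) -> "AnnotationTable":
        """Read two-column tab-separated ``term_id<TAB>gene_id`` pairs."""
        pairs = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ScoringDomainError(
                        f"{path}: expected term_id<TAB>gene_id, got {line!r}"
                    )
                pairs.append((parts[0], parts[1]))
        return cls.from_pairs(category, pairs, universe)

    @classmethod
    def from_gmt(
        cls,
        path: Union[str, Path],
        category: str,
        universe: Optional[set[str]] = None,
    ) -> "AnnotationTable":
        """Read a GMT gene-set file (term, description, members...)."""
        pairs = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                term = parts[0]
                for gene in parts[2:]:
                    if gene:
                        pairs.append((term, gene))
        return cls.from_pairs(category, pairs, universe)


@dataclass(frozen=True)
class BatchQuery:
    """A resolved target list of at most 200 identifiers."""

    raw: tuple[str, ...]
    resolved: frozenset[str]
    unresolved: tuple[str, ...]
    duplicates_collapsed: int = 0

    @classmethod
    def from_identifiers(
        cls,
        identifiers: Sequence[str],
        universe: set[str],
        synonyms: Optional[Mapping[str, str]] = None,
        limit: int = BATCH_LIMIT,
    ) -> "BatchQuery":
        """Resolve raw identifiers against the universe.

        A local synonym table (symbol/synonym -> canonical identifier) may
        be supplied; no live lookups are performed.  Duplicates are
        collapsed with a warning carrying the collapsed count.  More than
        ``limit`` identifiers is an error naming the limit.
        """
        identifiers = [i.strip() for i in identifiers if i.strip()]
        if len(identifiers) > limit:
            raise BatchSizeError(
                f"batch query has {len(identifiers)} identifiers; "
                f"the limit is {limit} targets"
            )
        seen: list[str] = []
        dup = 0
        for ident in identifiers:
            if ident in seen:
                dup += 1
            else:
                seen.append(ident)
        if dup:
            warnings.warn(f"collapsed {dup} duplicate identifiers", stacklevel=2)
        synonyms = synonyms or {}
        resolved, unresolved = set(), []
        for ident in seen:
            canonical = ident if ident in universe else synonyms.get(ident)
            if canonical is not None and canonical in universe:
                resolved.add(canonical)
            else:
                unresolved.append(ident)
        if not resolved:
            raise EmptyQueryError("no identifier resolved against the universe")
        return cls(
            raw=tuple(seen),
            resolved=frozenset(resolved),
            unresolved=tuple(unresolved),
            duplicates_collapsed=dup,
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested term with its hypergeometric and adjusted p-values."""

    term_id: str
    category: str
    k: int  # overlap
    K: int  # term set size
    n: int  # query size
    N: int  # universe size
    p_value: float
    adjusted_p: float


@dataclass(frozen=True)
class DrugHit:
    """A drug known to modulate some of the query targets (direct lookup)."""

    term_id: str
    targets: tuple[str, ...]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n).

    Computed by scipy's survival function (log-space internally, stable
    far into the tail).
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ScoringDomainError(
            f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def poisson_binomial_tail(probs: Sequence[float], k: int) -> float:
    """Upper-tail P(X >= k) for X = sum of Bernoulli(p_j).

    Dynamic-programming convolution over the success probabilities,
    O(n * k) time: after processing trial j, ``pmf[c]`` is P(count == c)
    truncated at k successes (the k-th cell absorbs "k or more").
    """
    probs = list(probs)
    for p in probs:
        if not (0.0 <= p <= 1.0):
            raise ScoringDomainError(f"probability outside [0, 1]: {p}")
    n = len(probs)
    if not (0 <= k <= n):
        raise ScoringDomainError(f"k={k} outside [0, {n}]")
    if k == 0:
        return 1.0
    # pmf[c] for c < k; absorb[>=k] tracked implicitly as 1 - sum(pmf)
    pmf = np.zeros(k, dtype=float)
    pmf[0] = 1.0
    for p in probs:
        # mass leaving pmf[k-1] on success crosses into the absorbed >= k tail
        pmf[1:] = pmf[1:] * (1.0 - p) + pmf[:-1] * p
        pmf[0] *= 1.0 - p
    return float(min(1.0, max(0.0, 1.0 - pmf.sum())))


def pathway_alteration_probability(gene_probs: Sequence[float]) -> float:
    """Probability a sample's pathway is altered: at least one gene mutated.

    ``gene_probs`` are the sample's per-gene mutation probabilities for
    the pathway's genes; the pathway is altered if any gene is mutated, so
    the probability is 1 - prod(1 - q_g).
    """
    for q in gene_probs:
        if not (0.0 <= q <= 1.0):
            raise ScoringDomainError(f"probability outside [0, 1]: {q}")
    out = 1.0
    for q in gene_probs:
        out *= 1.0 - q
    return 1.0 - out


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    if len(p_values) == 0:
        return []
    for p in p_values:
        if not (0.0 < p <= 1.0):
            raise ScoringDomainError(f"p-value outside (0, 1]: {p}")
    _, adjusted, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(p) for p in adjusted]


def batch_search(
    query: BatchQuery,
    tables: Sequence[AnnotationTable],
    adjust: bool = True,
) -> dict[str, list]:
    """Enrichment report per annotation category for a batch target list.

    Categories other than ``drug`` are tested with the hypergeometric
    upper tail over every term overlapping the query (k >= 1), BH-adjusted
    within the category (``adjust=False`` reports raw p-values in both
    columns), and ranked ascending by p-value then lexicographically by
    term.  The ``drug`` category is a direct lookup of modulating drugs
    ranked by the number of query targets hit.
    """
    report: dict[str, list] = {}
    for table in tables:
        if table.category == "drug":
            hits = [
                DrugHit(term_id=term, targets=tuple(sorted(members & query.resolved)))
                for term, members in table.sets.items()
                if members & query.resolved
            ]
            hits.sort(key=lambda h: (-len(h.targets), h.term_id))
            report[table.category] = hits
            continue

        n = len(query.resolved & table.universe)
        N = len(table.universe)
        tested = []
        for term in sorted(table.sets):
            members = table.sets[term]
            k = len(members & query.resolved)
            if k < 1:
                continue
            p = hypergeom_tail(k, len(members), n, N)
            tested.append((term, k, len(members), p))
        adjusted = (
            bh_adjust([t[3] for t in tested]) if adjust else [t[3] for t in tested]
        )
        results = [
            EnrichmentResult(
                term_id=term,
                category=table.category,
                k=k,
                K=K,
                n=n,
                N=N,
                p_value=p,
                adjusted_p=ap,
            )
            for (term, k, K, p), ap in zip(tested, adjusted)
        ]
        results.sort(key=lambda r: (r.p_value, r.term_id))
        report[table.category] = results
    return report
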