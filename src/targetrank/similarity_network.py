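"""Target-similarity network over the filtered association graph.

Associations form a bipartite graph with targets and diseases as vertices.
To reduce noise, only pairs supported by at least three evidence strings
and with an overall association score strictly greater than 0.1 become
edges.  Two targets are similar when they share diseases; the relationship
score is the ratio of shared diseases to the total diseases of both
targets (a Jaccard index over disease neighbour sets), optionally weighted
by inverse disease degree so that sharing a rare disease counts for more
than sharing a data-rich one such as cancer.  The same machinery applies
symmetrically to disease-disease similarity via shared targets.

All-pairs scoring is quadratic, so candidate pairs are shortlisted with
MinHash locality-sensitive hashing: per-entity signatures whose per-hash
collision probability equals the Jaccard similarity, bucketed in bands so
that only pairs agreeing on a whole band are ever scored.  A size-ratio
bound J(a,b) <= min(|A|,|B|)/max(|A|,|B|) additionally skips pairs that
cannot reach the candidate threshold.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import GraphLookupError, ScoringDomainError
from .evidence_model import AssociationRecord

__all__ = [
    "BipartiteGraph",
    "RelationshipScore",
    "LshConfig",
    "build_graph",
    "relationship_score",
    "minhash_signatures",
    "lsh_candidates",
    "similar_entities",
]

Side = Literal["targets", "diseases"]

#: Mersenne prime 2**61 - 1 used as the universal-hash modulus.
_MERSENNE = (1 << 61) - 1

#: Shared diseases reported per relationship, mirroring the top-20 display.
MAX_SHARED_REPORTED = 20


@dataclass
class BipartiteGraph:
    """Filtered target-disease graph with neighbour sets and degrees."""

    targets: dict[str, set[str]]
    diseases: dict[str, set[str]]
    edge_scores: dict[tuple[str, str], float]
    edge_evidence: dict[tuple[str, str], int]
    min_evidence: int = 3
    min_score: float = 0.1

    def neighbors(self, entity: str, side: Side) -> set[str]:
        table = self.targets if side == "targets" else self.diseases
        try:
            return table[entity]
        except KeyError:
            raise GraphLookupError(
                f"{side[:-1]} {entity!r} not in graph"
            ) from None

    def degree(self, entity: str, side: Side) -> int:
        return len(self.neighbors(entity, side))

    def entities(self, side: Side) -> list[str]:
        return sorted(self.targets if side == "targets" else self.diseases)


@dataclass(frozen=True)
class RelationshipScore:
    """Symmetric similarity between two entities with ranked shared neighbours."""

    entity_a: str
    entity_b: str
    score: float
    shared: tuple[str, ...]  # ranked, length <= MAX_SHARED_REPORTED


@dataclass(frozen=True)
class LshConfig:
    """MinHash/LSH parameters; ``bands * rows_per_band`` must equal ``num_hashes``."""

    num_hashes: int = 128
    bands: int = 32
    rows_per_band: int = 4
    seed: int = 0
    candidate_threshold: float = 0.1

    def __post_init__(self):
        if self.bands * self.rows_per_band != self.num_hashes:
            raise ScoringDomainError(
                f"bands ({self.bands}) x rows_per_band ({self.rows_per_band}) "
                f"must equal num_hashes ({self.num_hashes})"
            )


def build_graph(
    associations: Sequence[AssociationRecord],
    min_evidence: int = 3,
    min_score: float = 0.1,
) -> BipartiteGraph:
    """Build the filtered bipartite graph from association records.

    An edge is retained iff its total evidence count is at least
    ``min_evidence`` (inclusive) and its overall score is strictly greater
    than ``min_score``.
    """
    targets: dict[str, set[str]] = {}
    diseases: dict[str, set[str]] = {}
    edge_scores: dict[tuple[str, str], float] = {}
    edge_evidence: dict[tuple[str, str], int] = {}
    for rec in associations:
        if rec.total_evidence >= min_evidence and rec.overall > min_score:
            key = (rec.target_id, rec.disease_id)
            targets.setdefault(rec.target_id, set()).add(rec.disease_id)
            diseases.setdefault(rec.disease_id, set()).add(rec.target_id)
            edge_scores[key] = rec.overall
            edge_evidence[key] = rec.total_evidence
    return BipartiteGraph(
        targets=targets,
        diseases=diseases,
        edge_scores=edge_scores,
        edge_evidence=edge_evidence,
        min_evidence=min_evidence,
        min_score=min_score,
    )


def _other_side(side: Side) -> Side:
    return "diseases" if side == "targets" else "targets"


def relationship_score(
    a: str,
    b: str,
    graph: BipartiteGraph,
    weighting: str = "weighted",
    side: Side = "targets",
    denominator: str = "union",
) -> RelationshipScore:
    """Similarity of two same-side entities through shared neighbours.

    ``weighting="unweighted"`` gives the plain Jaccard index
    |N(a) & N(b)| / |N(a) | N(b)|.  ``"weighted"`` (default) weights each
    neighbour d by 1/degree(d), so a shared rare disease moves the score
    more than a shared ubiquitous one, and an entity linked to few
    diseases counts as more specific.  ``denominator="sum"`` replaces the
    union by |N(a)| + |N(b)| (a Sorensen-style reading); union is the
    default because it keeps identical neighbour sets at exactly 1.

    Shared neighbours are reported ranked by weight descending (rarest
    first, ties lexicographic), truncated to the top 20.
    """
    na = graph.neighbors(a, side)
    nb = graph.neighbors(b, side)
    inter = na & nb
    other = _other_side(side)

    if weighting == "unweighted":
        weight = {d: 1.0 for d in na | nb}
    elif weighting == "weighted":
        weight = {d: 1.0 / graph.degree(d, other) for d in na | nb}
    else:
        raise ScoringDomainError(f"unknown weighting mode {weighting!r}")

    num = sum(weight[d] for d in inter)
    if denominator == "union":
        den = sum(weight[d] for d in na | nb)
    elif denominator == "sum":
        den = sum(weight[d] for d in na) + sum(weight[d] for d in nb)
    else:
        raise ScoringDomainError(f"unknown denominator mode {denominator!r}")

    score = num / den if den > 0 else 0.0
    ranked = sorted(inter, key=lambda d: (-weight[d], d))[:MAX_SHARED_REPORTED]
    return RelationshipScore(entity_a=a, entity_b=b, score=score, shared=tuple(ranked))


def _element_ids(names: Sequence[str]) -> np.ndarray:
    """Stable 64-bit integers for neighbour identifiers (blake2b digest)."""
    return np.array(
        [
            int.from_bytes(hashlib.blake2b(n.encode(), digest_size=8).digest(), "big")
            % _MERSENNE
            for n in names
        ],
        dtype=np.uint64,
    )


def minhash_signatures(
    sets: dict[str, set[str]], config: LshConfig
) -> dict[str, np.ndarray]:
    """MinHash signature per entity, deterministic given ``config.seed``.

    Uses ``num_hashes`` universal hash functions h_i(x) = (a_i x + b_i)
    mod (2^61 - 1); the signature entry i is the minimum of h_i over the
    entity's neighbour set.  P[sig_a[i] == sig_b[i]] equals the Jaccard
    similarity of the two neighbour sets.
    """
    rng = np.random.default_rng(config.seed)
    a = rng.integers(1, _MERSENNE, size=config.num_hashes, dtype=np.uint64)
    b = rng.integers(0, _MERSENNE, size=config.num_hashes, dtype=np.uint64)

    all_names = sorted({n for members in sets.values() for n in members})
    ids = _element_ids(all_names)
    index = {n: i for i, n in enumerate(all_names)}
    # hash table: row = element, column = hash function (python ints avoid
    # uint64 overflow in the modular product)
    table = (
        ids[:, None].astype(object) * a[None, :].astype(object)
        + b[None, :].astype(object)
    ) % _MERSENNE
    table = table.astype(np.uint64) if table.size else table

    signatures: dict[str, np.ndarray] = {}
    for entity, members in sets.items():
        if not members:
            signatures[entity] = np.full(config.num_hashes, _MERSENNE, dtype=np.uint64)
            continue
        rows = np.array([index[m] for m in members], dtype=np.intp)
        signatures[entity] = np.asarray(table[rows].min(axis=0), dtype=np.uint64)
    return signatures


def lsh_candidates(
    graph: BipartiteGraph, side: Side, config: Optional[LshConfig] = None
) -> set[tuple[str, str]]:
    """Candidate same-side pairs co-bucketed in at least one LSH band.

    Entities with identical neighbour sets have identical signatures and
    are always candidates; the probability that a pair with Jaccard J is
    returned is 1 - (1 - J**rows_per_band)**bands.
    """
    config = config or LshConfig()
    table = graph.targets if side == "targets" else graph.diseases
    if not table:
        return set()
    signatures = minhash_signatures(table, config)
    candidates: set[tuple[str, str]] = set()
    r = config.rows_per_band
    for band in range(config.bands):
        buckets: dict[bytes, list[str]] = {}
        for entity, sig in signatures.items():
            key = sig[band * r : (band + 1) * r].tobytes()
            buckets.setdefault(key, []).append(entity)
        for members in buckets.values():
            if len(members) > 1:
                members = sorted(members)
                for i in range(len(members)):
                    for j in range(i + 1, len(members)):
                        candidates.add((members[i], members[j]))
    return candidates


#: Below this many entities on a side, similarity queries score all pairs
#: exactly instead of going through LSH.
EXACT_GUARD = 1000


def similar_entities(
    a: str,
    graph: BipartiteGraph,
    config: Optional[LshConfig] = None,
    weighting: str = "weighted",
    k: int = 20,
    side: Side = "targets",
) -> list[RelationshipScore]:
    """Top-k entities most similar to ``a`` by relationship score.

    For small graph sides (fewer than 1000 entities) every pair is scored
    exactly; larger sides are shortlisted with LSH plus the size-ratio
    Jaccard upper bound min(|A|,|B|)/max(|A|,|B|), which skips pairs that
    cannot reach the candidate threshold.  Ties are broken
    lexicographically by identifier; no padding when fewer than k
    candidates exist.
    """
    config = config or LshConfig()
    na = graph.neighbors(a, side)  # raises GraphLookupError if absent
    table = graph.targets if side == "targets" else graph.diseases

    if len(table) <= EXACT_GUARD:
        others = [e for e in table if e != a]
    else:
        pairs = lsh_candidates(graph, side, config)
        others = sorted(
            {x if y == a else y for x, y in pairs if a in (x, y)}
        )
        # size-ratio bound: J <= min/max of the two set sizes
        others = [
            e
            for e in others
            if min(len(na), len(table[e])) / max(len(na), len(table[e]))
            >= config.candidate_threshold
        ]

    scored = [
        relationship_score(a, b, graph, weighting=weighting, side=side)
        for b in others
    ]
    scored = [s for s in scored if s.score > 0.0]
    scored.sort(key=lambda s: (-s.score, s.entity_b))
    return scored[:k]
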