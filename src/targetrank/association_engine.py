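"""Harmonic-sum aggregation of scored evidence into association scores.

Scoring is carried out at four levels.  Evidence scores are aggregated per
data source with a normalised harmonic sum; source scores are aggregated
into data-type scores; and the overall association score for a
target-disease pair is the harmonic sum over its data-source scores.

The harmonic sum of scores s_(1) >= s_(2) >= ... (sorted descending) is

    HS(s) = sum_{i=1..min(n, cap)} s_(i) / i**e

with exponent e = 2 by default.  When normalised (the default) it is
divided by its same-length maximum sum_{i<=min(n, cap)} 1 / i**e, so the
result stays in [0, 1], a singleton maps to itself and a constant vector
maps to its constant.  Rank discounting means a pair with one strong piece
of evidence outranks a pair with many weak ones, while additional evidence
still never lowers a score.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import pydantic

from .errors import EvidenceValidationError, ScoringDomainError
from .evidence_model import (
    AssociationRecord,
    DataSourceRegistry,
    EvidenceString,
)

__all__ = [
    "HarmonicSumConfig",
    "AssociationRecord",
    "harmonic_sum",
    "aggregate",
    "read_associations",
    "flat_export",
]


@dataclass(frozen=True)
class HarmonicSumConfig:
    """Harmonic-sum parameters.

    ``cap`` truncates the sum after the top-ranked terms so unbounded
    evidence streams (text mining can contribute thousands of records per
    pair) cannot accumulate without limit.  ``overall_from`` selects
    whether the overall score aggregates data-source scores (default) or
    data-type scores.
    """

    exponent: float = 2.0
    cap: int = 100
    normalize: bool = True
    overall_from: str = "sources"  # or "types"

    def __post_init__(self):
        if self.exponent <= 0:
            raise ScoringDomainError(f"exponent must be positive, got {self.exponent}")
        if self.cap < 1:
            raise ScoringDomainError(f"cap must be >= 1, got {self.cap}")
        if self.overall_from not in ("sources", "types"):
            raise ScoringDomainError(
                f"overall_from must be 'sources' or 'types', got {self.overall_from!r}"
            )


def harmonic_sum(
    scores: Sequence[float], config: Optional[HarmonicSumConfig] = None
) -> float:
    """Rank-discounted harmonic sum of unit-interval scores.

    Empty input yields 0.  Sorting is on value only, so ties cannot change
    the result and the function is permutation-invariant.
    """
    config = config or HarmonicSumConfig()
    for s in scores:
        if not (0.0 <= s <= 1.0):
            raise ScoringDomainError(f"score outside [0, 1]: {s}")
    if not scores:
        return 0.0
    top = sorted(scores, reverse=True)[: config.cap]
    raw = sum(s / (i**config.exponent) for i, s in enumerate(top, start=1))
    if not config.normalize:
        return raw
    max_sum = sum(1.0 / (i**config.exponent) for i in range(1, len(top) + 1))
    return raw / max_sum


def aggregate(
    evidence: Sequence[EvidenceString],
    registry: Optional[DataSourceRegistry] = None,
    config: Optional[HarmonicSumConfig] = None,
) -> list[AssociationRecord]:
    """Aggregate scored evidence into per-pair association records.

    Evidence is grouped by (target_id, disease_id); within a pair the
    source score is the harmonic sum of that source's evidence scores, the
    type score the harmonic sum of its sources' scores, and the overall
    score the harmonic sum over all data-source scores.  Output is sorted
    lexicographically by (target_id, disease_id) so runs are deterministic.
    """
    registry = registry or DataSourceRegistry.default()
    config = config or HarmonicSumConfig()

    groups: dict[tuple[str, str], dict[str, list[float]]] = {}
    for ev in evidence:
        if ev.score is None:
            raise EvidenceValidationError(
                f"unscored evidence for ({ev.target_id}, {ev.disease_id}) "
                f"from {ev.data_source!r}; run score_evidence first"
            )
        pair = (ev.target_id, ev.disease_id)
        groups.setdefault(pair, {}).setdefault(ev.data_source, []).append(ev.score)

    records: list[AssociationRecord] = []
    for (target_id, disease_id) in sorted(groups):
        by_source = groups[(target_id, disease_id)]
        source_scores = {
            src: harmonic_sum(vals, config) for src, vals in sorted(by_source.items())
        }
        by_type: dict[str, list[float]] = {}
        for src, s in source_scores.items():
            by_type.setdefault(registry.data_type_of(src).value, []).append(s)
        type_scores = {
            t: harmonic_sum(vals, config) for t, vals in sorted(by_type.items())
        }
        if config.overall_from == "sources":
            overall = harmonic_sum(list(source_scores.values()), config)
        else:
            overall = harmonic_sum(list(type_scores.values()), config)
        counts = {src: len(vals) for src, vals in sorted(by_source.items())}
        records.append(
            AssociationRecord(
                target_id=target_id,
                disease_id=disease_id,
                source_scores=source_scores,
                type_scores=type_scores,
                overall=overall,
                evidence_count=counts,
                total_evidence=sum(counts.values()),
            )
        )
    return records


def read_associations(
    stream: Union[str, Path, IO[str], Iterable[str]]
) -> list[AssociationRecord]:
    """Read association records from JSON Lines."""
    if isinstance(stream, (str, Path)):
        with open(stream, "r", encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        lines = list(stream)
    records = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            records.append(AssociationRecord.model_validate(json.loads(line)))
        except (json.JSONDecodeError, pydantic.ValidationError) as exc:
            raise EvidenceValidationError(
                f"line {lineno}: invalid association record ({exc})"
            ) from exc
    return records


def flat_export(
    records: Sequence[AssociationRecord], destination: Union[str, Path]
) -> int:
    """Tab-separated flat export, one row per (pair, data source)."""
    registry = DataSourceRegistry.default()
    n = 0
    with open(destination, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["target_id", "disease_id", "datasource", "datatype", "score", "overall"]
        )
        for rec in records:
            for src, s in rec.source_scores.items():
                dtype = (
                    registry.data_type_of(src).value if src in registry else ""
                )
                writer.writerow(
                    [rec.target_id, rec.disease_id, src, dtype, f"{s:.12g}", f"{rec.overall:.12g}"]
                )
                n += 1
    return n
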