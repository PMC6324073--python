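"""Deterministic synthetic evidence corpora and annotation tables.

Every stage of the pipeline is testable without downloads: this module
generates evidence streams whose payloads are sampled inside each scoring
rule's valid domain, and annotation tables with planted enriched terms.
Planted target-disease pairs are given evidence whose *aggregated* overall
score lands within +-0.05 of a requested value — the planting search runs
through the real scoring and aggregation engines, so it exercises the same
code paths as production data.

A single integer seed drives one explicit numpy Generator; identical
configurations and seeds produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .association_engine import HarmonicSumConfig, aggregate
from .enrichment import AnnotationTable
from .errors import FixtureConfigError, PlantingError
from .evidence_model import (
    DataSourceRegistry,
    EvidencePayload,
    EvidenceString,
    write_evidence,
)
from .source_scoring import DEFAULT_CLINVAR_SCORES, ScoringConfig, score_all

__all__ = ["FixtureConfig", "generate_evidence", "generate_annotations", "write_fixtures"]

#: Pass-through source used to carry planted evidence.
_PLANT_SOURCE = "chembl"
#: Number of evidence strings planted per pair (enough to pass the
#: similarity graph's >= 3 evidence filter on its own).
_PLANT_COUNT = 3


@dataclass(frozen=True)
class FixtureConfig:
    """Synthetic-corpus shape.

    ``sources`` maps a registered data source to the number of background
    evidence records drawn for it; target/disease assignments and payloads
    are sampled uniformly within each rule's valid domain.  ``planted_pairs``
    request specific aggregated overall scores for specific pairs;
    ``planted_enriched_term`` adds one annotation term with exactly the
    stated members.
    """

    n_targets: int = 50
    n_diseases: int = 30
    sources: dict[str, int] = field(
        default_factory=lambda: {
            "phewas_catalog": 60,
            "gwas_catalog": 60,
            "cancer_gene_census": 40,
            "eva": 40,
            "genomics_england": 20,
            "chembl": 40,
            "europepmc": 60,
        }
    )
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    planted_enriched_term: Optional[tuple[str, tuple[str, ...]]] = None
    n_annotation_terms: int = 20
    seed: int = 0

    def target_ids(self) -> list[str]:
        return [f"ENSG{i:011d}" for i in range(1, self.n_targets + 1)]

    def disease_ids(self) -> list[str]:
        return [f"EFO_{i:07d}" for i in range(1, self.n_diseases + 1)]

    def validate(self) -> None:
        if self.n_targets < 1 or self.n_diseases < 1:
            raise FixtureConfigError("need at least one target and one disease")
        targets, diseases = set(self.target_ids()), set(self.disease_ids())
        for t, d, s in self.planted_pairs:
            if t not in targets or d not in diseases:
                raise FixtureConfigError(
                    f"planted pair ({t}, {d}) references out-of-range entities"
                )
            if not (0.0 <= s <= 1.0):
                raise FixtureConfigError(f"planted score outside [0, 1]: {s}")
        if self.planted_enriched_term is not None:
            _, members = self.planted_enriched_term
            stray = set(members) - targets
            if stray:
                raise FixtureConfigError(
                    f"planted term members outside universe: {sorted(stray)[:5]}"
                )


def _sample_payload(rule: str, rng: np.random.Generator) -> EvidencePayload:
    """Payload drawn uniformly inside the rule's valid domain."""
    if rule == "panelapp":
        return EvidencePayload()
    if rule == "phewas":
        return EvidencePayload(
            p_value=float(10.0 ** rng.uniform(-30, 0)),
            n_cases=int(rng.integers(0, 12001)),
        )
    if rule == "pvalue":
        return EvidencePayload(p_value=float(10.0 ** rng.uniform(-30, 0)))
    if rule == "cgc":
        return EvidencePayload(
            tier=int(rng.choice([1, 2])),
            poisson_fdr_disease=float(rng.uniform(0, 1)),
            poisson_fdr_pan=float(rng.uniform(0, 1)),
            n_mutated_samples=int(rng.integers(1, 51)),
            mutation_type=str(rng.choice(["missense", "nonsense", "fusion", "frameshift"])),
            fusion_only=bool(rng.random() < 0.2),
        )
    if rule == "clinvar":
        terms = sorted(DEFAULT_CLINVAR_SCORES)
        return EvidencePayload(clinical_significance=str(rng.choice(terms)))
    # precomputed pass-through sources
    return EvidencePayload(precomputed_score=float(rng.uniform(0, 1)))


def generate_evidence(
    config: FixtureConfig,
    registry: Optional[DataSourceRegistry] = None,
    scoring: Optional[ScoringConfig] = None,
    tolerance: float = 0.05,
) -> list[EvidenceString]:
    """Generate a deterministic evidence corpus with planted associations.

    Background evidence is drawn per source at its configured count over
    uniformly random target-disease pairs.  For each planted pair, three
    pass-through evidence strings sharing a common score s are appended,
    with s chosen by bisection so that the pair's aggregated overall score
    (background included) falls within ``tolerance`` of the request; an
    unreachable request raises :class:`PlantingError`.
    """
    config.validate()
    registry = registry or DataSourceRegistry.default()
    scoring = scoring or ScoringConfig()
    rng = np.random.default_rng(config.seed)
    targets, diseases = config.target_ids(), config.disease_ids()

    # planted pairs are reserved: background never lands on them, so the
    # requested aggregated score is not confounded by random collisions
    reserved = {(t, d) for t, d, _ in config.planted_pairs}
    if len(reserved) >= config.n_targets * config.n_diseases:
        raise FixtureConfigError("planted pairs leave no room for background evidence")

    evidence: list[EvidenceString] = []
    for source in sorted(config.sources):
        count = config.sources[source]
        rule = registry.rule_of(source)
        for _ in range(count):
            while True:
                pair = (str(rng.choice(targets)), str(rng.choice(diseases)))
                if pair not in reserved:
                    break
            evidence.append(
                EvidenceString(
                    target_id=pair[0],
                    disease_id=pair[1],
                    data_source=source,
                    data_type=registry.data_type_of(source),
                    payload=_sample_payload(rule, rng),
                )
            )

    for t, d, requested in config.planted_pairs:
        background = [
            ev for ev in evidence if ev.target_id == t and ev.disease_id == d
        ]
        s = _solve_planted_score(background, t, d, requested, registry, scoring, tolerance)
        for _ in range(_PLANT_COUNT):
            evidence.append(
                EvidenceString(
                    target_id=t,
                    disease_id=d,
                    data_source=_PLANT_SOURCE,
                    data_type=registry.data_type_of(_PLANT_SOURCE),
                    payload=EvidencePayload(precomputed_score=s),
                )
            )
    return evidence


def _overall_with_plant(
    background: list[EvidenceString],
    t: str,
    d: str,
    s: float,
    registry: DataSourceRegistry,
    scoring: ScoringConfig,
) -> float:
    planted = [
        EvidenceString(
            target_id=t,
            disease_id=d,
            data_source=_PLANT_SOURCE,
            data_type=registry.data_type_of(_PLANT_SOURCE),
            payload=EvidencePayload(precomputed_score=s),
        )
        for _ in range(_PLANT_COUNT)
    ]
    scored = score_all(background + planted, registry, scoring)
    records = aggregate(scored, registry, HarmonicSumConfig())
    return records[0].overall


def _solve_planted_score(
    background: list[EvidenceString],
    t: str,
    d: str,
    requested: float,
    registry: DataSourceRegistry,
    scoring: ScoringConfig,
    tolerance: float,
) -> float:
    """Bisect the planted evidence score; overall is monotone in it."""
    lo, hi = 0.0, 1.0
    f_lo = _overall_with_plant(background, t, d, lo, registry, scoring)
    f_hi = _overall_with_plant(background, t, d, hi, registry, scoring)
    if requested < f_lo - tolerance or requested > f_hi + tolerance:
        raise PlantingError(
            f"planted overall {requested} for ({t}, {d}) unreachable: "
            f"attainable range is [{f_lo:.4f}, {f_hi:.4f}] +- {tolerance}"
        )
    for _ in range(50):
        mid = (lo + hi) / 2.0
        if _overall_with_plant(background, t, d, mid, registry, scoring) < requested:
            lo = mid
        else:
            hi = mid
    s = (lo + hi) / 2.0
    achieved = _overall_with_plant(background, t, d, s, registry, scoring)
    if abs(achieved - requested) > tolerance:  # pragma: no cover - guarded above
        raise PlantingError(
            f"planting search for ({t}, {d}) stalled at {achieved:.4f} "
            f"(requested {requested})"
        )
    return s


def generate_annotations(
    config: FixtureConfig, categories: Sequence[str] = ("pathway",)
) -> list[AnnotationTable]:
    """Random term sets over the target universe plus the planted term.

    Term sets are drawn without replacement with sizes uniform in [3, 15]
    (clipped to the universe size); the planted enriched term, when
    configured, is added to every category with exactly its stated members.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from evidence
    universe = config.target_ids()
    tables = []
    for category in categories:
        pairs: list[tuple[str, str]] = []
        for i in range(1, config.n_annotation_terms + 1):
            size = int(rng.integers(3, min(16, config.n_targets + 1)))
            members = rng.choice(universe, size=size, replace=False)
            term = f"{category.upper()}_{i:04d}"
            pairs.extend((term, str(m)) for m in sorted(members))
        if config.planted_enriched_term is not None:
            term, members = config.planted_enriched_term
            pairs.extend((term, m) for m in sorted(members))
        tables.append(
            AnnotationTable.from_pairs(category, pairs, universe=set(universe))
        )
    return tables


def write_fixtures(config: FixtureConfig, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write evidence.jsonl and per-category annotation TSVs; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    evidence = generate_evidence(config)
    ev_path = out / "evidence.jsonl"
    write_evidence(evidence, ev_path)
    paths["evidence"] = ev_path

    for table in generate_annotations(config):
        tsv = out / f"annotations_{table.category}.tsv"
        with open(tsv, "w", encoding="utf-8") as fh:
            for term in sorted(table.sets):
                for gene in sorted(table.sets[term]):
                    fh.write(f"{term}\t{gene}\n")
        paths[table.category] = tsv
    return paths
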