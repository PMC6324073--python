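"""Per-source evidence scoring rules.

Every rule maps a validated evidence record to a score in [0, 1].  The
rules implemented here are the ones with published constants:

* **PanelApp** (Genomics England Green genes): expert-curated diagnostic
  genes always receive the maximum score of 1.
* **PheWAS catalog**: the GWAS-style p-value score, linear in -log10 p
  between p = 0.05 (score 0) and p = 1e-25 (score 1), multiplied by a
  case-count factor min(n_cases / 8800, 1).
* **Cancer Gene Census**: base score 0.5 modified by tier, two Poisson
  mutation-recurrence tests (FDR < 0.025 adds 0.25 each for tier-1 genes),
  a single-mutated-sample penalty of -0.25, and a fusion-only override.
* **ClinVar clinical significance**: a configurable term -> score table
  covering pathogenic, protective, association, risk factor, affects and
  drug response.

Sources without a bespoke rule (drugs, text mining, animal models,
expression, pathway methods) carry a precomputed unit-interval score that
is taken verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import yaml

from .errors import (
    RuleMismatchError,
    ScoringDomainError,
    UnknownTermError,
    UnscorableEvidenceError,
    EvidenceValidationError,
)
from .evidence_model import DataSourceRegistry, EvidenceString

__all__ = [
    "PValueScale",
    "PhewasParams",
    "ClinicalSignificanceMap",
    "ScoringConfig",
    "score_pvalue_linscale",
    "score_phewas",
    "score_panelapp",
    "score_cgc",
    "score_clinvar",
    "score_evidence",
    "score_all",
]


@dataclass(frozen=True)
class PValueScale:
    """P-value -> score mapping boundaries.

    ``p_max`` is the score floor (p >= p_max scores 0) and ``p_min`` the
    ceiling (p <= p_min scores 1); between them the score is linear in
    -log10 p.
    """

    p_max: float = 0.05
    p_min: float = 1e-25

    def __post_init__(self):
        if not (0.0 < self.p_min < self.p_max <= 1.0):
            raise ScoringDomainError(
                f"require 0 < p_min < p_max <= 1, got p_min={self.p_min}, "
                f"p_max={self.p_max}"
            )


@dataclass(frozen=True)
class PhewasParams:
    """PheWAS scaling: p-value scale plus the dataset's maximum case count."""

    scale: PValueScale = field(default_factory=PValueScale)
    max_cases: int = 8800

    def __post_init__(self):
        if self.max_cases <= 0:
            raise ScoringDomainError(f"max_cases must be positive, got {self.max_cases}")


#: Default clinical-significance scores.  ``pathogenic`` anchors the top of
#: the scale; the five newer terms default to the neutral midpoint 0.5.
#: These defaults are configuration, not published constants.
DEFAULT_CLINVAR_SCORES: Mapping[str, float] = {
    "pathogenic": 1.0,
    "likely pathogenic": 1.0,
    "protective": 0.5,
    "association": 0.5,
    "risk factor": 0.5,
    "affects": 0.5,
    "drug response": 0.5,
}

_REQUIRED_CLINVAR_TERMS = frozenset(
    {"pathogenic", "protective", "association", "risk factor", "affects", "drug response"}
)


@dataclass(frozen=True)
class ClinicalSignificanceMap:
    """Clinical-significance term -> unit-interval score table."""

    mapping: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLINVAR_SCORES)
    )

    def __post_init__(self):
        missing = _REQUIRED_CLINVAR_TERMS - set(self.mapping)
        if missing:
            raise ScoringDomainError(
                f"clinical significance map missing terms: {sorted(missing)}"
            )
        for term, s in self.mapping.items():
            if not (0.0 <= s <= 1.0):
                raise ScoringDomainError(f"score for {term!r} outside [0, 1]: {s}")


def score_pvalue_linscale(p: float, scale: Optional[PValueScale] = None) -> float:
    """Score a p-value linearly in -log10 p, clipped to [0, 1].

    p >= ``scale.p_max`` maps to 0 and p <= ``scale.p_min`` to 1; the map
    is monotone non-increasing in p.
    """
    scale = scale or PValueScale()
    if not (0.0 < p <= 1.0):
        raise ScoringDomainError(f"p-value must lie in (0, 1], got {p}")
    lo = -math.log10(scale.p_max)
    hi = -math.log10(scale.p_min)
    raw = (-math.log10(p) - lo) / (hi - lo)
    return min(1.0, max(0.0, raw))


def score_phewas(
    p: float, n_cases: int, params: Optional[PhewasParams] = None
) -> float:
    """PheWAS evidence score: case-count factor times the p-value score."""
    params = params or PhewasParams()
    if n_cases < 0:
        raise ScoringDomainError(f"n_cases must be non-negative, got {n_cases}")
    case_factor = min(n_cases / params.max_cases, 1.0)
    return case_factor * score_pvalue_linscale(p, params.scale)


def score_panelapp(ev: EvidenceString) -> float:
    """Genomics England PanelApp Green genes always score 1.

    The curation itself is the evidence; the score does not depend on the
    disease, provided the disease is ontology-mapped (non-empty).
    """
    if ev.data_source != "genomics_england":
        raise RuleMismatchError(
            f"PanelApp rule applied to source {ev.data_source!r}"
        )
    if not ev.disease_id.strip():
        raise EvidenceValidationError("PanelApp record with unmapped (empty) disease")
    return 1.0


def score_cgc(
    tier: int,
    poisson_fdr_disease: float,
    poisson_fdr_pan: float,
    n_mutated_samples: int,
    mutation_type: str = "",
    fusion_only: bool = False,
    fdr_threshold: float = 0.025,
    fusion_override_first: bool = True,
) -> float:
    """Cancer Gene Census somatic-mutation score.

    All CGC mutations start at a base score of 0.5.  For tier-1 genes each
    of the two Poisson recurrence tests (within-disease and pan-disease)
    with FDR below ``fdr_threshold`` adds 0.25; tier-2 genes stay at 0.5
    regardless.  If a tier-1 gene drives cancer only through fusions, any
    non-fusion mutation type is reset to 0.5 (fusions keep the test
    increments).  If only one sample is mutated, 0.25 is subtracted.  With
    ``fusion_override_first`` (default) the fusion reset is applied before
    the single-sample penalty, so the penalty always bites; the reverse
    order is available for sensitivity checks.  The result is clipped to
    [0, 1].
    """
    if tier not in (1, 2):
        raise ScoringDomainError(f"tier must be 1 or 2, got {tier}")
    if n_mutated_samples < 1:
        raise ScoringDomainError(
            f"n_mutated_samples must be >= 1, got {n_mutated_samples}"
        )
    for name, v in (
        ("poisson_fdr_disease", poisson_fdr_disease),
        ("poisson_fdr_pan", poisson_fdr_pan),
    ):
        if not (0.0 <= v <= 1.0):
            raise ScoringDomainError(f"{name} outside [0, 1]: {v}")

    score = 0.5
    if tier == 1:
        if poisson_fdr_disease < fdr_threshold:
            score += 0.25
        if poisson_fdr_pan < fdr_threshold:
            score += 0.25

    def fusion_override(s: float) -> float:
        if tier == 1 and fusion_only and mutation_type != "fusion":
            return 0.5
        return s

    def single_sample(s: float) -> float:
        return s - 0.25 if n_mutated_samples == 1 else s

    if fusion_override_first:
        score = single_sample(fusion_override(score))
    else:
        score = fusion_override(single_sample(score))
    return min(1.0, max(0.0, score))


def score_clinvar(
    clinical_significance: str,
    significance_map: Optional[ClinicalSignificanceMap] = None,
) -> float:
    """Look up the score for a ClinVar clinical-significance term."""
    significance_map = significance_map or ClinicalSignificanceMap()
    if not clinical_significance or not clinical_significance.strip():
        raise ScoringDomainError("empty clinical significance term")
    term = clinical_significance.strip().lower()
    try:
        return significance_map.mapping[term]
    except KeyError:
        raise UnknownTermError(
            f"clinical significance term {clinical_significance!r} has no "
            f"configured score"
        ) from None


@dataclass(frozen=True)
class ScoringConfig:
    """All scoring-rule parameters, loadable from a YAML file."""

    pvalue_scale: PValueScale = field(default_factory=PValueScale)
    phewas: PhewasParams = field(default_factory=PhewasParams)
    cgc_fdr_threshold: float = 0.025
    cgc_fusion_override_first: bool = True
    clinvar_map: ClinicalSignificanceMap = field(
        default_factory=ClinicalSignificanceMap
    )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ScoringConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        scale_raw = raw.get("pvalue_scale", {})
        scale = PValueScale(
            p_max=float(scale_raw.get("p_max", 0.05)),
            p_min=float(scale_raw.get("p_min", 1e-25)),
        )
        phewas_raw = raw.get("phewas", {})
        phewas = PhewasParams(
            scale=scale, max_cases=int(phewas_raw.get("max_cases", 8800))
        )
        cgc_raw = raw.get("cgc", {})
        clinvar_raw = raw.get("clinvar_map")
        clinvar = (
            ClinicalSignificanceMap(
                {**DEFAULT_CLINVAR_SCORES, **{k.lower(): float(v) for k, v in clinvar_raw.items()}}
            )
            if clinvar_raw
            else ClinicalSignificanceMap()
        )
        return cls(
            pvalue_scale=scale,
            phewas=phewas,
            cgc_fdr_threshold=float(cgc_raw.get("fdr_threshold", 0.025)),
            cgc_fusion_override_first=bool(
                cgc_raw.get("fusion_override_first", True)
            ),
            clinvar_map=clinvar,
        )


def _require(ev: EvidenceString, *fields: str) -> list:
    values = []
    for f in fields:
        v = getattr(ev.payload, f, None)
        if v is None:
            raise EvidenceValidationError(
                f"source {ev.data_source!r} requires payload field {f!r}"
            )
        values.append(v)
    return values


def score_evidence(
    ev: EvidenceString,
    registry: Optional[DataSourceRegistry] = None,
    config: Optional[ScoringConfig] = None,
) -> EvidenceString:
    """Dispatch an evidence record to its source's rule; return a scored copy.

    Sources registered with rule ``"precomputed"`` take
    ``payload.precomputed_score`` verbatim; records with neither a rule nor
    a precomputed score raise :class:`UnscorableEvidenceError`.
    """
    registry = registry or DataSourceRegistry.default()
    config = config or ScoringConfig()
    rule = registry.rule_of(ev.data_source)

    if rule == "panelapp":
        score = score_panelapp(ev)
    elif rule == "phewas":
        p, n_cases = _require(ev, "p_value", "n_cases")
        score = score_phewas(p, n_cases, config.phewas)
    elif rule == "pvalue":
        (p,) = _require(ev, "p_value")
        score = score_pvalue_linscale(p, config.pvalue_scale)
    elif rule == "cgc":
        tier, fdr_d, fdr_p, n_samples = _require(
            ev, "tier", "poisson_fdr_disease", "poisson_fdr_pan", "n_mutated_samples"
        )
        score = score_cgc(
            tier,
            fdr_d,
            fdr_p,
            n_samples,
            mutation_type=ev.payload.mutation_type or "",
            fusion_only=bool(ev.payload.fusion_only),
            fdr_threshold=config.cgc_fdr_threshold,
            fusion_override_first=config.cgc_fusion_override_first,
        )
    elif rule == "clinvar":
        (term,) = _require(ev, "clinical_significance")
        score = score_clinvar(term, config.clinvar_map)
    elif rule == "precomputed":
        if ev.payload.precomputed_score is None:
            raise UnscorableEvidenceError(
                f"source {ev.data_source!r} has no scoring rule and the record "
                f"carries no precomputed_score"
            )
        score = ev.payload.precomputed_score
    else:  # pragma: no cover - registry construction guards this
        raise UnscorableEvidenceError(
            f"source {ev.data_source!r} registered with unknown rule {rule!r}"
        )

    return ev.model_copy(update={"score": score})


def score_all(
    evidence: Sequence[EvidenceString],
    registry: Optional[DataSourceRegistry] = None,
    config: Optional[ScoringConfig] = None,
) -> list[EvidenceString]:
    """Score a whole evidence stream in input order."""
    registry = registry or DataSourceRegistry.default()
    config = config or ScoringConfig()
    return [score_evidence(ev, registry, config) for ev in evidence]
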