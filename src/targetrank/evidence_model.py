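"""Domain types, validation and JSON Lines I/O for evidence and associations.

An *evidence string* is one unit of support linking a drug target (an
Ensembl-style gene identifier) to a disease (an EFO/Orphanet/HP-style
ontology term), contributed by a single data source.  Sources are grouped
into seven data types (genetic associations, somatic mutations, drugs,
affected pathways, RNA expression, animal models, text mining).  Evidence
carries a unit-interval score once a scoring rule has been applied; scored
evidence is aggregated into :class:`AssociationRecord` objects downstream.

The interchange format is JSON Lines: one record per line, snake_case
fields, unknown payload fields preserved for forward compatibility.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Optional, Sequence, Union

import pydantic
from pydantic import BaseModel, ConfigDict, Field

from .errors import (
    EvidenceParseError,
    EvidenceValidationError,
    RegistryError,
)

__all__ = [
    "DataType",
    "EvidencePayload",
    "EvidenceString",
    "DataSourceRegistry",
    "AssociationRecord",
    "read_evidence",
    "write_evidence",
    "write_associations",
    "ID_PREFIXES",
]


class DataType(str, Enum):
    """The seven evidence data types."""

    GENETIC_ASSOCIATION = "genetic_association"
    SOMATIC_MUTATION = "somatic_mutation"
    KNOWN_DRUG = "known_drug"
    AFFECTED_PATHWAY = "affected_pathway"
    RNA_EXPRESSION = "rna_expression"
    ANIMAL_MODEL = "animal_model"
    LITERATURE = "literature"


#: Accepted identifier prefixes under strict validation.
ID_PREFIXES = {
    "target": ("ENSG",),
    "disease": ("EFO_", "Orphanet_", "HP_", "MONDO_", "DOID_"),
}


class EvidencePayload(BaseModel):
    """Source-specific fields consumed by the scoring rules.

    Unknown extra fields are preserved verbatim (``extra="allow"``): readers
    must not reject records from newer producers.
    """

    model_config = ConfigDict(extra="allow")

    p_value: Optional[float] = Field(default=None, gt=0.0, le=1.0)
    n_cases: Optional[int] = Field(default=None, ge=0)
    tier: Optional[int] = None
    n_mutated_samples: Optional[int] = Field(default=None, ge=1)
    poisson_fdr_disease: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    poisson_fdr_pan: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    mutation_type: Optional[str] = None
    fusion_only: Optional[bool] = None
    clinical_significance: Optional[str] = None
    precomputed_score: Optional[float] = Field(default=None, ge=0.0, le=1.0)

    @pydantic.field_validator("tier")
    @classmethod
    def _tier_in_range(cls, v):
        if v is not None and v not in (1, 2):
            raise ValueError("tier must be 1 or 2")
        return v


class EvidenceString(BaseModel):
    """One target-disease evidence record with optional unit-interval score."""

    model_config = ConfigDict(extra="allow")

    target_id: str = Field(min_length=1)
    disease_id: str = Field(min_length=1)
    data_source: str = Field(min_length=1)
    data_type: Optional[DataType] = None
    payload: EvidencePayload = Field(default_factory=EvidencePayload)
    score: Optional[float] = Field(default=None, ge=0.0, le=1.0)

    def validate_identifiers(self, strict: bool = False) -> None:
        """Check identifier shape; under ``strict`` also prefix conventions.

        Identifier syntax is never resolved against live services.
        """
        if not self.target_id.strip():
            raise EvidenceValidationError("empty target_id")
        if not self.disease_id.strip():
            raise EvidenceValidationError("empty disease_id")
        if strict:
            if not self.target_id.startswith(ID_PREFIXES["target"]):
                raise EvidenceValidationError(
                    f"target_id {self.target_id!r} lacks an ENSG prefix"
                )
            if not self.disease_id.startswith(ID_PREFIXES["disease"]):
                raise EvidenceValidationError(
                    f"disease_id {self.disease_id!r} lacks an ontology prefix "
                    f"({'/'.join(ID_PREFIXES['disease'])})"
                )

    def to_json(self) -> str:
        return self.model_dump_json(exclude_none=True)


class DataSourceRegistry:
    """Maps each data source to its data type and scoring-rule identifier.

    Rule identifiers are resolved by :mod:`targetrank.source_scoring`;
    ``"precomputed"`` marks sources whose evidence arrives pre-scored.
    """

    def __init__(self, entries: Mapping[str, tuple[DataType, str]]):
        self.entries: dict[str, tuple[DataType, str]] = dict(entries)

    def __contains__(self, source: str) -> bool:
        return source in self.entries

    def sources(self) -> Sequence[str]:
        return list(self.entries)

    def data_type_of(self, source: str) -> DataType:
        try:
            return self.entries[source][0]
        except KeyError:
            raise RegistryError(f"unknown data source {source!r}") from None

    def rule_of(self, source: str) -> str:
        try:
            return self.entries[source][1]
        except KeyError:
            raise RegistryError(f"unknown data source {source!r}") from None

    @classmethod
    def default(cls) -> "DataSourceRegistry":
        """The platform-style registry of bundled sources."""
        D = DataType
        return cls(
            {
                "genomics_england": (D.GENETIC_ASSOCIATION, "panelapp"),
                "phewas_catalog": (D.GENETIC_ASSOCIATION, "phewas"),
                "gwas_catalog": (D.GENETIC_ASSOCIATION, "pvalue"),
                "eva": (D.GENETIC_ASSOCIATION, "clinvar"),
                "uniprot_literature": (D.GENETIC_ASSOCIATION, "precomputed"),
                "cancer_gene_census": (D.SOMATIC_MUTATION, "cgc"),
                "intogen": (D.SOMATIC_MUTATION, "precomputed"),
                "eva_somatic": (D.SOMATIC_MUTATION, "clinvar"),
                "chembl": (D.KNOWN_DRUG, "precomputed"),
                "slapenrich": (D.AFFECTED_PATHWAY, "precomputed"),
                "progeny": (D.AFFECTED_PATHWAY, "precomputed"),
                "reactome": (D.AFFECTED_PATHWAY, "precomputed"),
                "expression_atlas": (D.RNA_EXPRESSION, "precomputed"),
                "phenodigm": (D.ANIMAL_MODEL, "precomputed"),
                "europepmc": (D.LITERATURE, "precomputed"),
            }
        )


class AssociationRecord(BaseModel):
    """Per-source, per-type and overall harmonic-sum scores for one pair."""

    target_id: str = Field(min_length=1)
    disease_id: str = Field(min_length=1)
    source_scores: dict[str, float] = Field(default_factory=dict)
    type_scores: dict[str, float] = Field(default_factory=dict)
    overall: float = Field(ge=0.0, le=1.0)
    evidence_count: dict[str, int] = Field(default_factory=dict)
    total_evidence: int = Field(ge=1)

    @pydantic.field_validator("source_scores", "type_scores")
    @classmethod
    def _unit_interval(cls, v):
        for key, s in v.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"score for {key!r} outside [0, 1]: {s}")
        return v

    def to_json(self) -> str:
        return self.model_dump_json()


# ---------------------------------------------------------------------------
# JSON Lines I/O


def _iter_lines(stream: Union[str, Path, IO[str], Iterable[str]]) -> Iterator[str]:
    if isinstance(stream, (str, Path)):
        with open(stream, "r", encoding="utf-8") as fh:
            yield from fh
    else:
        yield from stream


def read_evidence(
    stream: Union[str, Path, IO[str], Iterable[str]],
    registry: Optional[DataSourceRegistry] = None,
    strict: bool = False,
) -> list[EvidenceString]:
    """Read a JSON Lines evidence stream, validating against the registry.

    Records are returned in input order.  A malformed line raises
    :class:`EvidenceParseError` with its 1-based line number; an unknown
    ``data_source`` raises :class:`RegistryError`; field-level failures
    raise :class:`EvidenceValidationError` naming the offending field.
    A missing ``data_type`` is filled in from the registry; a present one
    must agree with it.
    """
    registry = registry or DataSourceRegistry.default()
    records: list[EvidenceString] = []
    for lineno, line in enumerate(_iter_lines(stream), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            raw = json.loads(line)
        except json.JSONDecodeError as exc:
            raise EvidenceParseError(lineno, f"invalid JSON ({exc.msg})") from exc
        try:
            ev = EvidenceString.model_validate(raw)
        except pydantic.ValidationError as exc:
            fields = ", ".join(
                ".".join(str(p) for p in err["loc"]) or "<record>"
                for err in exc.errors()
            )
            raise EvidenceValidationError(
                f"line {lineno}: invalid field(s): {fields}"
            ) from exc
        if ev.data_source not in registry:
            raise RegistryError(
                f"line {lineno}: data source {ev.data_source!r} not in registry"
            )
        expected = registry.data_type_of(ev.data_source)
        if ev.data_type is None:
            ev.data_type = expected
        elif ev.data_type != expected:
            raise RegistryError(
                f"line {lineno}: data_type {ev.data_type.value!r} does not match "
                f"registry type {expected.value!r} for {ev.data_source!r}"
            )
        ev.validate_identifiers(strict=strict)
        records.append(ev)
    return records


def write_evidence(
    records: Sequence[EvidenceString], destination: Union[str, Path, IO[str]]
) -> int:
    """Write evidence as JSON Lines; returns the number of rows written."""
    return _write_jsonl((r.to_json() for r in records), destination)


def write_associations(
    records: Sequence[AssociationRecord],
    destination: Union[str, Path, IO[str]],
    flat: Optional[Union[str, Path]] = None,
) -> int:
    """Write association records as JSON Lines, plus an optional flat TSV.

    The flat export has one row per (pair, data source) with columns
    ``target_id, disease_id, datasource, datatype, score, overall``.
    Returns the number of JSON Lines rows written.
    """
    n = _write_jsonl((r.to_json() for r in records), destination)
    if flat is not None:
        from .association_engine import flat_export  # local: avoid cycle at import

        flat_export(records, flat)
    return n


def _write_jsonl(
    rows: Iterable[str], destination: Union[str, Path, IO[str]]
) -> int:
    count = 0

    def _emit(fh: IO[str]) -> None:
        nonlocal count
        for row in rows:
            fh.write(row)
            fh.write("\n")
            count += 1

    if isinstance(destination, (str, Path)):
        with open(destination, "w", encoding="utf-8") as fh:
            _emit(fh)
    else:
        _emit(destination)
    return count
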