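import pytest
from hypothesis import HealthCheck, settings

from targetrank import DataSourceRegistry, EvidencePayload, EvidenceString

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def registry():
    return DataSourceRegistry.default()


def make_evidence(source="chembl", target="ENSG00000000001", disease="EFO_0000001", **payload):
    return EvidenceString(
        target_id=target,
        disease_id=disease,
        data_source=source,
        payload=EvidencePayload(**payload),
    )


@pytest.fixture
def evidence_factory():
    return make_evidence
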