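import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from phenonote.documents import KnowledgeDictionary, DictionaryEntry  # noqa: E402


@pytest.fixture
def toy_drug_dict() -> KnowledgeDictionary:
    return KnowledgeDictionary(
        [
            DictionaryEntry("N02BE01", "paracetamol", "fr", "ATC"),
            DictionaryEntry("M01AE01", "ibuprofene", "fr", "ATC"),
            DictionaryEntry("P01BA02", "hydroxychloroquine", "fr", "ATC"),
        ]
    )
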