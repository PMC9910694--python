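import pytest
from hypothesis import HealthCheck, settings

from amrcodes import Catalog, CatalogRecord, paper_registry

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


#: The six cardiovascular rows of the published condensed coding table:
#: canonical code -> (disease path, species path, modeling path, attribute digits).
TABLE4 = {
    "CSTR09:A0101B1111001C01D122": (
        ("cardiovascular disease", "myocarditis"),
        ("laboratory animal", "mouse", "BALB/c"),
        ("spontaneous",),
        "122",  # independent, free, frozen
    ),
    "CSTR09:A0101B1111001C01D312": (
        ("cardiovascular disease", "myocarditis"),
        ("laboratory animal", "mouse", "BALB/c"),
        ("spontaneous",),
        "312",  # outsourcing, paid, frozen
    ),
    "CSTR09:A0102B1127001C01D121": (
        ("cardiovascular disease", "pericarditis"),
        ("laboratory animal", "rabbit", "New Zealand"),
        ("spontaneous",),
        "121",  # independent, free, live
    ),
    "CSTR09:A0102B1127001C01D322": (
        ("cardiovascular disease", "pericarditis"),
        ("laboratory animal", "rabbit", "New Zealand"),
        ("spontaneous",),
        "322",  # outsourcing, free, frozen
    ),
    "CSTR09:A0103B1111001C02D121": (
        ("cardiovascular disease", "myocardial infarction"),
        ("laboratory animal", "mouse", "BALB/c"),
        ("induced",),
        "121",  # independent, free, live
    ),
    "CSTR09:A0103B1111001C02D311": (
        ("cardiovascular disease", "myocardial infarction"),
        ("laboratory animal", "mouse", "BALB/c"),
        ("induced",),
        "311",  # outsourcing, paid, live
    ),
}


@pytest.fixture(scope="session")
def registry():
    return paper_registry()


@pytest.fixture(scope="session")
def table4_catalog(registry):
    records = [
        CatalogRecord(record_id=f"T{i}", code=code, metadata={"name": f"model {i}"})
        for i, code in enumerate(sorted(TABLE4), start=1)
    ]
    return Catalog(records, registry=registry)
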