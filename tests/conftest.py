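import pytest

from aneurysmorph import AneurysmRecord, CohortTable


@pytest.fixture
def record():
    """The hand-worked reference aneurysm: h=w=10, d1=d2=4, r=1.5 mm."""
    return AneurysmRecord(
        id="ref", h=10.0, w=10.0, d1=4.0, d2=4.0, r=1.5,
        site="BT", ruptured=True, modality="CTA",
    )


@pytest.fixture
def small_cohort():
    """Six records, both rupture classes, all three sites, mixed sphericity."""
    recs = [
        AneurysmRecord(id="a1", h=5.0, w=4.5, d1=3.0, d2=2.5, r=1.5, site="BT",
                       ruptured=True, modality="CTA", smoking=True),
        AneurysmRecord(id="a2", h=6.0, w=6.2, d1=3.5, d2=3.0, r=1.2, site="Acom",
                       ruptured=False, modality="MRA", hypertension=False),
        AneurysmRecord(id="a3", h=4.0, w=4.4, d1=2.0, d2=1.8, r=1.0, site="Pcom",
                       ruptured=True, modality="DSA"),
        AneurysmRecord(id="a4", h=8.0, w=7.0, d1=4.0, d2=4.0, r=1.8, site="BT",
                       ruptured=False, modality="CTA", smoking=False, hypertension=True),
        AneurysmRecord(id="a5", h=10.0, w=6.0, d1=5.0, d2=4.0, r=2.0, site="BT",
                       ruptured=False, modality="CTA"),  # sphericity 0.25 -> screened out
        AneurysmRecord(id="a6", h=7.0, w=6.5, d1=3.2, d2=3.0, r=1.4, site="Acom",
                       ruptured=True, modality="MRA"),
    ]
    return CohortTable(records=recs, provenance="conftest fixture")
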