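import datetime as dt

import pytest

from kolrank.models import (
    AcademicTitle,
    Corpus,
    DiseaseCategory,
    DoctorRecord,
    Hospital,
    HospitalLevel,
    ProfessionalTitle,
    Publication,
    ReviewLog,
    SeedLabel,
)
from kolrank.synthetic import SyntheticConfig, generate_corpus


def make_doctor(i, **kw):
    defaults = dict(
        doctor_id=f"d{i}",
        name=f"li wei{i}",
        hospital_id="h1",
        specialty="gynecology",
        years_active=10.0 + i,
        academic_title=AcademicTitle.associate_professor,
        professional_title=ProfessionalTitle.chief_physician,
        social_fans=100 * (i + 1),
        source_id="registry",
        source_date=dt.date(2016, 1, 1),
    )
    defaults.update(kw)
    return DoctorRecord(**defaults)


@pytest.fixture
def small_corpus():
    """Three doctors, two hospitals, three publications, reviews and seeds
    for one disease category."""
    hospitals = [
        Hospital(
            hospital_id="h1",
            canonical_name="Union Medical College Hospital",
            aliases={"pumch"},
            level=HospitalLevel.GIII_A,
        ),
        Hospital(
            hospital_id="h2",
            canonical_name="City Second Hospital",
            aliases={"csh"},
            level=HospitalLevel.GI_C,
        ),
    ]
    doctors = [
        make_doctor(1, name="li wei", social_fans=20),
        make_doctor(2, name="zhang min", social_fans=100),
        make_doctor(3, name="wang fang", hospital_id="h2", social_fans=None,
                    academic_title=AcademicTitle.none,
                    professional_title=ProfessionalTitle.physician),
    ]
    pubs = [
        Publication(pub_id="p1", journal="j", pub_date=dt.date(2010, 1, 1),
                    author_ids=["d1", "d2"], raw_author_names=["li wei", "zhang min"],
                    categories={"c1"}, cites={"p2"}),
        Publication(pub_id="p2", journal="j", pub_date=dt.date(2011, 1, 1),
                    author_ids=["d1"], raw_author_names=["li wei"],
                    categories={"c1"}),
        Publication(pub_id="p3", journal="j", pub_date=dt.date(2012, 1, 1),
                    author_ids=["d2", "d3"], raw_author_names=["zhang min", "wang fang"],
                    categories={"c2"}),
    ]
    reviews = [
        ReviewLog(doctor_id="d1", disease_id="c1", level=8, timestamp=dt.date(2015, 11, 2)),
        ReviewLog(doctor_id="d1", disease_id="c1", level=9, timestamp=dt.date(2015, 11, 3)),
        ReviewLog(doctor_id="d1", disease_id="c1", level=1, timestamp=dt.date(2015, 11, 4)),
        ReviewLog(doctor_id="d2", disease_id="c1", level=9, timestamp=dt.date(2015, 11, 5)),
    ]
    return Corpus(
        doctors=doctors,
        hospitals=hospitals,
        publications=pubs,
        reviews=reviews,
        categories=[DiseaseCategory(category_id="c1", name="adenomyosis"),
                    DiseaseCategory(category_id="c2", name="ovarian cyst")],
        seed_labels=[SeedLabel(doctor_id="d1", category_id="c1", value=1.0)],
    )


@pytest.fixture(scope="session")
def default_corpus():
    """Default study conditions: 200 doctors, 5 categories, default noise."""
    return generate_corpus(SyntheticConfig(rng_seed=1))


@pytest.fixture(scope="session")
def zero_noise_corpus():
    """Degenerate deterministic world: every feature is an exact monotone
    transform of a single per-doctor skill."""
    return generate_corpus(SyntheticConfig.zero_noise(rng_seed=3))
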