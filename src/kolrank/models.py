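"""Domain types for the doctor-ranking corpus.

The unit of analysis is a doctor; doctors are ranked per disease category
from profile, expertise, and social-trust signals.  Records are validated
pydantic models so that malformed rows coming from flat files fail loudly
with row context attached by the readers.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator


class AcademicTitle(str, enum.Enum):
    none = "none"
    assistant_professor = "assistant_professor"
    associate_professor = "associate_professor"
    full_professor = "full_professor"


class ProfessionalTitle(str, enum.Enum):
    none = "none"
    physician = "physician"
    resident_physician = "resident_physician"
    physician_in_charge = "physician_in_charge"
    associate_chief_physician = "associate_chief_physician"
    chief_physician = "chief_physician"


class HospitalLevel(str, enum.Enum):
    """Chinese 3x3 hospital accreditation scale.

    Grade III class A (GIII-A) is the highest level, grade I class C (GI-C)
    the lowest.  Enum order is the total order used for scoring: grade
    dominates class.
    """

    GI_C = "GI-C"
    GI_B = "GI-B"
    GI_A = "GI-A"
    GII_C = "GII-C"
    GII_B = "GII-B"
    GII_A = "GII-A"
    GIII_C = "GIII-C"
    GIII_B = "GIII-B"
    GIII_A = "GIII-A"


#: Senior professional titles (chief / associate chief physician).
SENIOR_TITLES = frozenset(
    {ProfessionalTitle.chief_physician, ProfessionalTitle.associate_chief_physician}
)


class DoctorRecord(BaseModel):
    doctor_id: str
    name: str
    hospital_id: str
    specialty: str
    years_active: float = Field(ge=0)
    academic_title: AcademicTitle = AcademicTitle.none
    professional_title: ProfessionalTitle = ProfessionalTitle.none
    #: ``None`` means the doctor has no social-network presence at all,
    #: which is distinct from an account with 0 fans.
    social_fans: Optional[int] = Field(default=None, ge=0)
    source_id: str = "default"
    source_date: dt.date = dt.date(1970, 1, 1)


class Hospital(BaseModel):
    hospital_id: str
    canonical_name: str
    aliases: set[str] = set()
    level: HospitalLevel

    @model_validator(mode="after")
    def _canonical_in_aliases(self) -> "Hospital":
        self.aliases = set(self.aliases) | {self.canonical_name}
        return self


class Publication(BaseModel):
    pub_id: str
    journal: str = ""
    pub_date: dt.date = dt.date(1970, 1, 1)
    author_ids: list[str] = []
    raw_author_names: list[str] = []
    #: Optional affiliation hint per raw author name (parallel list).
    raw_author_affiliations: Optional[list[str]] = None
    categories: set[str] = set()
    cites: set[str] = set()

    @field_validator("author_ids")
    @classmethod
    def _no_duplicate_authors(cls, v: list[str]) -> list[str]:
        if len(v) != len(set(v)):
            raise ValueError("author_ids contains duplicates")
        return v

    @model_validator(mode="after")
    def _no_self_citation(self) -> "Publication":
        if self.pub_id in self.cites:
            raise ValueError(f"publication {self.pub_id} cites itself")
        return self


class ReviewLog(BaseModel):
    doctor_id: str
    disease_id: str
    level: int = Field(ge=1, le=9)
    timestamp: dt.date = dt.date(1970, 1, 1)


class DiseaseCategory(BaseModel):
    category_id: str
    name: str = ""


class SeedLabel(BaseModel):
    """A manually assigned expertise label used to seed propagation.

    ``value`` is 1 for a doctor considered perfect at treating the
    category, 0 for one completely unable to treat it.
    """

    doctor_id: str
    category_id: str
    value: float = Field(ge=0, le=1)


@dataclass
class Corpus:
    """In-memory bundle of all entity tables."""

    doctors: list[DoctorRecord] = field(default_factory=list)
    hospitals: list[Hospital] = field(default_factory=list)
    publications: list[Publication] = field(default_factory=list)
    reviews: list[ReviewLog] = field(default_factory=list)
    categories: list[DiseaseCategory] = field(default_factory=list)
    seed_labels: list[SeedLabel] = field(default_factory=list)

    def doctor_index(self) -> dict[str, DoctorRecord]:
        return {d.doctor_id: d for d in self.doctors}

    def hospital_index(self) -> dict[str, Hospital]:
        return {h.hospital_id: h for h in self.hospitals}

    @property
    def doctor_ids(self) -> list[str]:
        return [d.doctor_id for d in self.doctors]

    @property
    def category_ids(self) -> list[str]:
        return [c.category_id for c in self.categories]


class SchemaError(ValueError):
    """A required column is missing or a file does not match the schema."""


class ValidationFailure(ValueError):
    """A row holds a value outside its domain (bad enum, bad range...)."""


class ConfigurationError(ValueError):
    """Inconsistent configuration (e.g. overlapping hospital aliases)."""
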