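"""The ten ranking features and their assembly into a per-category matrix.

Feature groups:

* profile — working years, academic title, professional title, hospital
  level (ordinal encodings of the doctor's resume);
* expertise — publication count in the category, mean patient review
  level, propagated expertise-label score;
* social trust — distinct coauthors in the category, cited publications
  in the category, and a logarithmic social-recognition score of the
  follower count.

Columns are kept in one fixed documented order so serialized matrices
and learned weight vectors line up across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .labels import LabelMatrix
from .models import (
    AcademicTitle,
    Corpus,
    DoctorRecord,
    HospitalLevel,
    ProfessionalTitle,
    Publication,
    ReviewLog,
    ValidationFailure,
)

#: Fixed column order of every FeatureMatrix.
FEATURE_NAMES = [
    "professional_duration",
    "academic_title",
    "professional_title",
    "hospital_level",
    "publication_count",
    "patient_rating",
    "expertise_label",
    "coauthorship",
    "citation",
    "social_recognition",
]

_ACADEMIC_SCORE = {t: i for i, t in enumerate(AcademicTitle)}
_PROFESSIONAL_SCORE = {t: i for i, t in enumerate(ProfessionalTitle)}
# grade dominates class: GI-C=1 < ... < GIII-A=9
_HOSPITAL_SCORE = {lvl: i + 1 for i, lvl in enumerate(HospitalLevel)}


def encode_academic_title(title: AcademicTitle) -> int:
    """none=0, assistant=1, associate=2, full professor=3."""
    return _ACADEMIC_SCORE[AcademicTitle(title)]


def encode_professional_title(title: ProfessionalTitle) -> int:
    """Ordinal 0..5 from none up to chief physician."""
    return _PROFESSIONAL_SCORE[ProfessionalTitle(title)]


def encode_hospital_level(level: HospitalLevel) -> int:
    """Ordinal 1..9; grade III class A is the highest level and grade I
    class C the lowest."""
    return _HOSPITAL_SCORE[HospitalLevel(level)]


def social_recognition(fans: Optional[int]) -> int:
    """Logarithmic follower-count score.

    No social network (``None``) or zero fans scores 0; otherwise
    floor(log10(fans)) + 1, so 20 fans score 2, 100 fans score 3, and so
    on by decade.
    """
    if fans is None:
        return 0
    if fans < 0:
        raise ValidationFailure(f"negative fan count: {fans}")
    if fans == 0:
        return 0
    return int(math.floor(math.log10(fans))) + 1


def _pubs_of(doctor_id: str, category_id: str, publications: Sequence[Publication]):
    return [
        p
        for p in publications
        if doctor_id in p.author_ids and category_id in p.categories
    ]


def publication_count(
    doctor_id: str, category_id: str, publications: Sequence[Publication]
) -> int:
    """Number of the doctor's publications in the category."""
    return len(_pubs_of(doctor_id, category_id, publications))


def patient_rating(
    doctor_id: str, category_id: str, reviews: Sequence[ReviewLog]
) -> float:
    """Mean review level for the (doctor, category) pair; 0 when the
    doctor has no reviews there."""
    levels = [
        r.level for r in reviews if r.doctor_id == doctor_id and r.disease_id == category_id
    ]
    return float(np.mean(levels)) if levels else 0.0


def coauthorship_score(
    doctor_id: str, category_id: str, publications: Sequence[Publication]
) -> int:
    """Distinct coauthors over the doctor's publications in the category."""
    partners: set[str] = set()
    for p in _pubs_of(doctor_id, category_id, publications):
        partners.update(a for a in p.author_ids if a != doctor_id)
    return len(partners)


def citation_score(
    doctor_id: str,
    category_id: str,
    publications: Sequence[Publication],
    mode: str = "cited_pub_count",
) -> int:
    """Citation feature from in-corpus citation links.

    ``cited_pub_count`` (default): number of the doctor's publications in
    the category that receive at least one citation.  ``total_citations``:
    sum of citation counts over those publications.
    """
    if mode not in ("cited_pub_count", "total_citations"):
        raise ValidationFailure(f"unknown citation mode {mode!r}")
    counts: dict[str, int] = {}
    for p in publications:
        for cited in p.cites:
            counts[cited] = counts.get(cited, 0) + 1
    mine = _pubs_of(doctor_id, category_id, publications)
    if mode == "cited_pub_count":
        return sum(1 for p in mine if counts.get(p.pub_id, 0) > 0)
    return sum(counts.get(p.pub_id, 0) for p in mine)


def expertise_label_score(
    doctor_id: str, category_id: str, labels: LabelMatrix
) -> float:
    """Propagated expertise-label score in [0, 1] (matrix lookup)."""
    return labels.lookup(doctor_id, category_id)


def professional_duration(doctor: DoctorRecord) -> float:
    return float(doctor.years_active)


@dataclass
class FeatureMatrix:
    """Doctors x features scores for one disease category."""

    category_id: str
    doctor_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.doctor_ids), len(self.feature_names)):
            raise ValueError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.doctor_ids)} doctors x {len(self.feature_names)} features"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.doctor_ids, name="doctor_id"),
            columns=self.feature_names,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def build_feature_matrix(
    corpus: Corpus,
    category_id: str,
    labels: LabelMatrix,
    citation_mode: str = "cited_pub_count",
) -> FeatureMatrix:
    """Assemble the unnormalized 10-column feature matrix for a category.

    The corpus is assumed deduplicated with authors matched and labels
    propagated.  Index-based passes over publications and reviews keep
    this linear in corpus size (the per-cell operations above are the
    specification; this is their batched equivalent).
    """
    doctor_ids = corpus.doctor_ids
    row = {d: i for i, d in enumerate(doctor_ids)}
    n = len(doctor_ids)
    m = np.zeros((n, len(FEATURE_NAMES)))

    cite_counts: dict[str, int] = {}
    for p in corpus.publications:
        for cited in p.cites:
            cite_counts[cited] = cite_counts.get(cited, 0) + 1

    pub_n = np.zeros(n)
    cite_n = np.zeros(n)
    partners: list[set[str]] = [set() for _ in range(n)]
    for p in corpus.publications:
        if category_id not in p.categories:
            continue
        for a in p.author_ids:
            i = row.get(a)
            if i is None:
                continue
            pub_n[i] += 1
            partners[i].update(b for b in p.author_ids if b != a)
            c = cite_counts.get(p.pub_id, 0)
            if citation_mode == "cited_pub_count":
                cite_n[i] += 1 if c > 0 else 0
            elif citation_mode == "total_citations":
                cite_n[i] += c
            else:
                raise ValidationFailure(f"unknown citation mode {citation_mode!r}")

    level_sum = np.zeros(n)
    level_cnt = np.zeros(n)
    for r in corpus.reviews:
        if r.disease_id != category_id:
            continue
        i = row.get(r.doctor_id)
        if i is None:
            continue
        level_sum[i] += r.level
        level_cnt[i] += 1
    rating = np.divide(level_sum, level_cnt, out=np.zeros(n), where=level_cnt > 0)

    hospitals = corpus.hospital_index()
    for i, d in enumerate(corpus.doctors):
        m[i, 0] = professional_duration(d)
        m[i, 1] = encode_academic_title(d.academic_title)
        m[i, 2] = encode_professional_title(d.professional_title)
        m[i, 3] = encode_hospital_level(hospitals[d.hospital_id].level)
        m[i, 4] = pub_n[i]
        m[i, 5] = rating[i]
        m[i, 6] = expertise_label_score(d.doctor_id, category_id, labels)
        m[i, 7] = len(partners[i])
        m[i, 8] = cite_n[i]
        m[i, 9] = social_recognition(d.social_fans)

    return FeatureMatrix(
        category_id=category_id,
        doctor_ids=list(doctor_ids),
        feature_names=list(FEATURE_NAMES),
        values=m,
        normalized=False,
    )


def znormalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Column-wise z-scores with the population standard deviation.

    Columns with zero spread map to all-zeros rather than raising, so
    degenerate features quietly drop out of the linear score.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    v = matrix.values
    mean = v.mean(axis=0)
    sd = v.std(axis=0)  # population (ddof=0)
    out = np.zeros_like(v)
    nz = sd > 0
    out[:, nz] = (v[:, nz] - mean[nz]) / sd[nz]
    return FeatureMatrix(
        category_id=matrix.category_id,
        doctor_ids=list(matrix.doctor_ids),
        feature_names=list(matrix.feature_names),
        values=out,
        normalized=True,
    )
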