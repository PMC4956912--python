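"""Synthetic health-care corpora with planted per-category expertise.

The generator emulates the qualitative structure of a large multi-source
doctor corpus: bimodal patient-review levels (mass at levels 8–9 and at
level 1), heavy-tailed social-follower counts with a few "star" doctors,
quality-assortative coauthorship communities per disease category, and
profile fields (titles, hospital level, working years) positively
associated with a latent quality.  Every observable is a noisy monotone
transform of the planted quality, so downstream feature extraction,
label propagation, aggregation and evaluation can all be scored against
an exact ground truth.

With every noise parameter at zero (``SyntheticConfig.zero_noise()``)
the corpus degenerates to a fully deterministic world in which each of
the ten ranking features is an exact non-decreasing transform of quality
(working years strictly increasing); this is the regime in which perfect
recovery of the planted ranking is expected.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .models import (
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

_FAMILY = [
    "li", "wang", "zhang", "liu", "chen", "yang", "zhao", "huang", "zhou",
    "wu", "xu", "sun", "hu", "zhu", "gao", "lin", "he", "guo", "ma", "luo",
]
_GIVEN = [
    "wei", "fang", "na", "min", "jing", "lei", "qiang", "jun", "yang", "yan",
    "tao", "ming", "chao", "juan", "xia", "ping", "hua", "hong", "bin", "mei",
]
_SPECIALTIES = [
    "gynecology", "cardiology", "oncology", "neurology", "endocrinology",
    "dermatology", "orthopedics", "pediatrics",
]
_DISEASES = [
    "adenomyosis", "ovarian cyst", "vaginitis", "menoxenia", "cervicitis",
    "hypertension", "arrhythmia", "migraine", "diabetes", "eczema",
]
_JOURNALS = [
    "Chinese Journal of Clinical Medicine", "Journal of Practical Gynecology",
    "National Medical Frontiers", "Chinese Hospital Review",
]

#: Default per-observable noise standard deviations (on the quality scale,
#: which lives in [0, 1]).
DEFAULT_NOISE = {
    "years": 0.15,
    "academic_title": 0.15,
    "professional_title": 0.15,
    "hospital_level": 0.2,
    "publications": 0.25,
    "review_level": 0.15,
    "review_volume": 0.5,
    "fans": 0.5,
    "star": 0.5,
}

_LEVELS = list(HospitalLevel)  # ordered GI-C .. GIII-A


class SyntheticConfig(BaseModel):
    n_doctors: int = Field(default=200, ge=1)
    n_categories: int = Field(default=5, ge=1)
    n_publications: int = Field(default=600, ge=1)
    n_hospitals: int = Field(default=20, ge=1)
    #: Fraction of doctors emitting a seed expertise label (their top
    #: category, value 1).
    seed_fraction: float = Field(default=0.2, gt=0, le=1)
    #: Mean number of patient reviews per doctor.
    review_rate: float = Field(default=5.0, ge=0)
    noise_levels: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_NOISE))
    star_fraction: float = Field(default=0.02, ge=0, le=1)
    duplicate_rate: float = Field(default=0.0, ge=0, le=1)
    rng_seed: int = 0
    #: Weight of the category-specific quality component; 0 collapses all
    #: categories onto a single per-doctor skill.
    category_spread: float = Field(default=0.5, ge=0, le=1)
    #: Emit an exact seed label for every (doctor, category) pair instead
    #: of sparse top-category seeds.
    full_seed_matrix: bool = False
    #: Size of the per-category planted KOL set.
    n_kol: int = Field(default=30, ge=1)
    #: Quantile of per-doctor authorship counts above which papers are
    #: cited (citations concentrate on high-quality doctors' papers).
    cite_quantile: float = Field(default=0.5, ge=0, le=1)

    @field_validator("noise_levels")
    @classmethod
    def _nonnegative_noise(cls, v: dict[str, float]) -> dict[str, float]:
        merged = dict(DEFAULT_NOISE)
        merged.update(v)
        bad = {k: s for k, s in merged.items() if s < 0}
        if bad:
            raise ValueError(f"negative noise levels: {bad}")
        return merged

    @model_validator(mode="after")
    def _feasible(self) -> "SyntheticConfig":
        if round(self.seed_fraction * self.n_doctors) > self.n_doctors:
            raise ValueError("more seed doctors than doctors")
        return self

    @classmethod
    def zero_noise(cls, **overrides) -> "SyntheticConfig":
        """Fully deterministic configuration: every observable is an exact
        monotone transform of a single per-doctor skill."""
        defaults = dict(
            noise_levels={k: 0.0 for k in DEFAULT_NOISE},
            category_spread=0.0,
            full_seed_matrix=True,
            seed_fraction=1.0,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class PlantedTruth:
    """Latent expertise and the implied per-category KOL sets."""

    doctor_ids: list[str]
    category_ids: list[str]
    quality: np.ndarray  # doctors x categories, in [0, 1]
    kol_set: dict[str, list[str]]

    def quality_of(self, doctor_id: str, category_id: str) -> float:
        return float(
            self.quality[
                self.doctor_ids.index(doctor_id), self.category_ids.index(category_id)
            ]
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "doctor_ids": self.doctor_ids,
                    "category_ids": self.category_ids,
                    "quality": self.quality.tolist(),
                    "kol_set": self.kol_set,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            doctor_ids=d["doctor_ids"],
            category_ids=d["category_ids"],
            quality=np.asarray(d["quality"], dtype=float),
            kol_set={k: list(v) for k, v in d["kol_set"].items()},
        )


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def _top_k_by_quality(
    quality_col: np.ndarray, doctor_ids: list[str], k: int
) -> list[str]:
    """argmax-k with deterministic tie-break by doctor_id."""
    order = sorted(range(len(doctor_ids)), key=lambda i: (-quality_col[i], doctor_ids[i]))
    return [doctor_ids[i] for i in order[:k]]


def _pack_blocks(counts: dict[str, int], quality: dict[str, float]) -> list[list[str]]:
    """Materialize per-doctor authorship counts as papers of <= 3 authors.

    Doctors are sorted by (count desc, quality desc, id) and packed in
    consecutive blocks of three; a block with counts A >= B >= C yields C
    three-author papers, B-C two-author papers and A-B solo papers, so
    every doctor appears in exactly ``counts[d]`` papers.
    """
    active = [d for d, a in counts.items() if a > 0]
    active.sort(key=lambda d: (-counts[d], -quality[d], d))
    papers: list[list[str]] = []
    for start in range(0, len(active), 3):
        block = active[start : start + 3]
        a = [counts[d] for d in block]
        if len(block) == 3:
            papers += [list(block)] * a[2]
            papers += [[block[0], block[1]]] * (a[1] - a[2])
            papers += [[block[0]]] * (a[0] - a[1])
        elif len(block) == 2:
            papers += [list(block)] * a[1]
            papers += [[block[0]]] * (a[0] - a[1])
        else:
            papers += [[block[0]]] * a[0]
    return papers


def generate_corpus(config: SyntheticConfig) -> tuple[Corpus, PlantedTruth]:
    """Generate a corpus with planted truth; deterministic given
    ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    noise = config.noise_levels
    n, n_cat = config.n_doctors, config.n_categories

    doctor_ids = [f"d{i:05d}" for i in range(n)]
    category_ids = [f"c{j:02d}" for j in range(n_cat)]

    # --- latent quality -----------------------------------------------------
    skill = rng.beta(2.0, 2.0, size=n)
    z = rng.beta(2.0, 2.0, size=(n, n_cat))
    quality = (1 - config.category_spread) * skill[:, None] + config.category_spread * z

    kol_k = min(config.n_kol, n)
    kol_set = {
        category_ids[j]: _top_k_by_quality(quality[:, j], doctor_ids, kol_k)
        for j in range(n_cat)
    }
    truth = PlantedTruth(doctor_ids, category_ids, quality, kol_set)

    # --- hospitals ----------------------------------------------------------
    nh = config.n_hospitals
    hospitals = []
    for i in range(nh):
        level = _LEVELS[(i * 9) // nh]
        name = f"General Hospital {i:03d}"
        hospitals.append(
            Hospital(
                hospital_id=f"h{i:03d}",
                canonical_name=name,
                aliases={name, f"gh{i:03d}", f"hospital {i:03d}"},
                level=level,
            )
        )
    # doctors sort into hospitals by (noisy) skill quantile; hospital index
    # is ordered by level, so hospital level rises with skill
    hscore = _clip01(skill + noise["hospital_level"] * rng.standard_normal(n))
    hrank = np.argsort(np.argsort(hscore, kind="stable"), kind="stable")
    hospital_of = [hospitals[(r * nh) // n].hospital_id for r in hrank]

    # --- profile fields -----------------------------------------------------
    at_score = _clip01(skill + noise["academic_title"] * rng.standard_normal(n))
    pt_score = _clip01(skill + noise["professional_title"] * rng.standard_normal(n))
    yr_score = _clip01(skill + noise["years"] * rng.standard_normal(n))
    # full precision keeps working years injective in skill, so distinct
    # doctors never collide on the whole feature row
    years = 2.0 + 38.0 * yr_score
    academic = [
        list(AcademicTitle)[int(np.searchsorted([0.55, 0.75, 0.9], s, side="right"))]
        for s in at_score
    ]
    professional = [
        list(ProfessionalTitle)[
            int(np.searchsorted([0.2, 0.4, 0.6, 0.75, 0.9], s, side="right"))
        ]
        for s in pt_score
    ]

    # --- social fans: heavy-tailed, with a small star set -------------------
    presence = skill + noise["fans"] * rng.standard_normal(n) >= 0.3
    fans_base = np.floor(
        10.0 ** (1.0 + 3.0 * _clip01(skill + noise["fans"] * rng.standard_normal(n)))
    ).astype(np.int64)
    star_score = skill + noise["star"] * rng.standard_normal(n)
    n_star = int(round(config.star_fraction * n))
    stars = set(np.argsort(-star_score, kind="stable")[:n_star]) if n_star else set()
    fans: list[int | None] = [
        int(fans_base[i]) * (100 if i in stars else 1) if presence[i] else None
        for i in range(n)
    ]

    # --- doctor records -----------------------------------------------------
    # specialty follows the doctor's top category; name collisions on the
    # dedup key are broken deterministically so distinct doctors never merge
    names = [
        f"{_FAMILY[int(rng.integers(len(_FAMILY)))]} {_GIVEN[int(rng.integers(len(_GIVEN)))]}"
        for _ in range(n)
    ]
    top_cat = np.argmax(quality + 1e-12 * np.arange(n_cat)[None, ::-1], axis=1)
    specialties = [_SPECIALTIES[int(j) % len(_SPECIALTIES)] for j in top_cat]
    seen_keys: set[tuple[str, str, str]] = set()
    for i in range(n):
        key = (names[i], hospital_of[i], specialties[i])
        while key in seen_keys:
            names[i] = names[i] + f" {_GIVEN[int(rng.integers(len(_GIVEN)))]}"
            key = (names[i], hospital_of[i], specialties[i])
        seen_keys.add(key)

    doctors = [
        DoctorRecord(
            doctor_id=doctor_ids[i],
            name=names[i],
            hospital_id=hospital_of[i],
            specialty=specialties[i],
            years_active=float(years[i]),
            academic_title=academic[i],
            professional_title=professional[i],
            social_fans=fans[i],
            source_id="registry",
            source_date=dt.date(2016, 1, 1),
        )
        for i in range(n)
    ]
    hosp_name = {h.hospital_id: h.canonical_name for h in hospitals}

    # --- publications -------------------------------------------------------
    # target authorship count per (doctor, category); the scale is set so the
    # expected total paper count (~3 author slots per paper, mean quality 1/2)
    # matches config.n_publications
    pub_scale = 3.0 * config.n_publications / (0.5 * n * n_cat)
    a_counts = np.round(
        pub_scale
        * _clip01(quality + noise["publications"] * rng.standard_normal((n, n_cat)))
    ).astype(int)

    publications: list[Publication] = []
    pub_counter = 0
    for j, cat in enumerate(category_ids):
        counts = {doctor_ids[i]: int(a_counts[i, j]) for i in range(n)}
        qual = {doctor_ids[i]: float(quality[i, j]) for i in range(n)}
        author_sets = _pack_blocks(counts, qual)
        if not author_sets:
            continue
        # papers whose every author clears the citation quantile get cited
        active = [a for a in a_counts[:, j] if a > 0]
        threshold = max(1.0, float(np.quantile(active, config.cite_quantile))) if active else 1.0
        cat_pubs: list[Publication] = []
        cited_flags: list[bool] = []
        for authors in author_sets:
            pid = f"p{pub_counter:06d}"
            pub_counter += 1
            cat_pubs.append(
                Publication(
                    pub_id=pid,
                    journal=_JOURNALS[int(rng.integers(len(_JOURNALS)))],
                    pub_date=dt.date(int(rng.integers(1990, 2015)), int(rng.integers(1, 13)), 1),
                    author_ids=list(authors),
                    raw_author_names=[names[doctor_ids.index(a)] for a in authors],
                    raw_author_affiliations=[
                        hosp_name[hospital_of[doctor_ids.index(a)]] for a in authors
                    ],
                    categories={cat},
                )
            )
            cited_flags.append(all(counts[a] >= threshold for a in authors))
        # realize citation flags with in-corpus cite edges (round-robin
        # citers; extra citations go to high-quality author sets)
        if len(cat_pubs) > 1:
            citer = int(rng.integers(len(cat_pubs)))
            for k, pub in enumerate(cat_pubs):
                if not cited_flags[k]:
                    continue
                qbar = float(np.mean([qual[a] for a in pub.author_ids]))
                for _ in range(1 + int(round(2.0 * qbar))):
                    if citer == k:
                        citer = (citer + 1) % len(cat_pubs)
                    cat_pubs[citer].cites.add(pub.pub_id)
                    citer = (citer + 1) % len(cat_pubs)
        publications.extend(cat_pubs)

    # --- patient reviews: bimodal levels at {8,9} and {1} -------------------
    reviews: list[ReviewLog] = []
    row_sum = quality.sum(axis=1)
    sig_vol, sig_lvl = noise["review_volume"], noise["review_level"]
    middle_prob = min(0.3, sig_lvl)
    for i in range(n):
        if row_sum[i] <= 0:
            continue
        for j, cat in enumerate(category_ids):
            lam = config.review_rate * quality[i, j] / row_sum[i]
            k = int(round(lam + sig_vol * np.sqrt(lam) * rng.standard_normal()))
            for _ in range(max(0, k)):
                u = quality[i, j] + sig_lvl * rng.standard_normal()
                if middle_prob > 0 and rng.random() < middle_prob:
                    level = int(rng.integers(2, 8))
                elif u < 0.5:
                    level = 1
                else:
                    level = 9 if u >= 0.75 else 8
                reviews.append(
                    ReviewLog(
                        doctor_id=doctor_ids[i],
                        disease_id=cat,
                        level=level,
                        timestamp=dt.date(2015, 11, 1)
                        + dt.timedelta(days=int(rng.integers(0, 92))),
                    )
                )

    # --- seed expertise labels ----------------------------------------------
    seeds: list[SeedLabel] = []
    if config.full_seed_matrix:
        for i in range(n):
            for j, cat in enumerate(category_ids):
                seeds.append(
                    SeedLabel(
                        doctor_id=doctor_ids[i],
                        category_id=cat,
                        value=float(quality[i, j]),
                    )
                )
    else:
        n_seed = int(round(config.seed_fraction * n))
        chosen = rng.choice(n, size=n_seed, replace=False)
        for i in sorted(int(x) for x in chosen):
            seeds.append(
                SeedLabel(
                    doctor_id=doctor_ids[i],
                    category_id=category_ids[int(top_cat[i])],
                    value=1.0,
                )
            )

    corpus = Corpus(
        doctors=doctors,
        hospitals=hospitals,
        publications=publications,
        reviews=reviews,
        categories=[
            DiseaseCategory(category_id=c, name=_DISEASES[j % len(_DISEASES)])
            for j, c in enumerate(category_ids)
        ],
        seed_labels=seeds,
    )
    if config.duplicate_rate > 0:
        corpus, _ = inject_duplicates(corpus, config.duplicate_rate, config.rng_seed + 1)
    return corpus, truth


def noisy_feature_matrix(
    truth: PlantedTruth,
    category_id: str,
    sigmas: "np.ndarray | list[float]",
    rng: np.random.Generator,
):
    """Feature matrix whose columns are noisy copies of planted quality.

    Column i is quality + sigmas[i] * N(0, 1): a controlled instrument
    for studying how rank aggregation allocates weight across features of
    known, graded informativeness (the per-column sigma IS the feature's
    noise level, which no transform of real corpus observables can claim).
    """
    from .features import FeatureMatrix

    j = truth.category_ids.index(category_id)
    q = truth.quality[:, j]
    sig = np.asarray(sigmas, dtype=float)
    values = q[:, None] + sig[None, :] * rng.standard_normal((len(q), len(sig)))
    return FeatureMatrix(
        category_id=category_id,
        doctor_ids=list(truth.doctor_ids),
        feature_names=[f"noisy_quality_{i}" for i in range(len(sig))],
        values=values,
        normalized=False,
    )


def inject_duplicates(
    corpus: Corpus, rate: float, rng_seed: int
) -> tuple[Corpus, list[tuple[str, str, str]]]:
    """Append formatting-perturbed duplicate doctor rows.

    Exactly ``round(rate * n_doctors)`` doctors are re-emitted with case,
    whitespace and punctuation perturbations, a distinct source_id and an
    older source_date.  Returns the new corpus and the dedup keys of the
    injected rows, enabling exact scoring of de-duplication.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    from .corpus import dedup_key

    n_dup = int(round(rate * len(corpus.doctors)))
    if n_dup == 0:
        return corpus, []
    rng = np.random.default_rng(rng_seed)
    chosen = sorted(int(i) for i in rng.choice(len(corpus.doctors), n_dup, replace=False))
    dup_rows: list[DoctorRecord] = []
    keys: list[tuple[str, str, str]] = []
    for i in chosen:
        orig = corpus.doctors[i]
        style = int(rng.integers(3))
        if style == 0:
            name = orig.name.upper()
        elif style == 1:
            name = "  " + orig.name.replace(" ", "   ") + " "
        else:
            name = orig.name.title() + "."
        dup = orig.model_copy(
            update={
                "doctor_id": f"{orig.doctor_id}_dup",
                "name": name,
                "source_id": "secondary_crawl",
                "source_date": orig.source_date - dt.timedelta(days=365),
            }
        )
        dup_rows.append(dup)
        keys.append(dedup_key(orig))
    new = Corpus(
        doctors=list(corpus.doctors) + dup_rows,
        hospitals=corpus.hospitals,
        publications=corpus.publications,
        reviews=corpus.reviews,
        categories=corpus.categories,
        seed_labels=corpus.seed_labels,
    )
    return new, keys
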