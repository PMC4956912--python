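"""Corpus I/O and the multi-source matching / de-duplication pipeline.

Doctors harvested from several sources arrive with formatting noise
(case, whitespace, punctuation) and outright duplication.  The rules here
mirror a standard record-linkage pipeline: normalize names, match
hospitals through alias lists, treat (name, hospital, specialty) as the
doctor identity key, and resolve conflicting field values by source
priority then recency.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd
import pydantic

from .models import (
    ConfigurationError,
    Corpus,
    DiseaseCategory,
    DoctorRecord,
    Hospital,
    Publication,
    ReviewLog,
    SchemaError,
    SeedLabel,
    ValidationFailure,
)

logger = logging.getLogger(__name__)

_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)
_WS_RE = re.compile(r"\s+")

LIST_SEP = ";"

DOCTOR_COLUMNS = [
    "doctor_id",
    "name",
    "hospital_id",
    "specialty",
    "years_active",
    "academic_title",
    "professional_title",
    "social_fans",
    "source_id",
    "source_date",
]
HOSPITAL_COLUMNS = ["hospital_id", "canonical_name", "aliases", "level"]
PUBLICATION_COLUMNS = [
    "pub_id",
    "journal",
    "pub_date",
    "author_ids",
    "raw_author_names",
    "raw_author_affiliations",
    "categories",
    "cites",
]
REVIEW_COLUMNS = ["doctor_id", "disease_id", "level", "timestamp"]
CATEGORY_COLUMNS = ["category_id", "name"]
SEED_COLUMNS = ["doctor_id", "category_id", "value"]


def normalize_name(name: str) -> str:
    """Canonicalize a free-text name: NFKC fold, lowercase, strip
    punctuation, collapse whitespace.  Idempotent."""
    s = unicodedata.normalize("NFKC", name).lower()
    s = _PUNCT_RE.sub(" ", s)
    return _WS_RE.sub(" ", s).strip()


def match_hospital(name: str, hospitals: Sequence[Hospital]) -> Optional[str]:
    """Resolve a raw hospital name against alias lists.

    Raises :class:`ConfigurationError` if two hospitals register the same
    normalized alias.
    """
    alias_map: dict[str, str] = {}
    for h in hospitals:
        for alias in h.aliases:
            key = normalize_name(alias)
            prev = alias_map.get(key)
            if prev is not None and prev != h.hospital_id:
                raise ConfigurationError(
                    f"alias {alias!r} registered for hospitals {prev} and {h.hospital_id}"
                )
            alias_map[key] = h.hospital_id
    return alias_map.get(normalize_name(name))


def dedup_key(record: DoctorRecord) -> tuple[str, str, str]:
    """Doctor identity key: same name at the same hospital with the same
    specialty is considered a single doctor."""
    return (
        normalize_name(record.name),
        record.hospital_id,
        normalize_name(record.specialty),
    )


def resolve_conflict(
    group: Sequence[DoctorRecord],
    source_priority: Sequence[str] = (),
) -> DoctorRecord:
    """Merge records sharing a dedup key, field by field.

    For every field the value is taken from the record with the best
    (source priority, most recent source_date, stable input order).
    Missing values (``social_fans is None``) lose to present ones.
    Unknown source ids fall to lowest priority with a logged warning.
    """
    if not group:
        raise ValueError("resolve_conflict: empty group")
    rank = {sid: i for i, sid in enumerate(source_priority)}
    unknown = len(source_priority)

    def order(idx_rec: tuple[int, DoctorRecord]) -> tuple[int, int, int]:
        idx, rec = idx_rec
        pri = rank.get(rec.source_id, unknown)
        if rec.source_id not in rank and source_priority:
            logger.warning(
                "unknown source_id %r: treated as lowest priority", rec.source_id
            )
        return (pri, -rec.source_date.toordinal(), idx)

    ordered = [rec for _, rec in sorted(enumerate(group), key=order)]
    best = ordered[0]
    merged = best.model_copy(deep=True)
    # social_fans: absent values yield to the best record that has one
    if merged.social_fans is None:
        for rec in ordered[1:]:
            if rec.social_fans is not None:
                merged.social_fans = rec.social_fans
                break
    return merged


@dataclass
class MergeReport:
    """Outcome of de-duplication: one entry per merged group."""

    groups: list[dict] = field(default_factory=list)

    @property
    def n_merged_groups(self) -> int:
        return len(self.groups)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"groups": self.groups}, indent=1))


def deduplicate_doctors(
    records: Sequence[DoctorRecord],
    source_priority: Sequence[str] = (),
) -> tuple[list[DoctorRecord], MergeReport]:
    """Group records by identity key and merge each group.

    Returns the merged records (stable in first-appearance order) and a
    report listing every group of size > 1.
    """
    groups: dict[tuple[str, str, str], list[DoctorRecord]] = {}
    order: list[tuple[str, str, str]] = []
    for rec in records:
        key = dedup_key(rec)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    merged: list[DoctorRecord] = []
    report = MergeReport()
    for key in order:
        group = groups[key]
        winner = resolve_conflict(group, source_priority)
        merged.append(winner)
        if len(group) > 1:
            report.groups.append(
                {
                    "key": list(key),
                    "size": len(group),
                    "member_source_ids": [r.source_id for r in group],
                    "winning_source": winner.source_id,
                }
            )
    return merged, report


def match_authors(
    publications: Sequence[Publication],
    doctors: Sequence[DoctorRecord],
    hospitals: Sequence[Hospital] = (),
    use_affiliation: bool = True,
) -> list[Publication]:
    """Fill ``author_ids`` by matching raw author names to doctors.

    A raw name is matched by normalized name, narrowed by affiliation →
    hospital when available.  Names matching more than one doctor are
    left unmatched (ambiguity is logged, never guessed).
    """
    by_name: dict[str, list[DoctorRecord]] = {}
    for d in doctors:
        by_name.setdefault(normalize_name(d.name), []).append(d)

    out: list[Publication] = []
    for pub in publications:
        matched: list[str] = []
        affils = pub.raw_author_affiliations
        for i, raw in enumerate(pub.raw_author_names):
            cands = by_name.get(normalize_name(raw), [])
            if use_affiliation and affils is not None and i < len(affils) and affils[i]:
                hosp = match_hospital(affils[i], hospitals) if hospitals else None
                if hosp is not None:
                    cands = [d for d in cands if d.hospital_id == hosp]
            if len(cands) == 1:
                if cands[0].doctor_id not in matched:
                    matched.append(cands[0].doctor_id)
            elif len(cands) > 1:
                logger.info(
                    "ambiguous author %r on %s: %d candidate doctors, skipped",
                    raw,
                    pub.pub_id,
                    len(cands),
                )
        out.append(pub.model_copy(update={"author_ids": matched}))
    return out


def build_coauthorship_network(publications: Sequence[Publication]) -> nx.Graph:
    """Coauthorship graph: doctors are nodes, an edge joins every pair
    that coauthors at least one paper, weighted by the number of shared
    papers."""
    g = nx.Graph()
    for pub in publications:
        authors = pub.author_ids
        g.add_nodes_from(authors)
        for i in range(len(authors)):
            for j in range(i + 1, len(authors)):
                a, b = authors[i], authors[j]
                if g.has_edge(a, b):
                    g[a][b]["weight"] += 1
                else:
                    g.add_edge(a, b, weight=1)
    return g


# ---------------------------------------------------------------------------
# Flat-file I/O.  CSV: UTF-8, comma-separated, header required, RFC-4180
# quoting; list-valued cells use ';' separators.  JSON: one top-level array
# per entity file.
# ---------------------------------------------------------------------------


def _split_list(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return [x for x in str(cell).split(LIST_SEP) if x]


def _join_list(values: Iterable[str]) -> str:
    return LIST_SEP.join(values)


def _parse_date(value) -> dt.date:
    """Dates without day (or month) precision snap to the first of the
    period so ordering stays deterministic."""
    s = str(value).strip()
    for fmt in ("%Y-%m-%d", "%Y-%m", "%Y"):
        try:
            return dt.datetime.strptime(s, fmt).date()
        except ValueError:
            continue
    raise ValidationFailure(f"unparseable date: {value!r}")


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _load_table(path: Path, fmt: str) -> pd.DataFrame:
    if fmt == "csv":
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    if fmt == "json":
        data = json.loads(path.read_text())
        if not isinstance(data, list):
            raise SchemaError(f"{path}: JSON entity file must be a top-level array")
        return pd.DataFrame([{k: v for k, v in row.items()} for row in data])
    raise ValueError(f"unknown format {fmt!r}")


def _rows_to_models(df: pd.DataFrame, build, what: str) -> list:
    out = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        try:
            out.append(build(row))
        except (pydantic.ValidationError, ValueError) as exc:
            raise ValidationFailure(f"{what} row {idx}: {exc}") from exc
    return out


def read_corpus(paths: dict[str, str | Path], fmt: str = "csv") -> Corpus:
    """Read a corpus from entity files.

    ``paths`` maps entity names (doctors, hospitals, publications,
    reviews, categories) to file locations; missing entities yield empty
    tables.
    """
    if fmt not in ("csv", "json"):
        raise ValueError(f"unknown format {fmt!r}")
    corpus = Corpus()

    if "doctors" in paths:
        df = _load_table(Path(paths["doctors"]), fmt)
        _require_columns(df, DOCTOR_COLUMNS, "doctors")

        def build_doctor(row):
            fans = row.get("social_fans", "")
            fans = None if fans in ("", None) or pd.isna(fans) else int(float(fans))
            return DoctorRecord(
                doctor_id=row["doctor_id"],
                name=row["name"],
                hospital_id=row["hospital_id"],
                specialty=row["specialty"],
                years_active=float(row["years_active"]),
                academic_title=row["academic_title"],
                professional_title=row["professional_title"],
                social_fans=fans,
                source_id=row["source_id"],
                source_date=_parse_date(row["source_date"]),
            )

        corpus.doctors = _rows_to_models(df, build_doctor, "doctors")

    if "hospitals" in paths:
        df = _load_table(Path(paths["hospitals"]), fmt)
        _require_columns(df, HOSPITAL_COLUMNS, "hospitals")

        def build_hospital(row):
            aliases = row["aliases"]
            if isinstance(aliases, str):
                aliases = _split_list(aliases)
            return Hospital(
                hospital_id=row["hospital_id"],
                canonical_name=row["canonical_name"],
                aliases=set(aliases),
                level=row["level"],
            )

        corpus.hospitals = _rows_to_models(df, build_hospital, "hospitals")

    if "publications" in paths:
        df = _load_table(Path(paths["publications"]), fmt)
        _require_columns(df, PUBLICATION_COLUMNS, "publications")

        def build_pub(row):
            def as_list(v):
                return _split_list(v) if isinstance(v, str) or v is None else list(v)

            affils = as_list(row.get("raw_author_affiliations"))
            return Publication(
                pub_id=row["pub_id"],
                journal=row.get("journal", ""),
                pub_date=_parse_date(row["pub_date"]),
                author_ids=as_list(row["author_ids"]),
                raw_author_names=as_list(row["raw_author_names"]),
                raw_author_affiliations=affils or None,
                categories=set(as_list(row["categories"])),
                cites=set(as_list(row["cites"])),
            )

        corpus.publications = _rows_to_models(df, build_pub, "publications")

    if "reviews" in paths:
        df = _load_table(Path(paths["reviews"]), fmt)
        _require_columns(df, REVIEW_COLUMNS, "reviews")

        def build_review(row):
            return ReviewLog(
                doctor_id=row["doctor_id"],
                disease_id=row["disease_id"],
                level=int(float(row["level"])),
                timestamp=_parse_date(row["timestamp"]),
            )

        corpus.reviews = _rows_to_models(df, build_review, "reviews")

    if "categories" in paths:
        df = _load_table(Path(paths["categories"]), fmt)
        _require_columns(df, CATEGORY_COLUMNS, "categories")
        corpus.categories = _rows_to_models(
            df,
            lambda row: DiseaseCategory(
                category_id=row["category_id"], name=row.get("name", "")
            ),
            "categories",
        )

    if "seeds" in paths:
        df = _load_table(Path(paths["seeds"]), fmt)
        _require_columns(df, SEED_COLUMNS, "seeds")
        corpus.seed_labels = _rows_to_models(
            df,
            lambda row: SeedLabel(
                doctor_id=row["doctor_id"],
                category_id=row["category_id"],
                value=float(row["value"]),
            ),
            "seeds",
        )

    return corpus


def corpus_frames(corpus: Corpus) -> dict[str, pd.DataFrame]:
    """Entity tables as DataFrames in the documented column schemas."""
    doctors = pd.DataFrame(
        [
            {
                "doctor_id": d.doctor_id,
                "name": d.name,
                "hospital_id": d.hospital_id,
                "specialty": d.specialty,
                "years_active": d.years_active,
                "academic_title": d.academic_title.value,
                "professional_title": d.professional_title.value,
                "social_fans": "" if d.social_fans is None else d.social_fans,
                "source_id": d.source_id,
                "source_date": d.source_date.isoformat(),
            }
            for d in corpus.doctors
        ],
        columns=DOCTOR_COLUMNS,
    )
    hospitals = pd.DataFrame(
        [
            {
                "hospital_id": h.hospital_id,
                "canonical_name": h.canonical_name,
                "aliases": _join_list(sorted(h.aliases)),
                "level": h.level.value,
            }
            for h in corpus.hospitals
        ],
        columns=HOSPITAL_COLUMNS,
    )
    publications = pd.DataFrame(
        [
            {
                "pub_id": p.pub_id,
                "journal": p.journal,
                "pub_date": p.pub_date.isoformat(),
                "author_ids": _join_list(p.author_ids),
                "raw_author_names": _join_list(p.raw_author_names),
                "raw_author_affiliations": _join_list(p.raw_author_affiliations or []),
                "categories": _join_list(sorted(p.categories)),
                "cites": _join_list(sorted(p.cites)),
            }
            for p in corpus.publications
        ],
        columns=PUBLICATION_COLUMNS,
    )
    reviews = pd.DataFrame(
        [
            {
                "doctor_id": r.doctor_id,
                "disease_id": r.disease_id,
                "level": r.level,
                "timestamp": r.timestamp.isoformat(),
            }
            for r in corpus.reviews
        ],
        columns=REVIEW_COLUMNS,
    )
    categories = pd.DataFrame(
        [{"category_id": c.category_id, "name": c.name} for c in corpus.categories],
        columns=CATEGORY_COLUMNS,
    )
    seeds = pd.DataFrame(
        [
            {"doctor_id": s.doctor_id, "category_id": s.category_id, "value": s.value}
            for s in corpus.seed_labels
        ],
        columns=SEED_COLUMNS,
    )
    return {
        "doctors": doctors,
        "hospitals": hospitals,
        "publications": publications,
        "reviews": reviews,
        "categories": categories,
        "seeds": seeds,
    }


def write_corpus(corpus: Corpus, out_dir: str | Path, fmt: str = "csv") -> dict[str, Path]:
    """Write entity files to ``out_dir``; returns the path map that
    :func:`read_corpus` accepts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in corpus_frames(corpus).items():
        path = out / f"{name}.{fmt}"
        if fmt == "csv":
            df.to_csv(path, index=False)
        elif fmt == "json":
            path.write_text(json.dumps(df.to_dict(orient="records"), indent=0))
        else:
            raise ValueError(f"unknown format {fmt!r}")
        paths[name] = path
    return paths
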