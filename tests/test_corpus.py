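"""Record linkage: normalization, matching, de-duplication, I/O."""

import datetime as dt
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from kolrank.corpus import (
    build_coauthorship_network,
    dedup_key,
    deduplicate_doctors,
    match_authors,
    match_hospital,
    normalize_name,
    read_corpus,
    resolve_conflict,
    write_corpus,
)
from kolrank.models import (
    ConfigurationError,
    Hospital,
    HospitalLevel,
    Publication,
    SchemaError,
    ValidationFailure,
)
from .conftest import make_doctor


class TestNormalizeName:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            (" Li  Wei.", "li wei"),
            ("LI WEI", "li wei"),
            ("li wei", "li wei"),
            ("  Zhang,min ", "zhang min"),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_name(raw) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.text(max_size=40))
    def test_idempotent(self, s):
        assert normalize_name(normalize_name(s)) == normalize_name(s)

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="abcdefghijklmnopqrstuvwxyz .,-", max_size=30))
    def test_case_insensitive(self, s):
        assert normalize_name(s.upper()) == normalize_name(s.lower())


class TestMatchHospital:
    def hospitals(self):
        return [
            Hospital(hospital_id="H1", canonical_name="Union Hospital",
                     aliases={"pumch"}, level=HospitalLevel.GIII_A),
            Hospital(hospital_id="H2", canonical_name="Second Hospital",
                     aliases={"sh"}, level=HospitalLevel.GI_A),
        ]

    def test_alias_lookup_after_normalization(self):
        assert match_hospital("PUMCH", self.hospitals()) == "H1"
        assert match_hospital("union   hospital", self.hospitals()) == "H1"

    def test_unregistered_name(self):
        assert match_hospital("nowhere clinic", self.hospitals()) is None

    def test_overlapping_aliases_rejected(self):
        hs = self.hospitals()
        hs[1].aliases.add("PUMCH")
        with pytest.raises(ConfigurationError):
            match_hospital("anything", hs)


class TestResolveConflict:
    def test_singleton_identity(self):
        rec = make_doctor(1)
        assert resolve_conflict([rec], ["registry"]) == rec

    def test_priority_wins_fieldwise(self):
        a = make_doctor(1, social_fans=50, source_id="gov")
        b = make_doctor(1, social_fans=7, source_id="crawl")
        merged = resolve_conflict([b, a], ["gov", "crawl"])
        assert merged.social_fans == 50

    def test_recency_breaks_priority_ties(self):
        old = make_doctor(1, years_active=5, source_date=dt.date(2015, 1, 1))
        new = make_doctor(1, years_active=9, source_date=dt.date(2016, 1, 1))
        merged = resolve_conflict([old, new], ["registry"])
        assert merged.years_active == 9

    def test_missing_fans_filled_from_lower_priority(self):
        a = make_doctor(1, social_fans=None, source_id="gov")
        b = make_doctor(1, social_fans=123, source_id="crawl")
        merged = resolve_conflict([a, b], ["gov", "crawl"])
        assert merged.social_fans == 123

    def test_never_invents_values(self):
        group = [
            make_doctor(1, years_active=3, source_id="a"),
            make_doctor(1, years_active=8, source_id="b"),
        ]
        merged = resolve_conflict(group, ["b", "a"])
        for fieldname in ("years_active", "social_fans", "name", "specialty"):
            assert getattr(merged, fieldname) in {getattr(r, fieldname) for r in group}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            resolve_conflict([], [])


class TestDeduplicate:
    def test_same_key_merges(self):
        a = make_doctor(1, source_id="a")
        b = make_doctor(1, source_id="b")
        merged, report = deduplicate_doctors([a, b], ["a", "b"])
        assert len(merged) == 1
        assert report.n_merged_groups == 1

    def test_different_hospital_stays_separate(self):
        a = make_doctor(1)
        b = make_doctor(1, hospital_id="h9")
        merged, _ = deduplicate_doctors([a, b])
        assert len(merged) == 2

    def test_count_matches_distinct_key_oracle(self):
        # k duplicate pairs among n records -> n - k outputs
        records = []
        for i in range(12):
            records.append(make_doctor(i))
            if i % 3 == 0:  # perturbed duplicate
                records.append(make_doctor(i, source_id="dup",
                                           name=f" LI  WEI{i} "))
        merged, _ = deduplicate_doctors(records)
        assert len(merged) == len({dedup_key(r) for r in records})

    def test_idempotent(self):
        records = [make_doctor(i % 4, source_id=f"s{i}") for i in range(10)]
        once, _ = deduplicate_doctors(records)
        twice, report = deduplicate_doctors(once)
        assert twice == once
        assert report.n_merged_groups == 0


class TestMatchAuthors:
    def test_unique_name_and_affiliation(self, small_corpus):
        pub = Publication(pub_id="x", raw_author_names=["Li Wei"],
                          raw_author_affiliations=["PUMCH"], categories={"c1"})
        (out,) = match_authors([pub], small_corpus.doctors, small_corpus.hospitals)
        assert out.author_ids == ["d1"]

    def test_ambiguous_name_left_unmatched(self, small_corpus):
        twin = make_doctor(9, name="Li Wei", specialty="oncology")
        doctors = small_corpus.doctors + [twin]
        pub = Publication(pub_id="x", raw_author_names=["li wei"], categories={"c1"})
        (out,) = match_authors([pub], doctors, small_corpus.hospitals)
        assert out.author_ids == []

    def test_known_resolvable_subset(self, small_corpus):
        # 10 raw authors, exactly 7 resolvable against the roster
        doctors = [make_doctor(i, name=f"doc {i}") for i in range(7)]
        names = [f"Doc {i}" for i in range(7)] + ["ghost a", "ghost b", "ghost c"]
        pub = Publication(pub_id="x", raw_author_names=names, categories={"c"})
        (out,) = match_authors([pub], doctors)
        assert len(out.author_ids) == 7


class TestCoauthorshipNetwork:
    def test_single_paper_triangle(self):
        pub = Publication(pub_id="p", author_ids=["a", "b", "c"])
        g = build_coauthorship_network([pub])
        assert set(g.edges) == {("a", "b"), ("a", "c"), ("b", "c")}
        assert all(g[u][v]["weight"] == 1 for u, v in g.edges)

    def test_repeat_collaboration_counts(self):
        pubs = [Publication(pub_id=f"p{i}", author_ids=["a", "b"]) for i in range(3)]
        g = build_coauthorship_network(pubs)
        assert g["a"]["b"]["weight"] == 3

    def test_matches_quadratic_oracle(self, default_corpus):
        corpus, _ = default_corpus
        pubs = corpus.publications[:20]
        g = build_coauthorship_network(pubs)
        expected = {}
        for p in pubs:
            for a, b in itertools.combinations(sorted(p.author_ids), 2):
                expected[(a, b)] = expected.get((a, b), 0) + 1
        got = {tuple(sorted(e)): g.edges[e]["weight"] for e in g.edges}
        assert got == expected

    def test_no_self_loops_weight_sum(self):
        pubs = [
            Publication(pub_id="p1", author_ids=["a", "b", "c"]),
            Publication(pub_id="p2", author_ids=["d", "e"]),
        ]
        g = build_coauthorship_network(pubs)
        assert not any(u == v for u, v in g.edges)
        # no pair coauthors twice: weight sum = sum of C(n_authors, 2)
        assert sum(d["weight"] for _, _, d in g.edges(data=True)) == 3 + 1


class TestIO:
    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_round_trip(self, small_corpus, tmp_path, fmt):
        paths = write_corpus(small_corpus, tmp_path, fmt=fmt)
        back = read_corpus(paths, fmt=fmt)
        assert back.doctors == small_corpus.doctors
        assert back.hospitals == small_corpus.hospitals
        assert back.publications == small_corpus.publications
        assert back.reviews == small_corpus.reviews
        assert back.categories == small_corpus.categories
        assert back.seed_labels == small_corpus.seed_labels

    def test_missing_column_names_column(self, small_corpus, tmp_path):
        paths = write_corpus(small_corpus, tmp_path)
        text = paths["doctors"].read_text().splitlines()
        header = text[0].replace("professional_title", "job")
        paths["doctors"].write_text("\n".join([header] + text[1:]))
        with pytest.raises(SchemaError, match="professional_title"):
            read_corpus(paths)

    def test_bad_enum_reports_row(self, small_corpus, tmp_path):
        paths = write_corpus(small_corpus, tmp_path)
        text = paths["doctors"].read_text().replace("chief_physician", "Surgeon")
        paths["doctors"].write_text(text)
        with pytest.raises(ValidationFailure, match="row 0"):
            read_corpus(paths)

    def test_header_only_doctors_file(self, small_corpus, tmp_path):
        paths = write_corpus(small_corpus, tmp_path)
        header = paths["doctors"].read_text().splitlines()[0]
        paths["doctors"].write_text(header + "\n")
        corpus = read_corpus(paths)
        assert corpus.doctors == []
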