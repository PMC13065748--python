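"""Assessment tests: label normalization, clustering, the four consistency
metrics, and the coverage classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unhs.assessment import (
    AssessmentError,
    CatalogItem,
    FacilityCatalog,
    MappingHint,
    MatchStatus,
    cluster_items,
    consistency_metrics,
    coverage_report,
    match_catalog_to_registry,
    normalize_label,
    read_catalog,
    round_pct,
    write_catalog,
)


def catalog(facility_id, *rows):
    return FacilityCatalog(
        facility_id, [CatalogItem(code, label) for code, label in rows]
    )


class TestNormalizeLabel:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Aciclovir—200 mg tablet", "ACICLOVIR 200 MG TABLET"),
            ("  glucose ", "GLUCOSE"),
            ("Glucose", "GLUCOSE"),
            ("Radiographie simple du crâne", "RADIOGRAPHIE SIMPLE DU CRANE"),
            ("a,b;c  (d)", "A B C D"),
        ],
    )
    def test_rules(self, raw, expected):
        assert normalize_label(raw) == expected

    @given(st.text(max_size=60))
    @settings(derandomize=True, max_examples=200)
    def test_idempotent(self, text):
        once = normalize_label(text)
        assert normalize_label(once) == once


class TestClustering:
    def test_identical_labels_merge_across_facilities(self):
        cats = [
            catalog("A", ("1", "Glucose"), ("2", "X-ray")),
            catalog("B", ("9", "glucose "), ("8", "X-RAY")),
        ]
        clusters = cluster_items(cats)
        assert len(clusters) == 2
        assert all(len(c.members) == 2 for c in clusters)

    def test_concept_key_overrides_label_mismatch(self):
        cats = [catalog("A", ("1", "Glucose")), catalog("B", ("9", "Blood sugar"))]
        key = {("A", 0): "GLU", ("B", 0): "GLU"}
        clusters = cluster_items(cats, concept_key=key)
        assert len(clusters) == 1 and len(clusters[0].members) == 2

    def test_unknown_item_in_key_rejected(self):
        cats = [catalog("A", ("1", "Glucose"))]
        with pytest.raises(AssessmentError, match="unknown items"):
            cluster_items(cats, concept_key={("A", 5): "GLU"})

    def test_every_item_in_exactly_one_cluster(self, study_shape_fixture):
        _, _, catalogs, truth = study_shape_fixture
        clusters = cluster_items(catalogs, concept_key=truth.concept_key)
        members = [m for c in clusters for m in c.members]
        assert len(members) == len(set(members)) == truth.n_items


class TestConsistencyMetrics:
    def test_perfect_harmonization(self):
        rows = [("C1", "Glucose"), ("C2", "X-ray")]
        cats = [catalog(f, *rows) for f in "ABC"]
        report = consistency_metrics(cats, cluster_items(cats))
        assert report.pct_consistent_across_facilities == 100.0
        assert report.pct_duplicate_within_facility == 0.0
        assert report.pct_multiple_codes_across_facilities == 0.0
        assert report.pct_code_reuse_for_different_services == 0.0

    def test_single_facility_distinct_codes_no_duplicates(self):
        cats = [catalog("A", ("1", "Glucose"), ("2", "X-ray"), ("3", "MRI"))]
        report = consistency_metrics(cats, cluster_items(cats))
        assert report.pct_duplicate_within_facility == 0.0

    def test_duplicate_entries_counted_per_item(self):
        cats = [catalog("A", ("1", "Glucose"), ("1", "Glucose"), ("2", "X-ray"), ("3", "MRI"))]
        report = consistency_metrics(cats, cluster_items(cats))
        assert report.pct_duplicate_within_facility == 50.0  # 2 of 4 items
        assert report.denominators["duplicate_within"] == 4

    def test_code_reuse_across_services(self):
        cats = [catalog("A", ("7", "Glucose"), ("7", "X-ray"), ("8", "MRI"))]
        report = consistency_metrics(cats, cluster_items(cats))
        # code 7 serves two different services: 1 of 2 distinct codes
        assert report.pct_code_reuse_for_different_services == 50.0
        # cross-cluster code sharing is reuse, not duplication
        assert report.pct_duplicate_within_facility == 0.0

    def test_divergent_codes_count_as_multiple(self):
        cats = [catalog("A", ("1", "Glucose")), catalog("B", ("2", "Glucose"))]
        report = consistency_metrics(cats, cluster_items(cats))
        assert report.pct_multiple_codes_across_facilities == 100.0
        assert report.pct_consistent_across_facilities == 100.0  # labels agree

    def test_facility_and_item_order_invariance(self, study_shape_fixture):
        _, _, catalogs, truth = study_shape_fixture
        clusters = cluster_items(catalogs, concept_key=truth.concept_key)
        report = consistency_metrics(catalogs, clusters)
        reordered = list(reversed(catalogs))
        clusters2 = cluster_items(reordered, concept_key=truth.concept_key)
        report2 = consistency_metrics(reordered, clusters2)
        assert report == report2

    def test_clusters_must_match_catalogs(self):
        cats = [catalog("A", ("1", "Glucose"))]
        clusters = cluster_items([catalog("A", ("1", "Glucose"), ("2", "X-ray"))])
        with pytest.raises(AssessmentError, match="partition"):
            consistency_metrics(cats, clusters)


class TestMatching:
    def test_exact_label_match_is_direct(self, mock_registry):
        label = mock_registry.concepts[0].labels["en"]
        cat = catalog("A", ("1", label.lower()))
        matches = match_catalog_to_registry(cat, mock_registry)
        assert matches[0].status == MatchStatus.DIRECT
        assert matches[0].code == mock_registry.concepts[0].code

    def test_hint_relations(self, mock_registry):
        code = mock_registry.concepts[0].code
        cat = catalog("A", ("1", "local a"), ("2", "local b"), ("3", "local c"))
        mapping = {
            0: MappingHint("extension", code=code),
            1: MappingHint("header", code=code),
            2: MappingHint("operational", domain="PROC"),
        }
        statuses = [m.status for m in match_catalog_to_registry(cat, mock_registry, mapping)]
        assert statuses == [
            MatchStatus.EXTENSION_REQUIRED,
            MatchStatus.HEADER_MAPPED,
            MatchStatus.OPERATIONAL_ONLY,
        ]

    def test_unmatched_without_hint(self, mock_registry):
        cat = catalog("A", ("1", "completely local tariff line"))
        assert match_catalog_to_registry(cat, mock_registry)[0].status == MatchStatus.UNMATCHED

    def test_bad_hint_code_rejected(self, mock_registry):
        cat = catalog("A", ("1", "x"))
        with pytest.raises(AssessmentError, match="checksum"):
            match_catalog_to_registry(cat, mock_registry, {0: MappingHint("direct", code="RSCG")})

    def test_empty_catalog_gives_empty_statuses(self, mock_registry):
        assert match_catalog_to_registry(FacilityCatalog("A"), mock_registry) == []

    def test_fuzzy_matching_off_by_default_and_flagged_when_on(self, mock_registry):
        label = mock_registry.concepts[0].labels["en"]
        cat = catalog("A", ("1", label + " x"))  # near miss
        assert match_catalog_to_registry(cat, mock_registry)[0].status == MatchStatus.UNMATCHED
        fuzzy = match_catalog_to_registry(cat, mock_registry, fuzzy_threshold=0.9)[0]
        assert fuzzy.status == MatchStatus.DIRECT and fuzzy.fuzzy


class TestCoverageReport:
    def test_all_direct(self):
        report = coverage_report({"LAB": [MatchStatus.DIRECT] * 10})
        row = report.overall
        assert (row.international_coverage_pct, row.national_extension_pct,
                row.operational_only_pct, row.overall_coverage_pct) == (100.0, 0.0, 0.0, 100.0)

    def test_planted_overall_split(self):
        statuses = (
            [MatchStatus.DIRECT] * 910
            + [MatchStatus.EXTENSION_REQUIRED] * 67
            + [MatchStatus.OPERATIONAL_ONLY] * 23
        )
        report = coverage_report({"PROC": statuses})
        row = report.overall
        assert row.n_items == 1000
        assert row.international_coverage_pct == 91.0
        assert row.national_extension_pct == 6.7
        assert row.operational_only_pct == 2.3
        assert row.overall_coverage_pct == 97.7

    def test_validation_style_coverage_rate(self):
        statuses = [MatchStatus.DIRECT] * 4465 + [MatchStatus.UNMATCHED] * 202
        report = coverage_report({"LAB": statuses})
        assert report.overall.n_items == 4667
        assert report.overall.overall_coverage_pct == 95.7

    def test_shares_sum_to_hundred_before_rounding(self):
        counts = {"direct": 3, "extension_required": 1, "operational_only": 1,
                  "header_mapped": 1, "unmatched": 1}
        statuses = [s for s, k in counts.items() for _ in range(k)]
        row = coverage_report({"IMG": statuses}).overall
        total = (row.international_coverage_pct + row.national_extension_pct
                 + row.operational_only_pct + row.unmatched_pct)
        assert abs(total - 100.0) < 0.2  # rounding each share to one decimal

    def test_unknown_domain_rejected(self):
        with pytest.raises(Exception, match="domain"):
            coverage_report({"BOGUS": [MatchStatus.DIRECT]})

    def test_tran_alias_accepted(self):
        report = coverage_report({"TRAN": [MatchStatus.DIRECT]})
        assert report.rows[0].domain == "TRANS"


class TestRoundingAndIO:
    def test_round_half_up(self):
        assert round_pct(1, 8) == 12.5
        assert round_pct(25, 1000) == 2.5
        assert round_pct(4465, 4667) == 95.7
        assert round_pct(1, 16) == 6.3  # 6.25 rounds half-up
        assert round_pct(0, 0) == 0.0

    @pytest.mark.parametrize("dialect", ["csv", "tsv"])
    def test_catalog_round_trip(self, tmp_path, dialect):
        cats = [
            FacilityCatalog("A", [CatalogItem("1", "Glucose", 500.0), CatalogItem("2", "X-ray")]),
            FacilityCatalog("B", [CatalogItem("9", "Césarienne, forfait")]),
        ]
        path = tmp_path / f"cat.{dialect}"
        write_catalog(cats, path, dialect=dialect)
        loaded = read_catalog(path, dialect=dialect)
        assert [(c.facility_id, c.items) for c in loaded] == [
            (c.facility_id, c.items) for c in cats
        ]

    def test_bad_price_rejected_with_line(self, tmp_path):
        path = tmp_path / "cat.csv"
        path.write_text("facility_id,local_code,label,price\nA,1,Glucose,abc\n")
        with pytest.raises(AssessmentError, match="cat.csv:2"):
            read_catalog(path)
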