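"""Catalog retrieval: pattern search, neighbor expansion, keyword baseline, benchmark."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from amrcodes import (
    Catalog,
    CatalogRecord,
    GeneratorConfig,
    Query,
    QueryPattern,
    benchmark_one_shot,
    generate_catalog,
    keyword_search,
    make_query_set,
    neighbor_expansion,
    search_by_code_pattern,
)
from amrcodes.catalog import CatalogError
from amrcodes.codec import PROFILES


# -- independent oracles ---------------------------------------------------


def naive_pattern_match(pattern: QueryPattern, code: str) -> bool:
    """Char-by-char scan oracle, no regex."""
    widths = PROFILES[pattern.profile]
    template = "CSTR09:"
    for name, seg in zip("ABCD", (pattern.a, pattern.b, pattern.c, pattern.d)):
        template += name + ("?" * widths[name] if seg == "*" else seg)
    if len(code) != len(template):
        return False
    for want, have in zip(template, code):
        if want == "?":
            if not have.isdigit():
                return False
        elif want != have:
            return False
    return True


def naive_search(catalog: Catalog, pattern: QueryPattern) -> list[str]:
    hits = [r for r in catalog if naive_pattern_match(pattern, r.code)]
    return [r.record_id for r in sorted(hits, key=lambda r: (r.code, r.record_id))]


def layer_positions(profile: str, layers) -> list[int]:
    """Absolute character positions of the given layers in the canonical string."""
    from amrcodes.catalog import LAYER_SPANS, _LAYER_ALIASES

    widths = PROFILES[profile]
    part_start = {}
    pos = len("CSTR09:")
    for name in "ABCD":
        pos += 1  # the segment letter
        part_start[name.lower()] = pos
        pos += widths[name]
    out = []
    for layer in layers:
        part, offset, width = LAYER_SPANS[profile][_LAYER_ALIASES.get(layer, layer)]
        out.extend(range(part_start[part] + offset, part_start[part] + offset + width))
    return out


def naive_neighbors(catalog: Catalog, base: str, vary) -> list[str]:
    """Scan oracle: codes equal to base outside the varied digit positions."""
    allowed = set(layer_positions(catalog.profile, vary))
    hits = []
    for record in catalog:
        if record.code == base or len(record.code) != len(base):
            continue
        if all(
            record.code[i] == base[i] for i in range(len(base)) if i not in allowed
        ):
            hits.append(record)
    return [r.record_id for r in sorted(hits, key=lambda r: (r.code, r.record_id))]


@pytest.fixture(scope="module")
def synthetic_catalog(registry):
    return generate_catalog(registry, GeneratorConfig(total_records=1000, seed=7))


# -- pattern search --------------------------------------------------------


class TestPatternSearch:
    def test_partial_pattern_on_published_table(self, table4_catalog):
        pattern = QueryPattern(a="0101", c="01")
        result = search_by_code_pattern(table4_catalog, pattern)
        codes = [table4_catalog[i].code for i in result.record_ids]
        assert result.candidate_count == 2
        assert codes == ["CSTR09:A0101B1111001C01D122", "CSTR09:A0101B1111001C01D312"]

    def test_unconstrained_pattern_returns_all(self, table4_catalog):
        result = search_by_code_pattern(table4_catalog, QueryPattern())
        assert result.candidate_count == len(table4_catalog)

    def test_fully_literal_pattern_is_one_shot_on_unique_codes(self, table4_catalog):
        pattern = QueryPattern(a="0101", b="1111001", c="01", d="122")
        result = search_by_code_pattern(table4_catalog, pattern)
        assert result.candidate_count == 1

    def test_matches_scan_oracle_on_synthetic_catalog(self, synthetic_catalog):
        patterns = [
            QueryPattern(),
            QueryPattern(b="1111017"),
            QueryPattern(a="0101", c="0?"),
            QueryPattern(d="?2?"),
            QueryPattern(a="03??", b="11?????"),
        ]
        for pattern in patterns:
            result = search_by_code_pattern(synthetic_catalog, pattern)
            assert list(result.record_ids) == naive_search(synthetic_catalog, pattern)

    def test_malformed_pattern_rejected(self):
        with pytest.raises(CatalogError):
            QueryPattern(a="01")  # wrong width
        with pytest.raises(CatalogError):
            QueryPattern(d="1x2")

    @given(st.data())
    def test_adding_a_literal_digit_never_increases_candidates(self, synthetic_catalog, data):
        record = data.draw(st.sampled_from(synthetic_catalog.records))
        widths = PROFILES["paper"]
        segs = {}
        for name, part in zip(
            "abcd",
            (record.code[8:12], record.code[13:20], record.code[21:23], record.code[24:27]),
        ):
            mask = data.draw(st.lists(st.booleans(), min_size=len(part), max_size=len(part)))
            segs[name] = "".join(ch if keep else "?" for ch, keep in zip(part, mask))
        loose = QueryPattern(**segs)
        # specialize one wildcard position back to the record's digit
        positions = [
            (name, i) for name in "abcd" for i, ch in enumerate(segs[name]) if ch == "?"
        ]
        if not positions:
            return
        name, i = data.draw(st.sampled_from(positions))
        literal = {"a": record.code[8:12], "b": record.code[13:20],
                   "c": record.code[21:23], "d": record.code[24:27]}[name]
        tightened = dict(segs)
        tightened[name] = segs[name][:i] + literal[i] + segs[name][i + 1:]
        loose_count = search_by_code_pattern(synthetic_catalog, loose).candidate_count
        tight_count = search_by_code_pattern(synthetic_catalog, QueryPattern(**tightened)).candidate_count
        assert tight_count <= loose_count


# -- neighbor expansion ----------------------------------------------------


class TestNeighborExpansion:
    BASE = "CSTR09:A0101B1111001C01D122"

    def test_varying_cooperation_and_sharing_finds_the_sibling_row(self, table4_catalog):
        result = neighbor_expansion(
            table4_catalog, self.BASE, vary={"D.cooperation", "D.sharing"}
        )
        assert [table4_catalog[i].code for i in result.record_ids] == [
            "CSTR09:A0101B1111001C01D312"
        ]

    def test_varying_cooperation_and_preservation_finds_nothing(self, table4_catalog):
        # the only other myocarditis row differs in sharing, which stays fixed
        result = neighbor_expansion(
            table4_catalog, self.BASE, vary={"D.cooperation", "D.preservation"}
        )
        assert result.candidate_count == 0

    def test_single_record_catalog_has_no_neighbors(self, registry):
        catalog = Catalog(
            [CatalogRecord("only", self.BASE, {})], registry=registry
        )
        result = neighbor_expansion(catalog, self.BASE, vary={"A.intermediate"})
        assert result.candidate_count == 0

    @pytest.mark.parametrize(
        "vary",
        [
            {"C.category"},
            {"A.intermediate"},
            {"D.cooperation", "D.sharing", "D.preservation"},
            {"B.strain", "C.category"},
        ],
    )
    def test_equals_scan_oracle(self, table4_catalog, synthetic_catalog, vary):
        for catalog in (table4_catalog, synthetic_catalog):
            base = catalog.records[0].code
            result = neighbor_expansion(catalog, base, vary=vary)
            assert list(result.record_ids) == naive_neighbors(catalog, base, vary)

    def test_empty_vary_rejected(self, table4_catalog):
        with pytest.raises(CatalogError):
            neighbor_expansion(table4_catalog, self.BASE, vary=set())

    def test_invalid_base_code_rejected(self, table4_catalog):
        with pytest.raises(Exception):
            neighbor_expansion(table4_catalog, "CSTR09:A01", vary={"C.category"})


# -- keyword baseline ------------------------------------------------------


class TestKeywordSearch:
    def test_and_composition_equals_intersection(self, synthetic_catalog):
        f1 = {"name": "mouse"}
        f2 = {"disease_description": "cardiovascular"}
        both = keyword_search(synthetic_catalog, {**f1, **f2})
        only1 = set(keyword_search(synthetic_catalog, f1).record_ids)
        only2 = set(keyword_search(synthetic_catalog, f2).record_ids)
        assert set(both.record_ids) == only1 & only2

    def test_partial_fields_match_substrings(self, synthetic_catalog):
        full = keyword_search(synthetic_catalog, {"name": "myocarditis"})
        assert full.candidate_count > 0
        for record_id in full.record_ids:
            assert "myocarditis" in synthetic_catalog[record_id].metadata["name"]

    def test_exact_fields_require_equality(self, synthetic_catalog):
        result = keyword_search(synthetic_catalog, {"preservation": "froz"})
        assert result.candidate_count == 0
        result = keyword_search(synthetic_catalog, {"preservation": "frozen"})
        assert result.candidate_count > 0

    def test_empty_catalog_returns_nothing(self, registry):
        catalog = Catalog([], registry=registry)
        assert keyword_search(catalog, {"name": "SARS"}).candidate_count == 0

    def test_unknown_field_rejected(self, synthetic_catalog):
        with pytest.raises(CatalogError):
            keyword_search(synthetic_catalog, {"colour": "green"})

    def test_match_is_case_sensitive(self, synthetic_catalog):
        upper = keyword_search(synthetic_catalog, {"name": "MYOCARDITIS"})
        assert upper.candidate_count == 0


# -- catalog invariants ----------------------------------------------------


class TestCatalog:
    def test_duplicate_record_id_rejected(self, registry):
        records = [
            CatalogRecord("a", "CSTR09:A0101B1111001C01D122", {}),
            CatalogRecord("a", "CSTR09:A0101B1111001C01D312", {}),
        ]
        with pytest.raises(CatalogError):
            Catalog(records, registry=registry)

    def test_invalid_code_rejected_when_registry_given(self, registry):
        with pytest.raises(CatalogError):
            Catalog([CatalogRecord("a", "CSTR09:A9901B1111001C01D122", {})], registry=registry)

    def test_shared_codes_are_allowed(self, registry):
        code = "CSTR09:A0101B1111001C01D122"
        catalog = Catalog(
            [CatalogRecord("a", code, {}), CatalogRecord("b", code, {})], registry=registry
        )
        assert len(catalog) == 2


# -- benchmark -------------------------------------------------------------


class TestBenchmark:
    def test_unique_codes_give_perfect_new_method_one_shot_rate(self, table4_catalog):
        queries = [
            Query(r.record_id, {"name": r.metadata["name"]}, QueryPattern.from_code(r.code))
            for r in table4_catalog
        ]
        report = benchmark_one_shot(table4_catalog, queries)
        assert report.new_method.one_shot_rate == 1.0
        assert report.new_method.max_candidates == 1

    def test_old_method_candidate_lists_are_larger_on_synthetic_catalog(
        self, synthetic_catalog
    ):
        queries = make_query_set(synthetic_catalog, 100, seed=3)
        report = benchmark_one_shot(synthetic_catalog, queries)
        assert report.old_method.mean_candidates > report.new_method.mean_candidates
        assert report.n_queries == 100

    def test_empty_query_set_marks_rates_undefined(self, table4_catalog):
        report = benchmark_one_shot(table4_catalog, [])
        assert report.n_queries == 0
        assert report.old_method.one_shot_rate is None
        assert report.new_method.mean_candidates is None

    def test_unknown_target_rejected(self, table4_catalog):
        query = Query("nope", {"name": "x"}, QueryPattern())
        with pytest.raises(CatalogError):
            benchmark_one_shot(table4_catalog, [query])

    def test_report_round_trips_to_dict_and_text(self, table4_catalog):
        queries = make_query_set(table4_catalog, 3, seed=0)
        report = benchmark_one_shot(table4_catalog, queries)
        payload = report.as_dict()
        assert payload["schema_version"] == 1
        assert "one-shot rate" in str(report)
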