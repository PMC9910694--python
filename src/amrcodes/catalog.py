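"""Coded-record catalogs and the two retrieval routes they support.

The *code-pattern* route (the scheme's own retrieval method) matches canonical
codes digit by digit, with per-digit ``?`` wildcards and per-segment ``*``;
*neighbor expansion* wildcards chosen layers of a base code to pull related
models.  The *keyword* route emulates the field AND-matching of the national
database front end (substring match on the long text fields, exact match on
the short ones) and serves as the baseline in retrieval-efficiency benchmarks.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .codec import PROFILES, ModelCode, validate_code
from .registry import Registry

__all__ = [
    "CatalogRecord",
    "Catalog",
    "QueryPattern",
    "RetrievalResult",
    "Query",
    "MethodSummary",
    "BenchmarkReport",
    "CatalogError",
    "PARTIAL_MATCH_FIELDS",
    "EXACT_MATCH_FIELDS",
    "METADATA_FIELDS",
    "LAYER_SPANS",
    "search_by_code_pattern",
    "neighbor_expansion",
    "keyword_search",
    "benchmark_one_shot",
]

#: Text fields matched by substring (they hold long free text) vs. equality.
PARTIAL_MATCH_FIELDS = ("name", "english_name", "disease_description")
EXACT_MATCH_FIELDS = ("cooperation", "date", "preservation")
METADATA_FIELDS = PARTIAL_MATCH_FIELDS + EXACT_MATCH_FIELDS + ("keywords",)


class CatalogError(ValueError):
    pass


@dataclass
class CatalogRecord:
    record_id: str
    code: str
    metadata: dict = field(default_factory=dict)


class Catalog:
    """A collection of coded records.

    ``record_id`` is unique; codes are classification categories, so several
    records may legitimately share one code.  When a registry is supplied every
    code is validated against it at construction time.
    """

    def __init__(
        self,
        records: Iterable[CatalogRecord],
        registry: Optional[Registry] = None,
        profile: str = "paper",
    ) -> None:
        self.records = list(records)
        self.registry = registry
        self.profile = profile
        seen: set[str] = set()
        for record in self.records:
            if record.record_id in seen:
                raise CatalogError(f"duplicate record_id {record.record_id!r}")
            seen.add(record.record_id)
            if registry is not None:
                violations = validate_code(registry, record.code)
                if violations:
                    raise CatalogError(
                        f"record {record.record_id!r} has invalid code {record.code!r}: "
                        + "; ".join(str(v) for v in violations)
                    )
        self._by_id = {r.record_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, record_id: str) -> CatalogRecord:
        return self._by_id[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id


@dataclass(frozen=True)
class RetrievalResult:
    """Deterministically ordered match list; ``candidate_count`` == number of ids."""

    record_ids: tuple[str, ...]
    candidate_count: int

    def __post_init__(self) -> None:
        if self.candidate_count != len(self.record_ids):
            raise ValueError("candidate_count must equal the number of matched ids")

    @classmethod
    def from_records(cls, records: Sequence[CatalogRecord]) -> "RetrievalResult":
        ordered = sorted(records, key=lambda r: (r.code, r.record_id))
        ids = tuple(r.record_id for r in ordered)
        return cls(ids, len(ids))


# -- code-pattern search ---------------------------------------------------

#: Digit span of each layer inside its code segment: layer id -> (part, offset, width).
LAYER_SPANS = {
    "paper": {
        "A.major": ("a", 0, 2),
        "A.intermediate": ("a", 2, 2),
        "B.major": ("b", 0, 2),
        "B.intermediate": ("b", 2, 2),
        "B.minor": ("b", 4, 3),
        "C.category": ("c", 0, 2),
        "D.cooperation": ("d", 0, 1),
        "D.sharing": ("d", 1, 1),
        "D.preservation": ("d", 2, 1),
    },
    "extended": {
        "A.major": ("a", 0, 2),
        "A.intermediate": ("a", 2, 2),
        "A.minor": ("a", 4, 2),
        "B.major": ("b", 0, 2),
        "B.intermediate": ("b", 2, 2),
        "B.minor": ("b", 4, 3),
        "C.category": ("c", 0, 2),
        "C.subcategory": ("c", 2, 2),
        "D.cooperation": ("d", 0, 1),
        "D.sharing": ("d", 1, 1),
        "D.preservation": ("d", 2, 1),
    },
}

#: Friendlier layer names accepted everywhere a layer id is.
_LAYER_ALIASES = {
    "B.species": "B.intermediate",
    "B.strain": "B.minor",
    "A.disease": "A.intermediate",
}


@dataclass(frozen=True)
class QueryPattern:
    """Per-digit constraints over the four code segments.

    Each segment is either ``"*"`` (unconstrained) or a string of the segment's
    exact profile width mixing literal digits and ``"?"`` wildcards.
    """

    a: str = "*"
    b: str = "*"
    c: str = "*"
    d: str = "*"
    profile: str = "paper"

    def __post_init__(self) -> None:
        widths = PROFILES.get(self.profile)
        if widths is None:
            raise ValueError(f"unknown profile {self.profile!r}")
        for name, pattern in zip("ABCD", (self.a, self.b, self.c, self.d)):
            if pattern == "*":
                continue
            if len(pattern) != widths[name] or not re.fullmatch(r"[0-9?]+", pattern):
                raise CatalogError(
                    f"{name} pattern {pattern!r} must be '*' or {widths[name]} "
                    "characters of digits/'?'"
                )

    @classmethod
    def from_code(cls, code_text: str, wildcard_layers: Iterable[str] = ()) -> "QueryPattern":
        """Fully literal pattern from a code, optionally wildcarding whole layers."""
        code = ModelCode.parse(code_text)
        parts = {"a": code.a_part, "b": code.b_part, "c": code.c_part, "d": code.d_part}
        spans = LAYER_SPANS[code.profile]
        for layer in wildcard_layers:
            layer = _LAYER_ALIASES.get(layer, layer)
            if layer not in spans:
                raise CatalogError(
                    f"unknown layer {layer!r} for profile {code.profile!r}; "
                    f"valid: {', '.join(sorted(spans))}"
                )
            part, offset, width = spans[layer]
            text = parts[part]
            parts[part] = text[:offset] + "?" * width + text[offset + width :]
        return cls(parts["a"], parts["b"], parts["c"], parts["d"], code.profile)

    def to_regex(self) -> "re.Pattern[str]":
        widths = PROFILES[self.profile]

        def seg(name: str, pattern: str) -> str:
            if pattern == "*":
                return rf"[0-9]{{{widths[name]}}}"
            return pattern.replace("?", "[0-9]")

        return re.compile(
            r"CSTR09:A" + seg("A", self.a) + "B" + seg("B", self.b)
            + "C" + seg("C", self.c) + "D" + seg("D", self.d) + r"\Z"
        )

    def matches(self, code_text: str) -> bool:
        return self.to_regex().match(code_text) is not None


def search_by_code_pattern(catalog: Catalog, pattern: QueryPattern) -> RetrievalResult:
    """Records whose code matches every literal digit of ``pattern``,
    ordered by (code, record_id)."""
    if pattern.profile != catalog.profile:
        raise CatalogError(
            f"pattern profile {pattern.profile!r} does not match catalog profile "
            f"{catalog.profile!r}"
        )
    regex = pattern.to_regex()
    return RetrievalResult.from_records([r for r in catalog if regex.match(r.code)])


def neighbor_expansion(
    catalog: Catalog, base_code: str, vary: Iterable[str]
) -> RetrievalResult:
    """Related-model search: wildcard the ``vary`` layers of ``base_code``, keep
    every other digit fixed, and exclude records carrying the base code itself."""
    vary = list(vary)
    if not vary:
        raise CatalogError("vary must name at least one layer")
    base = ModelCode.parse(base_code).canonical
    pattern = QueryPattern.from_code(base, wildcard_layers=vary)
    hits = search_by_code_pattern(catalog, pattern)
    kept = [catalog[rid] for rid in hits.record_ids if catalog[rid].code != base]
    return RetrievalResult.from_records(kept)


# -- keyword baseline ------------------------------------------------------


def _norm(text: str) -> str:
    return unicodedata.normalize("NFC", text).strip()


def keyword_search(
    catalog: Catalog,
    field_terms: Mapping[str, str],
    match_mode: str = "field",
) -> RetrievalResult:
    """Field AND-matching baseline.

    Every supplied field must match its record value: substring containment for
    the long text fields (name, english_name, disease_description), byte
    equality for the short ones (cooperation, date, preservation) — both after
    Unicode NFC normalization and trimming, case-sensitive.  ``match_mode``
    may force ``"partial"`` or ``"exact"`` semantics for all fields; the
    default ``"field"`` uses the per-field schema above.
    """
    if match_mode not in {"field", "partial", "exact"}:
        raise CatalogError(f"unknown match_mode {match_mode!r}")
    searchable = PARTIAL_MATCH_FIELDS + EXACT_MATCH_FIELDS
    for name in field_terms:
        if name not in searchable:
            raise CatalogError(
                f"unknown field {name!r}; searchable fields: {', '.join(searchable)}"
            )

    def matches(record: CatalogRecord) -> bool:
        for name, term in field_terms.items():
            value = _norm(str(record.metadata.get(name, "")))
            needle = _norm(str(term))
            partial = (match_mode == "partial") or (
                match_mode == "field" and name in PARTIAL_MATCH_FIELDS
            )
            if partial:
                if needle not in value:
                    return False
            elif needle != value:
                return False
        return True

    return RetrievalResult.from_records([r for r in catalog if matches(r)])


# -- benchmark -------------------------------------------------------------


@dataclass(frozen=True)
class Query:
    """One benchmark query: a target record, the keyword terms a user of the
    old front end would type, and the code pattern the new route would use."""

    target_id: str
    old_terms: Mapping[str, str]
    new_pattern: QueryPattern


@dataclass(frozen=True)
class MethodSummary:
    one_shot_rate: Optional[float]
    mean_candidates: Optional[float]
    max_candidates: Optional[int]

    def as_dict(self) -> dict:
        return {
            "one_shot_rate": self.one_shot_rate,
            "mean_candidates": self.mean_candidates,
            "max_candidates": self.max_candidates,
        }


@dataclass(frozen=True)
class BenchmarkReport:
    """Retrieval-efficiency summary: keyword baseline vs code-pattern route."""

    n_queries: int
    old_method: MethodSummary
    new_method: MethodSummary
    schema_version: int = 1

    def as_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "n_queries": self.n_queries,
            "old_method": self.old_method.as_dict(),
            "new_method": self.new_method.as_dict(),
        }

    def __str__(self) -> str:
        def fmt(x: Optional[float]) -> str:
            return "n/a" if x is None else f"{x:g}"

        lines = [
            f"queries: {self.n_queries}",
            f"{'method':<12} {'one-shot rate':>14} {'mean cands':>12} {'max cands':>10}",
        ]
        for name, summary in (("old (keyword)", self.old_method), ("new (code)", self.new_method)):
            lines.append(
                f"{name:<12} {fmt(summary.one_shot_rate):>14} "
                f"{fmt(summary.mean_candidates):>12} {fmt(summary.max_candidates):>10}"
            )
        return "\n".join(lines)


def _summarize(one_shot: list[bool], sizes: list[int]) -> MethodSummary:
    if not sizes:
        return MethodSummary(None, None, None)
    return MethodSummary(
        one_shot_rate=sum(one_shot) / len(one_shot),
        mean_candidates=sum(sizes) / len(sizes),
        max_candidates=max(sizes),
    )


def benchmark_one_shot(catalog: Catalog, query_set: Sequence[Query]) -> BenchmarkReport:
    """Run every query through both routes and summarize.

    A query is a *one-shot* hit when the result set is exactly the single
    target record — the strictest reading of "retrieved at one time".
    """
    old_hits: list[bool] = []
    old_sizes: list[int] = []
    new_hits: list[bool] = []
    new_sizes: list[int] = []
    for query in query_set:
        if query.target_id not in catalog:
            raise CatalogError(f"unknown target record_id {query.target_id!r}")
        old = keyword_search(catalog, query.old_terms)
        new = search_by_code_pattern(catalog, query.new_pattern)
        old_hits.append(old.record_ids == (query.target_id,))
        old_sizes.append(old.candidate_count)
        new_hits.append(new.record_ids == (query.target_id,))
        new_sizes.append(new.candidate_count)
    return BenchmarkReport(
        n_queries=len(query_set),
        old_method=_summarize(old_hits, old_sizes),
        new_method=_summarize(new_hits, new_sizes),
    )
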