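"""Seeded synthetic catalogs emulating a national model-resource database.

Real model holdings are heavily clustered: a handful of disease x species x
method cells (induced mouse models of common diseases, above all) hold a large
share of all deposits, while most cells hold one model or none.  The generator
reproduces that shape by drawing each record's leaf cell from a skewed
categorical distribution — Dirichlet-distributed weights with a small
concentration parameter, plus optional explicit hotspot cells — then filling
in attributes (each independently missing with a configured probability) and
label-derived free-text metadata, and encoding a valid canonical code for
every record.

Defaults model a deposit of 865 records with one hotspot cell holding ~21% of
them; both numbers mirror the scale of the national resource the scheme was
designed for.  The true cell distribution is unpublished, so these defaults
are explicitly fictional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .catalog import Catalog, CatalogRecord, Query, QueryPattern
from .codec import (
    AttributeTriple,
    Cooperation,
    ModelRecord,
    Preservation,
    Sharing,
    encode_record,
)
from .registry import Registry

__all__ = ["GeneratorConfig", "CellKey", "generate_catalog", "make_query_set"]

#: A leaf cell named by label paths: (disease "major/intermediate",
#: species "major/species/strain", method "category"), joined with "/".
CellKey = tuple[str, str, str]

DEFAULT_HOTSPOTS: tuple[tuple[CellKey, float], ...] = (
    (
        (
            "cardiovascular disease/myocarditis",
            "laboratory animal/mouse/BALB/c",
            "induced",
        ),
        0.21,
    ),
)

_NOISE_TOKENS = (
    "cohort", "pilot", "archive", "series", "panel", "batch", "stock", "line",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions of a synthetic catalog draw.

    ``cell_skew`` is the Dirichlet concentration for the non-hotspot cell
    weights: values below 1 concentrate mass on few cells, mimicking the
    observed clustering.  ``hotspot_cells`` pins chosen cells to fixed
    probabilities (their weights must sum to < 1).
    """

    total_records: int = 865
    seed: int = 0
    cell_skew: float = 0.3
    hotspot_cells: tuple[tuple[CellKey, float], ...] = DEFAULT_HOTSPOTS
    attribute_missing_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.total_records < 1:
            raise ValueError("total_records must be >= 1")
        if self.cell_skew <= 0:
            raise ValueError("cell_skew must be > 0")
        if not 0.0 <= self.attribute_missing_rate <= 1.0:
            raise ValueError("attribute_missing_rate must be in [0, 1]")
        weights = [w for _, w in self.hotspot_cells]
        if any(w < 0 for w in weights):
            raise ValueError("hotspot weights must be >= 0")
        if sum(weights) >= 1.0:
            raise ValueError("hotspot weights must sum to < 1")


def _leaf_cells(registry: Registry) -> list[tuple]:
    diseases = list(registry.iter_nodes("A", layer="intermediate"))
    strains = list(registry.iter_nodes("B", layer="minor"))
    methods = list(registry.iter_nodes("C", layer="category"))
    if not diseases or not strains or not methods:
        raise ValueError(
            "registry must hold at least one labelled leaf in each trunk dimension"
        )
    return [(d, s, m) for d in diseases for s in strains for m in methods]


def _cell_key(cell: tuple) -> CellKey:
    d, s, m = cell
    return ("/".join(d.label_path), "/".join(s.label_path), "/".join(m.label_path))


def _cell_weights(
    cells: Sequence[tuple], config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    n = len(cells)
    weights = rng.dirichlet(np.full(n, config.cell_skew))
    if config.hotspot_cells:
        keys = [_cell_key(c) for c in cells]
        index = {k: i for i, k in enumerate(keys)}
        hot_idx: list[int] = []
        hot_w: list[float] = []
        for key, w in config.hotspot_cells:
            if key not in index:
                raise ValueError(f"hotspot cell {key!r} does not exist in the registry")
            hot_idx.append(index[key])
            hot_w.append(w)
        hot_total = float(np.sum(hot_w))
        weights[hot_idx] = 0.0
        rest = weights.sum()
        if rest > 0:
            weights *= (1.0 - hot_total) / rest
        weights[hot_idx] = hot_w
        weights /= weights.sum()
    return weights


def _draw_attributes(rng: np.random.Generator, missing_rate: float) -> AttributeTriple:
    def draw(enum_cls):
        if rng.random() < missing_rate:
            return enum_cls(0)
        present = [v for v in enum_cls if v != 0]
        return present[rng.integers(len(present))]

    return AttributeTriple(draw(Cooperation), draw(Sharing), draw(Preservation))


def _metadata(cell: tuple, attrs: AttributeTriple, rng: np.random.Generator) -> dict:
    disease, strain, method = cell
    token = _NOISE_TOKENS[rng.integers(len(_NOISE_TOKENS))]
    serial = int(rng.integers(100, 1000))
    disease_label = disease.label
    major_label = disease.parent.label if disease.parent else ""
    strain_label = strain.label
    species_label = strain.parent.label if strain.parent else ""
    method_label = method.label
    coop, share, pres = attrs.labels
    year = 2015 + int(rng.integers(8))
    month = 1 + int(rng.integers(12))
    return {
        "name": f"{disease_label} {strain_label} {species_label} {method_label} model {token} {serial}",
        "english_name": f"{method_label} {species_label} model of {disease_label} ({strain_label})",
        "disease_description": f"{major_label}: {disease_label} study {token}",
        "cooperation": "" if coop == "missing" else coop,
        "date": f"{year:04d}-{month:02d}",
        "preservation": "" if pres == "missing" else pres,
        "keywords": ";".join(
            [disease_label, species_label, strain_label, method_label]
        ),
    }


def generate_catalog(registry: Registry, config: GeneratorConfig = GeneratorConfig()) -> Catalog:
    """Draw a synthetic coded catalog; byte-identical for a given config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    cells = _leaf_cells(registry)
    weights = _cell_weights(cells, config, rng)
    cell_idx = rng.choice(len(cells), size=config.total_records, p=weights)
    records: list[CatalogRecord] = []
    for i, idx in enumerate(cell_idx):
        disease, strain, method = cells[idx]
        attrs = _draw_attributes(rng, config.attribute_missing_rate)
        record = ModelRecord(
            disease=disease.label_path,
            species=strain.label_path,
            modeling=method.label_path,
            attributes=attrs,
        )
        code = encode_record(registry, record, profile="paper")
        metadata = _metadata(cells[idx], attrs, rng)
        records.append(CatalogRecord(record_id=f"M{i:05d}", code=code, metadata=metadata))
    return Catalog(records, registry=registry, profile="paper")


def make_query_set(
    catalog: Catalog, n_queries: int, seed: int
) -> list[Query]:
    """Benchmark queries over sampled target records.

    Old-method terms are a whitespace token drawn from the target's name (so
    the keyword route always matches the target, possibly among many); the
    new-method pattern is the target's fully literal code.
    """
    if n_queries > len(catalog):
        raise ValueError(
            f"n_queries ({n_queries}) exceeds catalog size ({len(catalog)})"
        )
    rng = np.random.default_rng(seed)
    targets = rng.choice(len(catalog), size=n_queries, replace=False)
    queries: list[Query] = []
    for idx in targets:
        record = catalog.records[int(idx)]
        tokens = [t for t in str(record.metadata.get("name", "")).split() if t]
        term = tokens[rng.integers(len(tokens))] if tokens else record.record_id
        queries.append(
            Query(
                target_id=record.record_id,
                old_terms={"name": term},
                new_pattern=QueryPattern.from_code(record.code),
            )
        )
    return queries
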