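"""File round-tripping: catalogs as CSV / JSON-lines, generator configs as YAML."""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .catalog import Catalog, CatalogRecord, METADATA_FIELDS
from .registry import Registry
from .synthetic import GeneratorConfig

__all__ = [
    "CATALOG_COLUMNS",
    "read_catalog",
    "write_catalog",
    "catalog_to_dataframe",
    "catalog_from_dataframe",
    "read_generator_config",
]

CATALOG_COLUMNS = ("record_id", "code") + METADATA_FIELDS


def catalog_to_dataframe(catalog: Catalog) -> pd.DataFrame:
    rows = [
        {
            "record_id": r.record_id,
            "code": r.code,
            **{f: r.metadata.get(f, "") for f in METADATA_FIELDS},
        }
        for r in catalog
    ]
    return pd.DataFrame(rows, columns=list(CATALOG_COLUMNS))


def catalog_from_dataframe(
    frame: pd.DataFrame, registry: Optional[Registry] = None, profile: str = "paper"
) -> Catalog:
    records = [
        CatalogRecord(
            record_id=str(row["record_id"]),
            code=str(row["code"]),
            metadata={f: ("" if pd.isna(row.get(f, "")) else str(row.get(f, ""))) for f in METADATA_FIELDS},
        )
        for _, row in frame.iterrows()
    ]
    return Catalog(records, registry=registry, profile=profile)


def _is_stdio(path: Union[str, Path]) -> bool:
    return str(path) == "-"


def read_catalog(
    path: Union[str, Path],
    registry: Optional[Registry] = None,
    profile: str = "paper",
    fmt: Optional[str] = None,
) -> Catalog:
    """Read a catalog from CSV or JSON-lines; ``"-"`` reads standard input.

    The format is taken from the suffix (``.csv`` / ``.jsonl``) unless ``fmt``
    forces one.
    """
    if fmt is None:
        fmt = "jsonl" if str(path).endswith((".jsonl", ".ndjson")) else "csv"
    handle = sys.stdin if _is_stdio(path) else None
    if fmt == "jsonl":
        text = handle.read() if handle else Path(path).read_text(encoding="utf-8")
        rows = [json.loads(line) for line in text.splitlines() if line.strip()]
        frame = pd.DataFrame(rows)
    else:
        frame = pd.read_csv(handle if handle else path, dtype=str, keep_default_na=False)
    return catalog_from_dataframe(frame, registry=registry, profile=profile)


def write_catalog(catalog: Catalog, path: Union[str, Path], fmt: Optional[str] = None) -> None:
    """Write a catalog as CSV or JSON-lines; ``"-"`` writes standard output."""
    if fmt is None:
        fmt = "jsonl" if str(path).endswith((".jsonl", ".ndjson")) else "csv"
    frame = catalog_to_dataframe(catalog)
    if fmt == "jsonl":
        text = "\n".join(
            json.dumps(row, ensure_ascii=False) for row in frame.to_dict(orient="records")
        )
        if text:
            text += "\n"
        if _is_stdio(path):
            sys.stdout.write(text)
        else:
            Path(path).write_text(text, encoding="utf-8")
    else:
        if _is_stdio(path):
            frame.to_csv(sys.stdout, index=False)
        else:
            frame.to_csv(path, index=False)


def read_generator_config(path: Union[str, Path]) -> GeneratorConfig:
    """Load a :class:`GeneratorConfig` from a YAML mapping (keys as in the dataclass)."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if "hotspot_cells" in doc and doc["hotspot_cells"] is not None:
        doc["hotspot_cells"] = tuple(
            (tuple(cell), float(weight)) for cell, weight in doc["hotspot_cells"]
        )
    return GeneratorConfig(**doc)
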