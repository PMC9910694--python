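"""Controlled-vocabulary registry for the classification trunk and attribute branch.

The coding scheme classifies an animal model along three hierarchical trunk
dimensions — system disease (A), animal species (B), modeling method (C) — and
one parallel branch dimension of essential attributes (D: cooperation, sharing,
preservation).  The registry stores the labelled nodes of the trunk hierarchy,
assigns zero-padded sequence codes layer by layer, and resolves codes back to
labels.  The all-zeros code at any layer ("00"/"000") is reserved: it stands
for "this layer is empty" and never carries a label.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "LayerSpec",
    "DimensionSpec",
    "TaxonomyNode",
    "Registry",
    "RegistryError",
    "DuplicateNodeError",
    "UnknownPathError",
    "CodeFormatError",
    "CapacityError",
    "EMPTY_LAYER",
    "DIMENSIONS",
    "load_registry",
    "read_taxonomy",
    "paper_registry",
    "registry_stats",
]


class RegistryError(ValueError):
    """Base class for taxonomy/registry violations."""


class DuplicateNodeError(RegistryError):
    """A sibling with the same code or the same label already exists."""


class UnknownPathError(RegistryError, KeyError):
    """A referenced parent or code path does not resolve to a node."""

    def __str__(self) -> str:  # KeyError quotes its repr; keep the message readable
        return self.args[0] if self.args else ""


class CodeFormatError(RegistryError):
    """A code has the wrong width, non-digit characters, or is the reserved zeros."""


class CapacityError(RegistryError):
    """All assignable codes under a parent are exhausted."""


class _EmptyLayer:
    """Marker returned when a code path ends in the all-zeros supplementary code."""

    _instance: Optional["_EmptyLayer"] = None

    def __new__(cls) -> "_EmptyLayer":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "EMPTY_LAYER"


EMPTY_LAYER = _EmptyLayer()


@dataclass(frozen=True)
class LayerSpec:
    name: str
    width: int
    optional: bool = False

    def __post_init__(self) -> None:
        if self.width < 1:
            raise RegistryError(f"layer {self.name!r}: digit width must be >= 1")


@dataclass(frozen=True)
class DimensionSpec:
    letter: str
    name: str
    layers: tuple[LayerSpec, ...]
    is_trunk: bool = True

    def layer_at(self, depth: int) -> LayerSpec:
        """Layer spec at 1-based depth."""
        return self.layers[depth - 1]

    def layer_named(self, name: str) -> LayerSpec:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise RegistryError(f"dimension {self.letter}: no layer named {name!r}")

    def depth_of(self, name: str) -> int:
        for i, layer in enumerate(self.layers, start=1):
            if layer.name == name:
                return i
        raise RegistryError(f"dimension {self.letter}: no layer named {name!r}")


#: The four fixed dimensions of the coding scheme.  A/B/C form the hierarchical
#: trunk; D is the flat branch of essential attributes (one digit per attribute,
#: handled by the codec — the registry stores no D nodes).
DIMENSIONS: Mapping[str, DimensionSpec] = {
    "A": DimensionSpec(
        "A",
        "system disease",
        (LayerSpec("major", 2), LayerSpec("intermediate", 2), LayerSpec("minor", 2, optional=True)),
    ),
    "B": DimensionSpec(
        "B",
        "animal species",
        (LayerSpec("major", 2), LayerSpec("intermediate", 2), LayerSpec("minor", 3)),
    ),
    "C": DimensionSpec(
        "C",
        "modeling method",
        (LayerSpec("category", 2), LayerSpec("subcategory", 2, optional=True)),
    ),
    "D": DimensionSpec(
        "D",
        "essential attributes",
        (LayerSpec("cooperation", 1), LayerSpec("sharing", 1), LayerSpec("preservation", 1)),
        is_trunk=False,
    ),
}


@dataclass
class TaxonomyNode:
    """One labelled classification entry.

    ``code`` is zero-padded to the layer's digit width; ``parent`` is the node
    one layer up (None at the top layer).
    """

    dimension: str
    layer: str
    code: str
    label: str
    parent: Optional["TaxonomyNode"] = None
    provenance: str = "stated"

    @property
    def code_path(self) -> tuple[str, ...]:
        parts: list[str] = []
        node: Optional[TaxonomyNode] = self
        while node is not None:
            parts.append(node.code)
            node = node.parent
        return tuple(reversed(parts))

    @property
    def label_path(self) -> tuple[str, ...]:
        parts: list[str] = []
        node: Optional[TaxonomyNode] = self
        while node is not None:
            parts.append(node.label)
            node = node.parent
        return tuple(reversed(parts))

    def __repr__(self) -> str:
        return f"TaxonomyNode({self.dimension}:{'.'.join(self.code_path)} {self.label!r})"


def _is_zeros(code: str) -> bool:
    return set(code) == {"0"}


class Registry:
    """Node store with layer-aware code assignment and bidirectional lookup."""

    def __init__(self, dimensions: Mapping[str, DimensionSpec] = DIMENSIONS) -> None:
        letters = sorted(dimensions)
        if letters != ["A", "B", "C", "D"]:
            raise RegistryError("exactly the four dimensions A, B, C, D must be defined")
        self.dimensions = dict(dimensions)
        # children of a parent, keyed by the parent's code path (() = dimension root)
        self._by_code: dict[tuple[str, tuple[str, ...]], dict[str, TaxonomyNode]] = {}
        self._by_label: dict[tuple[str, tuple[str, ...]], dict[str, TaxonomyNode]] = {}
        # codes handed out by assign_next_code but not yet carrying a node
        self._reserved: dict[tuple[str, tuple[str, ...]], set[str]] = {}

    # -- insertion ---------------------------------------------------------

    def add_node(
        self,
        dimension: str,
        label: str,
        parent: Union[TaxonomyNode, Sequence[str], None] = None,
        code: Optional[str] = None,
        layer: Optional[str] = None,
        provenance: str = "stated",
    ) -> TaxonomyNode:
        """Insert a labelled node; with ``code=None`` the next sequence code is used.

        ``parent`` may be a node, a label path (sequence of labels from the top
        layer down), or None for a top-layer node.
        """
        spec = self._dimension(dimension)
        parent_node = self._resolve_parent(dimension, parent)
        depth = 1 if parent_node is None else len(parent_node.code_path) + 1
        if depth > len(spec.layers):
            raise RegistryError(
                f"dimension {dimension}: node {label!r} would sit below the deepest layer"
            )
        layer_spec = spec.layer_at(depth)
        if layer is not None and layer != layer_spec.name:
            raise RegistryError(
                f"dimension {dimension}: layer {layer!r} does not match depth-{depth} "
                f"layer {layer_spec.name!r}"
            )
        key = (dimension, parent_node.code_path if parent_node else ())
        if code is None:
            code = self.assign_next_code(dimension, parent_node)
        else:
            self._check_code(dimension, layer_spec, code)
            if code in self._by_code.get(key, {}):
                raise DuplicateNodeError(
                    f"dimension {dimension}: duplicate code {code!r} under "
                    f"{parent_node.label_path if parent_node else '(top)'}"
                )
        if label in self._by_label.get(key, {}):
            raise DuplicateNodeError(
                f"dimension {dimension}: duplicate label {label!r} under "
                f"{parent_node.label_path if parent_node else '(top)'}"
            )
        node = TaxonomyNode(dimension, layer_spec.name, code, label, parent_node, provenance)
        self._by_code.setdefault(key, {})[code] = node
        self._by_label.setdefault(key, {})[label] = node
        self._reserved.get(key, set()).discard(code)
        return node

    def assign_next_code(
        self,
        dimension: str,
        parent: Union[TaxonomyNode, Sequence[str], None] = None,
    ) -> str:
        """Smallest unused nonzero code under ``parent``, zero-padded to the layer width.

        The code is reserved, so repeated calls return strictly increasing codes
        even before nodes are inserted.  The all-zeros code is never emitted.
        """
        spec = self._dimension(dimension)
        parent_node = self._resolve_parent(dimension, parent)
        depth = 1 if parent_node is None else len(parent_node.code_path) + 1
        if depth > len(spec.layers):
            raise RegistryError(f"dimension {dimension}: no layer below the deepest layer")
        width = spec.layer_at(depth).width
        key = (dimension, parent_node.code_path if parent_node else ())
        taken = set(self._by_code.get(key, {})) | self._reserved.get(key, set())
        for value in range(1, 10**width):
            code = str(value).zfill(width)
            if code not in taken:
                self._reserved.setdefault(key, set()).add(code)
                return code
        raise CapacityError(
            f"dimension {dimension}: all {10**width - 1} codes of width {width} are used "
            f"under {parent_node.label_path if parent_node else '(top)'}"
        )

    # -- lookup ------------------------------------------------------------

    def lookup_by_code(
        self, dimension: str, code_path: Sequence[str]
    ) -> Union[TaxonomyNode, _EmptyLayer]:
        """Resolve a code path; an all-zeros tail resolves to ``EMPTY_LAYER``."""
        spec = self._dimension(dimension)
        if not code_path:
            raise UnknownPathError(f"dimension {dimension}: empty code path")
        if len(code_path) > len(spec.layers):
            raise CodeFormatError(
                f"dimension {dimension}: path {'.'.join(code_path)} is deeper than "
                f"{len(spec.layers)} layers"
            )
        node: Optional[TaxonomyNode] = None
        for depth, code in enumerate(code_path, start=1):
            layer_spec = spec.layer_at(depth)
            if len(code) != layer_spec.width or not code.isdigit():
                raise CodeFormatError(
                    f"dimension {dimension}, layer {layer_spec.name}: code {code!r} must be "
                    f"{layer_spec.width} digits"
                )
            if _is_zeros(code):
                rest = code_path[depth:]
                if any(not _is_zeros(c) for c in rest):
                    raise UnknownPathError(
                        f"dimension {dimension}: nonzero code below empty layer "
                        f"{layer_spec.name} in {'.'.join(code_path)}"
                    )
                return EMPTY_LAYER
            key = (dimension, node.code_path if node else ())
            child = self._by_code.get(key, {}).get(code)
            if child is None:
                raise UnknownPathError(
                    f"dimension {dimension}, layer {layer_spec.name}: unknown code {code!r}"
                    + (f" under {'/'.join(node.label_path)}" if node else "")
                )
            node = child
        assert node is not None
        return node

    def lookup_by_labels(self, dimension: str, label_path: Sequence[str]) -> TaxonomyNode:
        self._dimension(dimension)
        node: Optional[TaxonomyNode] = None
        for label in label_path:
            key = (dimension, node.code_path if node else ())
            child = self._by_label.get(key, {}).get(label)
            if child is None:
                raise UnknownPathError(
                    f"dimension {dimension}: unknown label {label!r}"
                    + (f" under {'/'.join(node.label_path)}" if node else "")
                )
            node = child
        if node is None:
            raise UnknownPathError(f"dimension {dimension}: empty label path")
        return node

    def children(
        self, dimension: str, parent: Union[TaxonomyNode, Sequence[str], None] = None
    ) -> list[TaxonomyNode]:
        parent_node = self._resolve_parent(dimension, parent)
        key = (dimension, parent_node.code_path if parent_node else ())
        kids = self._by_code.get(key, {})
        return [kids[c] for c in sorted(kids)]

    def iter_nodes(
        self, dimension: Optional[str] = None, layer: Optional[str] = None
    ) -> Iterator[TaxonomyNode]:
        for (dim, _parent), nodes in sorted(self._by_code.items()):
            if dimension is not None and dim != dimension:
                continue
            for code in sorted(nodes):
                node = nodes[code]
                if layer is None or node.layer == layer:
                    yield node

    def stats(self) -> dict[str, dict[str, int]]:
        """Labelled-node counts per dimension and layer (supplementary codes excluded)."""
        counts: dict[str, dict[str, int]] = {
            letter: {layer.name: 0 for layer in spec.layers}
            for letter, spec in self.dimensions.items()
            if spec.is_trunk
        }
        for node in self.iter_nodes():
            counts[node.dimension][node.layer] += 1
        return counts

    # -- helpers -----------------------------------------------------------

    def _dimension(self, letter: str) -> DimensionSpec:
        try:
            return self.dimensions[letter]
        except KeyError:
            raise RegistryError(f"unknown dimension {letter!r}") from None

    def _resolve_parent(
        self, dimension: str, parent: Union[TaxonomyNode, Sequence[str], None]
    ) -> Optional[TaxonomyNode]:
        if parent is None:
            return None
        if isinstance(parent, TaxonomyNode):
            return parent
        if len(parent) == 0:
            return None
        return self.lookup_by_labels(dimension, parent)

    @staticmethod
    def _check_code(dimension: str, layer_spec: LayerSpec, code: str) -> None:
        if len(code) != layer_spec.width or not code.isdigit():
            raise CodeFormatError(
                f"dimension {dimension}, layer {layer_spec.name}: code {code!r} must be "
                f"{layer_spec.width} digits"
            )
        if _is_zeros(code):
            raise CodeFormatError(
                f"dimension {dimension}, layer {layer_spec.name}: {code!r} is the reserved "
                "supplementary (empty-layer) code and cannot label a node"
            )


# -- loading ---------------------------------------------------------------

_PARENT_NONE = {"", "-", "–", None}


def load_registry(rows: Iterable[Mapping[str, object]]) -> Registry:
    """Build a registry from tabular rows.

    Each row holds ``dimension``, ``layer``, ``parent_path`` (labels joined with
    "/"; empty for top-layer nodes), ``label``, and an optional explicit ``code``
    (rows without one receive the next incremental code under their parent).
    Parents must appear before their children.
    """
    registry = Registry()
    for row in rows:
        dimension = str(row["dimension"]).strip()
        label = str(row["label"]).strip()
        layer = row.get("layer")
        layer = str(layer).strip() if layer not in _PARENT_NONE else None
        raw_parent = row.get("parent_path")
        if raw_parent in _PARENT_NONE or str(raw_parent).strip() in _PARENT_NONE:
            parent: Optional[list[str]] = None
        else:
            parent = [p for p in str(raw_parent).split("/") if p]
        raw_code = row.get("code")
        if raw_code in _PARENT_NONE or str(raw_code).strip() in _PARENT_NONE:
            code = None
        else:
            code = str(raw_code).strip()
        provenance = str(row.get("provenance") or "stated").strip()
        registry.add_node(dimension, label, parent, code, layer, provenance)
    return registry


def read_taxonomy(source: Union[str, Path, io.TextIOBase]) -> Registry:
    """Load a registry from a taxonomy file (tab-separated ``.tsv`` or ``.yaml``)."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text(encoding="utf-8")
        suffix = path.suffix.lower()
    else:
        text = source.read()
        suffix = ".tsv" if "\t" in text.splitlines()[0] else ".yaml"
    if suffix in {".yaml", ".yml"}:
        doc = yaml.safe_load(text)
        return load_registry(doc["nodes"])
    rows = list(csv.DictReader(io.StringIO(text), delimiter="\t"))
    return load_registry(rows)


def paper_registry() -> Registry:
    """The bundled reference taxonomy: every classification node the scheme's
    published tables and worked examples enumerate."""
    with resources.files("amrcodes.data").joinpath("paper_taxonomy.tsv").open(
        "r", encoding="utf-8"
    ) as handle:
        return read_taxonomy(handle)


def registry_stats(registry: Registry) -> dict[str, dict[str, int]]:
    """Functional alias for :meth:`Registry.stats`."""
    return registry.stats()
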