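"""Record <-> code conversion, code validation, and national-identifier parsing.

A canonical model code concatenates five parts::

    CSTR09:A<disease>B<species>C<method>D<attributes>

``CSTR09`` is the fixed identification prefix (Chinese science-and-technology
resource, type 09 = experimental materials).  A, B, C carry the hierarchical
trunk classification as fixed-width, zero-padded layer codes; D carries the
three parallel essential-attribute digits (cooperation, sharing, preservation).
Two width profiles exist: the ``paper`` profile omits the optional disease
minor layer and method subcategory (A is 4 digits, C is 2); the ``extended``
profile includes them, zero-filled when empty (A is 6 digits, C is 4).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Optional, Sequence, Union

from .registry import (
    EMPTY_LAYER,
    Registry,
    RegistryError,
    TaxonomyNode,
    UnknownPathError,
)

__all__ = [
    "IDENTIFICATION",
    "PROFILES",
    "Cooperation",
    "Sharing",
    "Preservation",
    "AttributeTriple",
    "ModelRecord",
    "ModelCode",
    "NationalIdentifier",
    "Violation",
    "CodecError",
    "canonicalize",
    "encode_record",
    "decode_code",
    "validate_code",
    "parse_national_identifier",
    "combinatorial_capacity",
    "enumerate_valid_d_parts",
]

IDENTIFICATION = "CSTR09"

#: Segment digit widths per profile.
PROFILES = {
    "paper": {"A": 4, "B": 7, "C": 2, "D": 3},
    "extended": {"A": 6, "B": 7, "C": 4, "D": 3},
}

#: Trunk layers present in each profile, in code order.
PROFILE_LAYERS = {
    "paper": {"A": ("major", "intermediate"), "B": ("major", "intermediate", "minor"), "C": ("category",)},
    "extended": {
        "A": ("major", "intermediate", "minor"),
        "B": ("major", "intermediate", "minor"),
        "C": ("category", "subcategory"),
    },
}


class CodecError(ValueError):
    """A record or code cannot be converted; carries the violation list."""

    def __init__(self, violations: Sequence["Violation"]):
        self.violations = list(violations)
        super().__init__("; ".join(str(v) for v in violations))


class Cooperation(IntEnum):
    MISSING = 0
    INDEPENDENCE = 1
    COOPERATION = 2
    OUTSOURCING = 3


class Sharing(IntEnum):
    MISSING = 0
    PAID = 1
    FREE = 2


class Preservation(IntEnum):
    MISSING = 0
    LIVE = 1
    FROZEN = 2


_ATTRIBUTE_ALIASES = {
    Cooperation: {"independent": "INDEPENDENCE", "independence": "INDEPENDENCE",
                  "cooperation": "COOPERATION", "cooperative": "COOPERATION",
                  "outsourcing": "OUTSOURCING", "missing": "MISSING", "": "MISSING"},
    Sharing: {"paid": "PAID", "free": "FREE", "missing": "MISSING", "": "MISSING"},
    Preservation: {"live": "LIVE", "living": "LIVE", "frozen": "FROZEN",
                   "missing": "MISSING", "": "MISSING"},
}


def _parse_attribute(enum_cls: type, value: object) -> IntEnum:
    if isinstance(value, enum_cls):
        return value  # type: ignore[return-value]
    if isinstance(value, int):
        return enum_cls(value)  # type: ignore[call-arg]
    if isinstance(value, str):
        text = value.strip().lower()
        if text.isdigit():
            return enum_cls(int(text))  # type: ignore[call-arg]
        alias = _ATTRIBUTE_ALIASES[enum_cls].get(text)
        if alias is not None:
            return enum_cls[alias]  # type: ignore[index]
    raise ValueError(f"cannot interpret {value!r} as {enum_cls.__name__}")


@dataclass(frozen=True)
class AttributeTriple:
    """The three branch attributes; digit 0 is the supplementary code for missing data."""

    cooperation: Cooperation = Cooperation.MISSING
    sharing: Sharing = Sharing.MISSING
    preservation: Preservation = Preservation.MISSING

    @property
    def digits(self) -> str:
        return f"{self.cooperation}{self.sharing}{self.preservation}"

    @classmethod
    def from_digits(cls, d_part: str) -> "AttributeTriple":
        violations = _d_part_violations(d_part)
        if violations:
            raise CodecError(violations)
        return cls(Cooperation(int(d_part[0])), Sharing(int(d_part[1])), Preservation(int(d_part[2])))

    @classmethod
    def from_values(cls, cooperation: object = 0, sharing: object = 0, preservation: object = 0) -> "AttributeTriple":
        return cls(
            _parse_attribute(Cooperation, cooperation),  # type: ignore[arg-type]
            _parse_attribute(Sharing, sharing),  # type: ignore[arg-type]
            _parse_attribute(Preservation, preservation),  # type: ignore[arg-type]
        )

    @property
    def labels(self) -> tuple[str, str, str]:
        return (
            self.cooperation.name.lower(),
            self.sharing.name.lower(),
            self.preservation.name.lower(),
        )


def _d_part_violations(d_part: str) -> list["Violation"]:
    out: list[Violation] = []
    if len(d_part) != 3 or not d_part.isdigit():
        out.append(Violation("D", f"D part {d_part!r} must be exactly 3 digits"))
        return out
    ranges = (("cooperation", 3), ("sharing", 2), ("preservation", 2))
    for pos, ((name, top), ch) in enumerate(zip(ranges, d_part)):
        if int(ch) > top:
            out.append(
                Violation("D", f"invalid {name} digit {ch!r} (valid: 0-{top})", layer=name, position=pos)
            )
    return out


def enumerate_valid_d_parts() -> list[str]:
    """All valid D parts in ascending order: {0-3} x {0-2} x {0-2}, 36 strings."""
    return [
        f"{c}{s}{p}" for c in range(4) for s in range(3) for p in range(3)
    ]


@dataclass
class ModelRecord:
    """A model's classification label paths, attributes, and free-text metadata.

    Label paths run from the top layer down (e.g. disease = (major, intermediate)),
    and may stop early when lower layers are empty.
    """

    disease: tuple[str, ...]
    species: tuple[str, ...]
    modeling: tuple[str, ...]
    attributes: AttributeTriple = field(default_factory=AttributeTriple)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.disease = tuple(self.disease)
        self.species = tuple(self.species)
        self.modeling = tuple(self.modeling)


@dataclass(frozen=True)
class ModelCode:
    """Parsed five-part code with a canonical string form."""

    a_part: str
    b_part: str
    c_part: str
    d_part: str
    profile: str = "paper"
    identification: str = IDENTIFICATION

    def __post_init__(self) -> None:
        widths = PROFILES.get(self.profile)
        if widths is None:
            raise ValueError(f"unknown profile {self.profile!r}")
        for part_name, part in zip("ABCD", (self.a_part, self.b_part, self.c_part, self.d_part)):
            if len(part) != widths[part_name] or not part.isdigit():
                raise ValueError(
                    f"{part_name} part {part!r} must be {widths[part_name]} digits "
                    f"in the {self.profile} profile"
                )

    @property
    def canonical(self) -> str:
        return (
            f"{self.identification}:A{self.a_part}B{self.b_part}"
            f"C{self.c_part}D{self.d_part}"
        )

    def __str__(self) -> str:
        return self.canonical

    @classmethod
    def parse(cls, text: str) -> "ModelCode":
        violations, code = _parse_code(text)
        if violations:
            raise CodecError(violations)
        assert code is not None
        return code


_CODE_RE = re.compile(r"^(?P<prefix>[A-Z0-9]{6}):A(?P<a>\d+)B(?P<b>\d+)C(?P<c>\d+)D(?P<d>\d+)$")


def canonicalize(text: str) -> str:
    """Uppercase and strip all whitespace (tables print a space after the colon)."""
    return re.sub(r"\s+", "", text).upper()


def _parse_code(text: str) -> tuple[list["Violation"], Optional[ModelCode]]:
    cleaned = canonicalize(text)
    match = _CODE_RE.match(cleaned)
    if not match:
        return [Violation("code", f"text {text!r} does not match CSTR09:A…B…C…D… grammar")], None
    violations: list[Violation] = []
    if match["prefix"] != IDENTIFICATION:
        violations.append(
            Violation("identification", f"prefix {match['prefix']!r} must be {IDENTIFICATION!r}")
        )
    a, b, c, d = match["a"], match["b"], match["c"], match["d"]
    profile = None
    for name, widths in PROFILES.items():
        if (len(a), len(b), len(c), len(d)) == (widths["A"], widths["B"], widths["C"], widths["D"]):
            profile = name
            break
    if profile is None:
        for part_name, part in zip("ABCD", (a, b, c, d)):
            allowed = sorted({PROFILES[p][part_name] for p in PROFILES})
            if len(part) not in allowed:
                violations.append(
                    Violation(
                        part_name,
                        f"{part_name} part {part!r} has width {len(part)}; expected "
                        + " or ".join(map(str, allowed)),
                    )
                )
        if not any(v.part in set("ABCD") for v in violations):
            violations.append(Violation("code", "segment widths mix the paper and extended profiles"))
        return violations, None
    if violations:
        return violations, None
    return [], ModelCode(a, b, c, d, profile)


@dataclass(frozen=True)
class Violation:
    """One machine-readable validation finding."""

    part: str
    message: str
    layer: Optional[str] = None
    position: Optional[int] = None

    def __str__(self) -> str:
        where = self.part if self.layer is None else f"{self.part}.{self.layer}"
        return f"[{where}] {self.message}"


# -- encode / decode -------------------------------------------------------


def _encode_trunk(
    registry: Registry, dimension: str, labels: Sequence[str], layers: tuple[str, ...]
) -> str:
    spec = registry.dimensions[dimension]
    if len(labels) == 0:
        raise CodecError([Violation(dimension, "at least the top layer label is required")])
    if len(labels) > len(layers):
        raise CodecError(
            [
                Violation(
                    dimension,
                    f"label path {'/'.join(labels)} is deeper than the profile's "
                    f"{len(layers)} layer(s)",
                )
            ]
        )
    try:
        node = registry.lookup_by_labels(dimension, labels)
    except UnknownPathError as exc:
        raise CodecError([Violation(dimension, str(exc))]) from exc
    parts = list(node.code_path)
    for layer_name in layers[len(parts):]:
        parts.append("0" * spec.layer_named(layer_name).width)
    return "".join(parts)


def encode_record(registry: Registry, record: ModelRecord, profile: str = "paper") -> str:
    """Encode a record's classification and attributes to the canonical code string.

    Absent optional layers are omitted under the ``paper`` profile and
    zero-filled under ``extended``; missing attributes encode as digit 0.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    layers = PROFILE_LAYERS[profile]
    code = ModelCode(
        a_part=_encode_trunk(registry, "A", record.disease, layers["A"]),
        b_part=_encode_trunk(registry, "B", record.species, layers["B"]),
        c_part=_encode_trunk(registry, "C", record.modeling, layers["C"]),
        d_part=record.attributes.digits,
        profile=profile,
    )
    return code.canonical


def _split_trunk(part: str, widths: Iterable[int]) -> list[str]:
    out, pos = [], 0
    for width in widths:
        out.append(part[pos : pos + width])
        pos += width
    return out

def _decode_trunk(
    registry: Registry, dimension: str, part: str, layers: tuple[str, ...]
) -> tuple[str, ...]:
    spec = registry.dimensions[dimension]
    widths = [spec.layer_named(name).width for name in layers]
    segments = _split_trunk(part, widths)
    # trailing zero segments mean "layer empty": drop them before lookup
    while segments and set(segments[-1]) == {"0"}:
        segments.pop()
    if not segments:
        raise CodecError(
            [Violation(dimension, f"{dimension} part {part!r} has no nonzero layer")]
        )
    try:
        node = registry.lookup_by_code(dimension, segments)
    except RegistryError as exc:
        raise CodecError([Violation(dimension, str(exc))]) from exc
    assert node is not EMPTY_LAYER and isinstance(node, TaxonomyNode)
    return node.label_path


def decode_code(registry: Registry, code_text: str) -> ModelRecord:
    """Resolve a code back to a record skeleton (labels + attributes, no metadata).

    ``decode_code(registry, encode_record(registry, r))`` reproduces ``r``'s
    classification and attributes exactly.
    """
    code = ModelCode.parse(code_text)
    layers = PROFILE_LAYERS[code.profile]
    d_violations = _d_part_violations(code.d_part)
    if d_violations:
        raise CodecError(d_violations)
    return ModelRecord(
        disease=_decode_trunk(registry, "A", code.a_part, layers["A"]),
        species=_decode_trunk(registry, "B", code.b_part, layers["B"]),
        modeling=_decode_trunk(registry, "C", code.c_part, layers["C"]),
        attributes=AttributeTriple.from_digits(code.d_part),
    )


def validate_code(registry: Registry, code_text: str) -> list[Violation]:
    """All violations found in ``code_text``; an empty list means the code is valid."""
    violations, code = _parse_code(code_text)
    if code is None:
        return violations
    out = list(violations)
    layers = PROFILE_LAYERS[code.profile]
    for dimension, part in (("A", code.a_part), ("B", code.b_part), ("C", code.c_part)):
        try:
            _decode_trunk(registry, dimension, part, layers[dimension])
        except CodecError as exc:
            out.extend(exc.violations)
    out.extend(_d_part_violations(code.d_part))
    return out


# -- national resource identifier -----------------------------------------


@dataclass(frozen=True)
class NationalIdentifier:
    """Platform-level resource identifier, e.g. ``CSTR:16397.09.0C01001234``.

    Four fixed-width components: resource code (4 characters), registered
    institution code (5), resource type (2), and the unit's self-compiled
    resource code (10) — 21 content characters in total.
    """

    resource_code: str
    institution_code: str
    resource_type: str
    unit_code: str

    _WIDTHS = (4, 5, 2, 10)

    def __post_init__(self) -> None:
        parts = (self.resource_code, self.institution_code, self.resource_type, self.unit_code)
        names = ("resource_code", "institution_code", "resource_type", "unit_code")
        for name, part, width in zip(names, parts, self._WIDTHS):
            if len(part) != width:
                raise ValueError(f"{name} {part!r} must be exactly {width} characters")

    @property
    def content_length(self) -> int:
        return sum(self._WIDTHS)

    def compose(self) -> str:
        return f"{self.resource_code}:{self.institution_code}.{self.resource_type}.{self.unit_code}"

    def __str__(self) -> str:
        return self.compose()


def parse_national_identifier(text: str) -> NationalIdentifier:
    """Parse ``resource:institution.type.unit`` with exact component widths 4/5/2/10."""
    parts = text.strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"identifier {text!r} must contain exactly one ':'")
    tail = parts[1].split(".")
    if len(tail) != 3:
        raise ValueError(f"identifier {text!r} must have institution.type.unit after the ':'")
    return NationalIdentifier(parts[0], tail[0], tail[1], tail[2])


def combinatorial_capacity(major_counts: Sequence[int]) -> int:
    """Maximum number of leaf cells a set of per-dimension category counts yields.

    With 10 disease, 6 species, and 3 method categories the trunk alone
    separates at most 10*6*3 = 180 cells — the motivation for deeper layers
    plus the attribute branch.
    """
    counts = list(major_counts)
    if not counts:
        raise ValueError("major_counts must be non-empty")
    if any(c < 1 for c in counts):
        raise ValueError("all counts must be >= 1")
    return math.prod(counts)
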