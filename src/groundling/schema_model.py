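"""Knowledge-schema formalism: classes, typed attributes, prefix and value-set constraints.

A knowledge schema constrains the shape of instances extracted from text.
It is a collection of named classes; each class has an ordered list of
attributes whose *range* is a primitive type (string/number/boolean),
another class (embedded inline or passed by reference), or a value set.
Classes that represent named entities additionally carry identifier-prefix
constraints (``id_prefixes``, upper-case CURIE prefixes) and optionally a
value set restricting which terms are acceptable groundings.

Schema documents are written in a small YAML dialect (a strict subset of
the LinkML surface syntax): top-level ``name``, ``prefixes``,
``entry_class``, ``classes`` and ``enums``; per-class ``attributes``,
``id_prefixes``, ``values_from`` and ``named_entity``; per-attribute
``range``, ``multivalued``, ``inlined``, ``identifier``, ``prompt`` and
``annotations.prompt``.
"""

from __future__ import annotations

from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, Field

PRIMITIVE_RANGES = ("string", "number", "boolean")

RangeKind = Literal["primitive", "class-inlined", "class-reference", "value-set"]


class SchemaError(ValueError):
    """Base class for schema-document problems."""


class SchemaParseError(SchemaError):
    """The document is not well-formed in the schema dialect."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class UnresolvedRangeError(SchemaError):
    """An attribute range names neither a primitive, a class, nor a value set."""


class SchemaCycleError(SchemaError):
    """The graph of inlined class-valued ranges contains a cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("cyclic inlined ranges: " + " -> ".join(cycle + cycle[:1]))


class ValueSetSpec(BaseModel):
    """A set of permissible grounded values, given explicitly or as an ontology query.

    Exactly one of ``extensional`` (a fixed list of CURIEs) or
    ``intensional`` (include/exclude ontology branches, resolved against a
    term-parent edge table at grounding time) is present.
    """

    name: str
    extensional: Optional[list[str]] = None
    intensional: Optional[dict[str, Any]] = None


class AttributeDefinition(BaseModel):
    name: str
    prompt: Optional[str] = None
    multivalued: bool = False
    identifier: bool = False
    inlined: bool = False
    range: str = "string"


class ClassDefinition(BaseModel):
    name: str
    attributes: list[AttributeDefinition] = Field(default_factory=list)
    id_spaces: list[str] = Field(default_factory=list)
    value_set: Optional[ValueSetSpec] = None
    is_named_entity: bool = False

    def attribute(self, name: str) -> AttributeDefinition:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(f"{self.name} has no attribute {name!r}")


class RangeDescriptor(BaseModel):
    kind: RangeKind
    target: str


class SchemaDefinition(BaseModel):
    """A full knowledge schema: classes, prefix declarations, entry point."""

    name: str
    classes: list[ClassDefinition]
    prefix_declarations: dict[str, str] = Field(default_factory=dict)
    entry_class: str
    value_sets: dict[str, ValueSetSpec] = Field(default_factory=dict)

    def class_named(self, name: str) -> ClassDefinition:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(f"schema {self.name} has no class {name!r}")

    def has_class(self, name: str) -> bool:
        return any(c.name == name for c in self.classes)


class Issue(BaseModel):
    severity: Literal["error", "warning"]
    path: str
    message: str


def _attr_from_mapping(name: str, spec: Any) -> AttributeDefinition:
    if spec is None:
        spec = {}
    if not isinstance(spec, dict):
        raise SchemaParseError(f"attribute {name!r} must map to a mapping, got {type(spec).__name__}")
    prompt = spec.get("prompt")
    ann = spec.get("annotations")
    if prompt is None and isinstance(ann, dict):
        prompt = ann.get("prompt")
    return AttributeDefinition(
        name=name,
        prompt=prompt,
        multivalued=bool(spec.get("multivalued", False)),
        identifier=bool(spec.get("identifier", False)),
        inlined=bool(spec.get("inlined", False)),
        range=str(spec.get("range", "string")),
    )


def _value_set_from_mapping(name: str, spec: Any) -> ValueSetSpec:
    if not isinstance(spec, dict):
        raise SchemaParseError(f"enum {name!r} must map to a mapping")
    extensional = spec.get("permissible_values")
    intensional = spec.get("reachable_from")
    if (extensional is None) == (intensional is None):
        raise SchemaParseError(
            f"enum {name!r}: exactly one of permissible_values / reachable_from required"
        )
    if extensional is not None:
        if isinstance(extensional, dict):
            extensional = list(extensional)
        return ValueSetSpec(name=name, extensional=[str(v) for v in extensional])
    return ValueSetSpec(name=name, intensional=dict(intensional))


def load_schema(document: str) -> SchemaDefinition:
    """Parse a schema document in the YAML dialect into a :class:`SchemaDefinition`.

    Attribute order is preserved from the document.  Raises
    :class:`SchemaParseError` on malformed documents (naming the line for
    YAML syntax errors), :class:`UnresolvedRangeError` when an attribute
    range does not resolve, and :class:`SchemaCycleError` when inlined
    class-valued ranges form a cycle.
    """
    try:
        data = yaml.safe_load(document)
    except yaml.YAMLError as exc:
        line = None
        mark = getattr(exc, "problem_mark", None)
        if mark is not None:
            line = mark.line + 1
        raise SchemaParseError(f"invalid YAML: {exc}", line=line) from exc
    if not isinstance(data, dict) or "classes" not in data:
        raise SchemaParseError("document must be a mapping with a 'classes' section")
    raw_classes = data["classes"]
    if not isinstance(raw_classes, dict) or not raw_classes:
        raise SchemaParseError("'classes' must be a non-empty mapping")

    value_sets: dict[str, ValueSetSpec] = {}
    for vs_name, vs_spec in (data.get("enums") or {}).items():
        value_sets[str(vs_name)] = _value_set_from_mapping(str(vs_name), vs_spec)

    classes: list[ClassDefinition] = []
    for cls_name, cls_spec in raw_classes.items():
        cls_spec = cls_spec or {}
        if not isinstance(cls_spec, dict):
            raise SchemaParseError(f"class {cls_name!r} must map to a mapping")
        attributes = [
            _attr_from_mapping(str(a_name), a_spec)
            for a_name, a_spec in (cls_spec.get("attributes") or {}).items()
        ]
        id_spaces = [str(p) for p in (cls_spec.get("id_prefixes") or [])]
        values_from = cls_spec.get("values_from")
        value_set = None
        if values_from is not None:
            if values_from not in value_sets:
                raise SchemaParseError(f"class {cls_name!r}: unknown value set {values_from!r}")
            value_set = value_sets[values_from]
        is_named_entity = bool(
            cls_spec.get("named_entity", bool(id_spaces) or value_set is not None)
        )
        classes.append(
            ClassDefinition(
                name=str(cls_name),
                attributes=attributes,
                id_spaces=id_spaces,
                value_set=value_set,
                is_named_entity=is_named_entity,
            )
        )

    entry_class = str(data.get("entry_class", classes[0].name))
    schema = SchemaDefinition(
        name=str(data.get("name", "schema")),
        classes=classes,
        prefix_declarations={str(k): str(v) for k, v in (data.get("prefixes") or {}).items()},
        entry_class=entry_class,
        value_sets=value_sets,
    )
    _check_structure(schema)
    return schema


def _check_structure(schema: SchemaDefinition) -> None:
    names = [c.name for c in schema.classes]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SchemaParseError(f"duplicate class names: {', '.join(dupes)}")
    if not schema.has_class(schema.entry_class):
        raise SchemaParseError(f"entry class {schema.entry_class!r} is not a declared class")
    for cls in schema.classes:
        attr_names = [a.name for a in cls.attributes]
        if len(set(attr_names)) != len(attr_names):
            raise SchemaParseError(f"class {cls.name!r} has duplicate attribute names")
        for attr in cls.attributes:
            if attr.range in PRIMITIVE_RANGES or attr.range in schema.value_sets:
                continue
            if not schema.has_class(attr.range):
                raise UnresolvedRangeError(
                    f"{cls.name}.{attr.name}: range {attr.range!r} is not a primitive, "
                    "declared class, or value set"
                )
    _check_inlining_acyclic(schema)


def _check_inlining_acyclic(schema: SchemaDefinition) -> None:
    # DFS over the inlined-range graph; a back edge is a load-time error
    # because recursive extraction only terminates on acyclic inlining.
    edges: dict[str, list[str]] = {c.name: [] for c in schema.classes}
    for cls in schema.classes:
        for attr in cls.attributes:
            if attr.inlined and schema.has_class(attr.range):
                edges[cls.name].append(attr.range)
    WHITE, GREY, BLACK = 0, 1, 2
    color = {n: WHITE for n in edges}
    stack: list[str] = []

    def visit(node: str) -> None:
        color[node] = GREY
        stack.append(node)
        for nxt in edges[node]:
            if color[nxt] == GREY:
                cycle = stack[stack.index(nxt):]
                raise SchemaCycleError(cycle)
            if color[nxt] == WHITE:
                visit(nxt)
        stack.pop()
        color[node] = BLACK

    for node in edges:
        if color[node] == WHITE:
            visit(node)


def validate_schema(schema: SchemaDefinition) -> list[Issue]:
    """Check all type invariants; returns an empty list iff the schema is valid.

    Issues are data (severity, dotted class/attribute path, message), never
    exceptions.
    """
    issues: list[Issue] = []
    for cls in schema.classes:
        for prefix in cls.id_spaces:
            if prefix != prefix.upper():
                issues.append(
                    Issue(
                        severity="error",
                        path=cls.name,
                        message=f"id prefix {prefix!r} must be upper-case",
                    )
                )
        if cls.value_set is not None and not cls.is_named_entity:
            issues.append(
                Issue(
                    severity="error",
                    path=cls.name,
                    message="a class with a value set must be a named entity",
                )
            )
        n_identifier = sum(1 for a in cls.attributes if a.identifier)
        if n_identifier > 1:
            issues.append(
                Issue(
                    severity="error",
                    path=cls.name,
                    message=f"{n_identifier} identifier attributes; at most one allowed",
                )
            )
        for attr in cls.attributes:
            path = f"{cls.name}.{attr.name}"
            if attr.inlined and not schema.has_class(attr.range):
                issues.append(
                    Issue(
                        severity="error",
                        path=path,
                        message="inlined=true requires a class-valued range",
                    )
                )
    return issues


def resolve_range(schema: SchemaDefinition, attribute: AttributeDefinition) -> RangeDescriptor:
    """Classify an attribute's range as primitive, inlined class, class reference, or value set."""
    if attribute.range in PRIMITIVE_RANGES:
        return RangeDescriptor(kind="primitive", target=attribute.range)
    if attribute.range in schema.value_sets:
        return RangeDescriptor(kind="value-set", target=attribute.range)
    if schema.has_class(attribute.range):
        kind = "class-inlined" if attribute.inlined else "class-reference"
        return RangeDescriptor(kind=kind, target=attribute.range)
    raise UnresolvedRangeError(f"range {attribute.range!r} does not resolve")


def serialize_schema(schema: SchemaDefinition) -> str:
    """Render a schema back to the YAML dialect (round-trips through :func:`load_schema`)."""
    doc: dict[str, Any] = {"name": schema.name, "entry_class": schema.entry_class}
    if schema.prefix_declarations:
        doc["prefixes"] = dict(schema.prefix_declarations)
    if schema.value_sets:
        enums: dict[str, Any] = {}
        for name, vs in schema.value_sets.items():
            if vs.extensional is not None:
                enums[name] = {"permissible_values": list(vs.extensional)}
            else:
                enums[name] = {"reachable_from": dict(vs.intensional or {})}
        doc["enums"] = enums
    classes: dict[str, Any] = {}
    for cls in schema.classes:
        spec: dict[str, Any] = {}
        if cls.attributes:
            attrs: dict[str, Any] = {}
            for a in cls.attributes:
                a_spec: dict[str, Any] = {"range": a.range}
                if a.prompt is not None:
                    a_spec["prompt"] = a.prompt
                for flag in ("multivalued", "identifier", "inlined"):
                    if getattr(a, flag):
                        a_spec[flag] = True
                attrs[a.name] = a_spec
            spec["attributes"] = attrs
        if cls.id_spaces:
            spec["id_prefixes"] = list(cls.id_spaces)
        if cls.value_set is not None:
            spec["values_from"] = cls.value_set.name
        spec["named_entity"] = cls.is_named_entity
        classes[cls.name] = spec
    doc["classes"] = classes
    return yaml.safe_dump(doc, sort_keys=False)
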