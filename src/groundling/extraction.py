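"""Extraction core: heuristic pseudo-YAML parsing and recursive descent.

A language model asked for ``name: value`` lines rarely returns strict
YAML, so completions are parsed heuristically and totally: any input —
including arbitrary garbage — yields an instance (possibly empty) plus
skip records, never an exception.  Values are parsed by the range of the
matched attribute: primitives are kept as-is, references to named-entity
classes and value sets are marked for grounding, and inlined classes
trigger a recursive prompt/complete/parse cycle on the value text, which
terminates because the inlined-range graph is acyclic by schema-load
invariant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Union

from .completion import (
    Chunk,
    CompletionBackend,
    CompletionConfig,
    CompletionRecord,
    chunk_text,
    complete,
)
from .grounding import GroundedRef, Grounder, Placeholder, placeholder_label
from .prompt_builder import SPLIT_INSTRUCTIONS, generate_prompt
from .schema_model import (
    AttributeDefinition,
    ClassDefinition,
    SchemaDefinition,
    resolve_range,
)

#: Right-hand sides treated as "no value" (common language-model fillers).
DEFAULT_NULL_VALUES = frozenset({"", "none", "n/a", "not mentioned", "not specified", "null"})


@dataclass(frozen=True)
class Literal:
    """A primitive value (string, number, or boolean) kept as extracted."""

    value: Union[str, int, float, bool]


@dataclass(frozen=True)
class PendingRef:
    """A span naming an entity, awaiting grounding."""

    span: str


Value = Union[Literal, PendingRef, GroundedRef, Placeholder, "InstanceNode"]


@dataclass
class InstanceNode:
    """One extracted instance: an attribute → value(s) map conforming to a class.

    Multivalued attributes always hold a list (possibly empty);
    single-valued attributes are present only once populated.
    """

    class_name: str
    values: dict[str, Union[Value, list[Value]]] = field(default_factory=dict)

    def get(self, attribute: str, default=None):
        return self.values.get(attribute, default)


@dataclass(frozen=True)
class SkipRecord:
    line: str
    reason: str


@dataclass
class ParseLog:
    """Recoverable irregularities met while parsing completions."""

    skipped: list[SkipRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)


@dataclass
class ParseConfig:
    delimiter: str = ";"
    null_values: frozenset = DEFAULT_NULL_VALUES
    coerce_numbers: bool = True


@dataclass
class ExtractionConfig:
    completion: CompletionConfig = field(default_factory=CompletionConfig)
    parse: ParseConfig = field(default_factory=ParseConfig)
    instructions: str = SPLIT_INSTRUCTIONS
    wrap_prompts: bool = True
    chunk: bool = False
    window: int = 2500
    overlap: int = 250


@dataclass
class ExtractionResult:
    """Root instance plus full provenance of how it was produced."""

    root: InstanceNode
    schema_name: str
    class_name: str
    records: list[CompletionRecord] = field(default_factory=list)
    chunks: list[Chunk] = field(default_factory=list)
    unresolved: list[Placeholder] = field(default_factory=list)
    log: ParseLog = field(default_factory=ParseLog)


class InvalidMergeError(ValueError):
    """Chunk results to merge do not instantiate the same class."""


_KEY_WS = re.compile(r"\s+")
_BULLET = re.compile(r"^-\s+")


def _normalize_key(text: str) -> str:
    return _KEY_WS.sub("_", text.strip()).casefold()


def _clean_value(text: str) -> str:
    text = text.strip()
    if len(text) >= 2 and text[0] == text[-1] and text[0] in "\"'":
        text = text[1:-1].strip()
    return text


def empty_instance(schema: SchemaDefinition, class_name: str) -> InstanceNode:
    cls = schema.class_named(class_name)
    return InstanceNode(
        class_name=class_name,
        values={a.name: [] for a in cls.attributes if a.multivalued},
    )


Recurse = Callable[[str, str], InstanceNode]


def _coerce_primitive(
    token: str, target: str, config: ParseConfig, log: Optional[ParseLog]
) -> Literal:
    if target == "number" and config.coerce_numbers:
        try:
            return Literal(value=int(token))
        except ValueError:
            pass
        try:
            return Literal(value=float(token))
        except ValueError:
            if log is not None:
                log.warnings.append(f"could not coerce {token!r} to a number; kept as string")
            return Literal(value=token)
    if target == "boolean":
        folded = token.casefold()
        if folded in {"true", "yes"}:
            return Literal(value=True)
        if folded in {"false", "no"}:
            return Literal(value=False)
        if log is not None:
            log.warnings.append(f"could not coerce {token!r} to a boolean; kept as string")
    return Literal(value=token)


def parse_value(
    value_text: str,
    attribute: AttributeDefinition,
    schema: SchemaDefinition,
    *,
    recurse: Optional[Recurse] = None,
    log: Optional[ParseLog] = None,
    config: Optional[ParseConfig] = None,
) -> Union[Value, list[Value], None]:
    """Parse one right-hand side according to the attribute's range and cardinality.

    Multivalued values are first split on the delimiter (default ``;``)
    and each token parsed independently.  Primitive ranges keep the value
    as-is (with opt-in number/boolean coercion); named-entity references
    and value-set ranges become :class:`PendingRef` tokens for the
    grounding step; inlined class ranges recurse with the token as the new
    input text (no recursion callback: the raw token is kept as a
    literal).
    """
    config = config or ParseConfig()
    desc = resolve_range(schema, attribute)

    def one(token: str) -> Value:
        if desc.kind == "primitive":
            return _coerce_primitive(token, desc.target, config, log)
        if desc.kind in ("class-reference", "value-set"):
            return PendingRef(span=token)
        # class-inlined
        if recurse is not None:
            return recurse(desc.target, token)
        return Literal(value=token)

    if attribute.multivalued:
        tokens = [_clean_value(t) for t in value_text.split(config.delimiter)]
        tokens = [t for t in tokens if t and t.casefold() not in config.null_values]
        return [one(t) for t in tokens]
    cleaned = _clean_value(value_text)
    if not cleaned or cleaned.casefold() in config.null_values:
        return None
    return one(cleaned)


def parse_completion(
    raw: str,
    schema: SchemaDefinition,
    class_name: str,
    *,
    recurse: Optional[Recurse] = None,
    log: Optional[ParseLog] = None,
    config: Optional[ParseConfig] = None,
) -> InstanceNode:
    """Heuristically parse a pseudo-YAML completion into an (ungrounded) instance.

    Total on arbitrary text: lines are split on newlines, each split at
    the first ``:``; the left part is matched case-insensitively against
    the class's attribute names with whitespace normalized to underscores;
    unmatched lines are recorded in ``log`` and skipped.  Duplicate lines:
    first wins for single-valued attributes, concatenation for multivalued.
    """
    config = config or ParseConfig()
    cls = schema.class_named(class_name)
    instance = empty_instance(schema, class_name)
    lookup = {_normalize_key(a.name): a for a in cls.attributes}

    for line in raw.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        stripped = _BULLET.sub("", stripped)
        if ":" not in stripped:
            if log is not None:
                log.skipped.append(SkipRecord(line=line, reason="no colon"))
            continue
        key_part, _, value_part = stripped.partition(":")
        key = _normalize_key(key_part)
        if not key:
            if log is not None:
                log.skipped.append(SkipRecord(line=line, reason="empty key"))
            continue
        attribute = lookup.get(key)
        if attribute is None:
            if log is not None:
                log.skipped.append(SkipRecord(line=line, reason=f"unknown attribute {key!r}"))
            continue
        parsed = parse_value(
            value_part, attribute, schema, recurse=recurse, log=log, config=config
        )
        if attribute.multivalued:
            assert isinstance(parsed, list)
            existing = instance.values.setdefault(attribute.name, [])
            existing.extend(parsed)
        else:
            if attribute.name in instance.values:
                if log is not None:
                    log.warnings.append(
                        f"duplicate line for single-valued {cls.name}.{attribute.name}; first wins"
                    )
                continue
            if parsed is not None:
                instance.values[attribute.name] = parsed
    return instance


def merge_chunk_results(
    results: list[InstanceNode],
    schema: SchemaDefinition,
    class_name: str,
    *,
    log: Optional[ParseLog] = None,
) -> InstanceNode:
    """Merge per-chunk instances of one class into a single instance.

    Multivalued attributes take the set-union in first-seen order;
    single-valued attributes keep the first non-empty value, recording
    conflicting later values.
    """
    for node in results:
        if node.class_name != class_name:
            raise InvalidMergeError(
                f"cannot merge {node.class_name!r} into {class_name!r}"
            )
    cls = schema.class_named(class_name)
    merged = empty_instance(schema, class_name)
    for node in results:
        for attribute in cls.attributes:
            if attribute.name not in node.values:
                continue
            value = node.values[attribute.name]
            if attribute.multivalued:
                target = merged.values[attribute.name]
                for item in value:
                    if item not in target:
                        target.append(item)
            else:
                if attribute.name not in merged.values:
                    merged.values[attribute.name] = value
                elif merged.values[attribute.name] != value and log is not None:
                    log.conflicts.append(
                        f"{class_name}.{attribute.name}: kept "
                        f"{merged.values[attribute.name]!r}, dropped {value!r}"
                    )
    return merged


def _map_values(node: InstanceNode, fn) -> InstanceNode:
    out = InstanceNode(class_name=node.class_name)
    for name, value in node.values.items():
        if isinstance(value, list):
            out.values[name] = [fn(node, name, v) for v in value]
        else:
            out.values[name] = fn(node, name, value)
    return out


def _ground_tree(
    node: InstanceNode,
    schema: SchemaDefinition,
    grounder: Grounder,
) -> InstanceNode:
    cls = schema.class_named(node.class_name)

    def one(_node, attr_name, value):
        if isinstance(value, InstanceNode):
            return _ground_tree(value, schema, grounder)
        if isinstance(value, PendingRef):
            desc = resolve_range(schema, cls.attribute(attr_name))
            if desc.kind == "class-reference":
                target_cls = schema.class_named(desc.target)
                if target_cls.is_named_entity:
                    return grounder.ground(value.span, target_cls)
                return value
            if desc.kind == "value-set":
                spec = schema.value_sets[desc.target]
                anon = ClassDefinition(name=desc.target, is_named_entity=True)
                return grounder.ground(value.span, anon, value_set_spec=spec)
        return value

    return _map_values(node, one)


def iter_values(node: InstanceNode):
    """Depth-first iteration over (node, attribute, value) leaves and subtrees."""
    for name, value in node.values.items():
        items = value if isinstance(value, list) else [value]
        for item in items:
            yield node, name, item
            if isinstance(item, InstanceNode):
                yield from iter_values(item)


def _uniquify_placeholders(node: InstanceNode) -> tuple[InstanceNode, list[Placeholder]]:
    used: dict[str, int] = {}
    collected: list[Placeholder] = []

    def relabel(tree: InstanceNode) -> InstanceNode:
        def one(_node, _name, value):
            if isinstance(value, InstanceNode):
                return relabel(value)
            if isinstance(value, Placeholder):
                base = value.label or placeholder_label(value.span)
                count = used.get(base, 0)
                used[base] = count + 1
                label = base if count == 0 else f"{base}_{count + 1}"
                fresh = replace(value, label=label)
                collected.append(fresh)
                return fresh
            return value

        return _map_values(tree, one)

    return relabel(node), collected


def extract(
    schema: SchemaDefinition,
    class_name: str,
    text: str,
    backend: CompletionBackend,
    grounder: Optional[Grounder] = None,
    config: Optional[ExtractionConfig] = None,
) -> ExtractionResult:
    """Run the full pipeline: prompt, complete, parse (recursing over inlined
    classes), then ground every leaf named entity.

    With chunking enabled the text is windowed, each chunk extracted
    independently, and the per-chunk instances merged.  Backend
    unavailability propagates; every parse irregularity is recoverable and
    recorded in the result log.
    """
    config = config or ExtractionConfig()
    log = ParseLog()
    records: list[CompletionRecord] = []

    def run_class(cls_name: str, fragment: str) -> InstanceNode:
        if not fragment:
            return empty_instance(schema, cls_name)
        prompt = generate_prompt(
            schema,
            cls_name,
            fragment,
            instructions=config.instructions,
            wrap_prompts=config.wrap_prompts,
        )
        record = complete(prompt, backend, config.completion)
        records.append(record)
        return parse_completion(
            record.raw, schema, cls_name, recurse=run_class, log=log, config=config.parse
        )

    chunks: list[Chunk] = []
    if config.chunk:
        chunks = chunk_text(text, window=config.window, overlap=config.overlap)
        parts = [run_class(class_name, c.text) for c in chunks]
        root = merge_chunk_results(parts, schema, class_name, log=log)
    else:
        root = run_class(class_name, text)

    if grounder is not None:
        root = _ground_tree(root, schema, grounder)
    root, placeholders = _uniquify_placeholders(root)

    return ExtractionResult(
        root=root,
        schema_name=schema.name,
        class_name=class_name,
        records=records,
        chunks=chunks,
        unresolved=placeholders,
        log=log,
    )
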