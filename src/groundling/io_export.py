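"""Serialization of extracted instance trees: YAML, JSON, and RDF instance graphs.

The YAML rendering mirrors how curated instance records are usually
displayed: one ``attribute: value`` pair per line, hyphen-prefixed list
elements, grounded terms as CURIEs followed by their human-readable label
after a double-hash comment, and ungroundable values in RDF blank-node
syntax (``_:Label``).  The RDF export is a plain instance graph (one node
per instance, one triple per attribute-value pair, one type assertion per
node); OWL axiomatization and reasoning are left to dedicated external
tooling.
"""

from __future__ import annotations

import json
import re
from typing import Union

import yaml
from rdflib import RDF, BNode, Graph, Literal as RDFLiteral, Namespace, URIRef

from .extraction import ExtractionResult, InstanceNode, Literal, PendingRef
from .grounding import GroundedRef, Placeholder, curie_prefix
from .schema_model import SchemaDefinition


class RdfExportError(ValueError):
    """A grounded CURIE uses a prefix absent from the schema's declarations."""


_PLAIN_SCALAR = re.compile(r"^[A-Za-z0-9_][A-Za-z0-9 _./'()-]*$")


def _yaml_scalar(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    text = str(value)
    if _PLAIN_SCALAR.match(text) and text.casefold() not in {"true", "false", "null", "none"}:
        return text
    return json.dumps(text)


def _leaf_yaml(value) -> str:
    if isinstance(value, GroundedRef):
        return f"{value.curie} ## {value.matched_label}"
    if isinstance(value, Placeholder):
        return f"_:{value.label}"
    if isinstance(value, PendingRef):
        return _yaml_scalar(value.span)
    if isinstance(value, Literal):
        return _yaml_scalar(value.value)
    return _yaml_scalar(value)


def _yaml_body(node: InstanceNode, indent: int) -> list[str]:
    pad = " " * indent
    lines: list[str] = []
    for name, value in node.values.items():
        if isinstance(value, list):
            if not value:
                continue
            lines.append(f"{pad}{name}:")
            for item in value:
                if isinstance(item, InstanceNode):
                    body = _yaml_body(item, indent + 4)
                    if not body:
                        lines.append(f"{pad}  - {{}}")
                        continue
                    first = body[0].lstrip()
                    lines.append(f"{pad}  - {first}")
                    lines.extend(body[1:])
                else:
                    lines.append(f"{pad}  - {_leaf_yaml(item)}")
        elif isinstance(value, InstanceNode):
            body = _yaml_body(value, indent + 2)
            if body:
                lines.append(f"{pad}{name}:")
                lines.extend(body)
            else:
                lines.append(f"{pad}{name}: {{}}")
        else:
            lines.append(f"{pad}{name}: {_leaf_yaml(value)}")
    return lines


def _to_jsonable(node: InstanceNode) -> dict:
    out: dict = {"@class": node.class_name}

    def one(value):
        if isinstance(value, InstanceNode):
            return _to_jsonable(value)
        if isinstance(value, GroundedRef):
            return {"id": value.curie, "label": value.matched_label}
        if isinstance(value, Placeholder):
            return f"_:{value.label}"
        if isinstance(value, PendingRef):
            return {"span": value.span}
        if isinstance(value, Literal):
            return value.value
        return value

    for name, value in node.values.items():
        if isinstance(value, list):
            if value:
                out[name] = [one(v) for v in value]
        else:
            out[name] = one(value)
    return out


def render_instance(
    result: Union[ExtractionResult, InstanceNode], format: str = "yaml"
) -> str:
    """Render an instance tree as a YAML or canonical JSON document."""
    node = result.root if isinstance(result, ExtractionResult) else result
    if format == "json":
        return json.dumps(_to_jsonable(node), indent=2) + "\n"
    if format != "yaml":
        raise ValueError(f"unknown format {format!r}")
    lines = [f"{node.class_name}:"] + _yaml_body(node, 2)
    return "\n".join(lines) + "\n"


def parse_rendered_yaml(document: str) -> dict:
    """Re-parse a rendered YAML instance document with a standard parser.

    Grounded values come back as their bare CURIEs (the ``## label``
    comments are YAML comments and vanish), which is what round-trip
    checks compare on.
    """
    data = yaml.safe_load(document)
    if not isinstance(data, dict):
        raise ValueError("rendered document did not parse to a mapping")
    return data


def _expand(curie: str, schema: SchemaDefinition) -> URIRef:
    prefix = curie_prefix(curie)
    if prefix not in schema.prefix_declarations:
        raise RdfExportError(f"prefix {prefix!r} is not declared in schema {schema.name!r}")
    local = curie.split(":", 1)[1]
    return URIRef(schema.prefix_declarations[prefix] + local)


def export_rdf(
    result: Union[ExtractionResult, InstanceNode],
    schema: SchemaDefinition,
    base_iri: str | None = None,
) -> Graph:
    """Project an instance tree onto a plain RDF instance graph.

    Each instance becomes a node (a blank node unless its identifier
    attribute is populated) with one ``rdf:type`` assertion and one triple
    per populated attribute-value pair; grounded CURIEs expand through the
    schema's prefix declarations (undeclared prefixes are an error).
    """
    root = result.root if isinstance(result, ExtractionResult) else result
    base = Namespace(base_iri or f"https://w3id.org/groundling/{schema.name}/")
    graph = Graph()
    graph.bind("rdf", RDF)
    for prefix, iri in schema.prefix_declarations.items():
        graph.bind(prefix.lower(), Namespace(iri))

    def node_subject(node: InstanceNode):
        cls = schema.class_named(node.class_name)
        for attr in cls.attributes:
            if attr.identifier and attr.name in node.values:
                value = node.values[attr.name]
                if isinstance(value, Literal) and isinstance(value.value, str):
                    try:
                        return _expand(value.value, schema)
                    except (RdfExportError, ValueError):
                        return URIRef(str(base) + value.value)
        return BNode()

    def emit(node: InstanceNode):
        subject = node_subject(node)
        graph.add((subject, RDF.type, URIRef(str(base) + node.class_name)))
        for name, value in node.values.items():
            predicate = URIRef(str(base) + name)
            items = value if isinstance(value, list) else [value]
            for item in items:
                if isinstance(item, InstanceNode):
                    child = emit(item)
                    graph.add((subject, predicate, child))
                elif isinstance(item, GroundedRef):
                    graph.add((subject, predicate, _expand(item.curie, schema)))
                elif isinstance(item, Placeholder):
                    graph.add((subject, predicate, BNode(item.label)))
                elif isinstance(item, PendingRef):
                    graph.add((subject, predicate, RDFLiteral(item.span)))
                elif isinstance(item, Literal):
                    graph.add((subject, predicate, RDFLiteral(item.value)))
        return subject

    emit(root)
    return graph


def render_rdf(result, schema: SchemaDefinition, base_iri: str | None = None) -> str:
    """Serialize the RDF projection in Turtle."""
    return export_rdf(result, schema, base_iri).serialize(format="turtle")
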