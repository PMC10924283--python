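"""Deterministic prompt-text generation from a schema, a class, and an input text.

A prompt is the concatenation, in fixed order, of an instruction line, a
pseudo-YAML attribute template (one line per attribute of the target
class), the fixed text introducer ``Text:``, the input text itself, and a
break marker (three break characters).  Generation is a pure function: no
randomness, no backend calls.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .schema_model import SchemaDefinition

#: Instruction used for recursive calls on short text fragments.
SPLIT_INSTRUCTIONS = "Split the following piece of text into fields in the following format:"
#: Instruction used when extracting entities from a larger document.
EXTRACT_INSTRUCTIONS = "From the text below, extract the following entities in the following format:"

TEXT_INTRO = "Text:"
BREAK_MARKER = "==="

MULTIVALUED_PREFIX = "A semicolon-separated list"


class UnresolvedClassError(KeyError):
    """The requested class is not declared in the schema."""


@dataclass(frozen=True)
class PromptParts:
    """The ordered pieces of a generated prompt.

    ``assemble()`` is the canonical concatenation; it reproduces the
    emitted prompt byte-for-byte.
    """

    instructions: str
    attribute_template: str
    text_intro: str
    break_marker: str
    input_text: str

    def assemble(self) -> str:
        return (
            self.instructions
            + "\n"
            + self.attribute_template
            + self.text_intro
            + "\n"
            + self.input_text
            + "\n"
            + self.break_marker
        )


def auto_prompt(attribute_name: str) -> str:
    """Derive a prompt from an attribute name: underscores become spaces, prefixed with "the".

    >>> auto_prompt("food_item")
    'the food item'
    """
    if not attribute_name:
        raise ValueError("attribute name must be non-empty")
    words = re.sub(r"[_\s]+", " ", attribute_name).strip()
    return f"the {words}"


def _prompt_text(attr) -> str:
    text = attr.prompt if attr.prompt is not None else auto_prompt(attr.name)
    if attr.multivalued:
        text = f"{MULTIVALUED_PREFIX} of {text}"
    return text


def attribute_template(
    schema: SchemaDefinition, class_name: str, *, wrap_prompts: bool = True
) -> str:
    """One template line per attribute, in schema order: ``name: <prompt>``.

    Multivalued attributes have their prompt preceded with
    ``"A semicolon-separated list"``; attributes without an explicit prompt
    get one auto-generated from the name.
    """
    if not schema.has_class(class_name):
        raise UnresolvedClassError(class_name)
    cls = schema.class_named(class_name)
    lines = []
    for attr in cls.attributes:
        prompt = _prompt_text(attr)
        if wrap_prompts:
            prompt = f"<{prompt}>"
        lines.append(f"{attr.name}: {prompt}\n")
    return "".join(lines)


def build_prompt_parts(
    schema: SchemaDefinition,
    class_name: str,
    text: str,
    *,
    instructions: str = SPLIT_INSTRUCTIONS,
    wrap_prompts: bool = True,
) -> PromptParts:
    if not text:
        raise ValueError("input text must be non-empty")
    return PromptParts(
        instructions=instructions,
        attribute_template=attribute_template(schema, class_name, wrap_prompts=wrap_prompts),
        text_intro=TEXT_INTRO,
        break_marker=BREAK_MARKER,
        input_text=text,
    )


def generate_prompt(
    schema: SchemaDefinition,
    class_name: str,
    text: str,
    *,
    instructions: str = SPLIT_INSTRUCTIONS,
    wrap_prompts: bool = True,
) -> str:
    """Generate the full prompt for extracting one instance of ``class_name`` from ``text``."""
    return build_prompt_parts(
        schema, class_name, text, instructions=instructions, wrap_prompts=wrap_prompts
    ).assemble()
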