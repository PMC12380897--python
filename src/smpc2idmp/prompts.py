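"""Prompt assembly for the three few-shot prefix patterns.

Three manual prompting patterns are supported:

* **CARE** (Context-Action-Result-Example) — contextual grounding plus at
  least one illustrative example,
* **RISE** (Role-Input-Steps-Expectation) — procedural guidance with no
  examples,
* **CIAEE** (Context-Input-Action-Expectation-Example) — a hybrid of the two.

A prompt carries the field's natural-language question, all retrieved context
passages, a format instruction matching the field's value kind, and — in
semantic retrieval mode only — the instruction to return an empty string when
the context holds no relevant information (rule-based retrieval guarantees
the mapped chapter is supplied, so the fallback is omitted there).

Templates are plain-text data files with ``$slot`` markers so the exact
wording stays auditable and swappable; the example bank ships as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from string import Template

from .idmp_model import FieldSpec
from .retrieval import RetrievedContext

__all__ = [
    "PromptPattern",
    "FieldExample",
    "PATTERNS",
    "get_pattern",
    "default_examples_for",
    "build_prompt",
    "EMPTY_STRING_INSTRUCTION",
]

EMPTY_STRING_INSTRUCTION = (
    " If the context does not contain the requested information, "
    "return an empty string."
)

_FORMAT_INSTRUCTIONS = {
    "scalar-text": "Answer with the extracted value only, as plain text.",
    "scalar-date": "Answer with the extracted date only, as plain text.",
    "list-of-text": "Answer with a JSON array of strings.",
    "list-of-records": "Answer with a JSON array of objects.",
    "nested-record": "Answer with a JSON object.",
}


@dataclass(frozen=True)
class PromptPattern:
    name: str
    slot_order: tuple[str, ...]
    requires_examples: bool


PATTERNS = {
    "care": PromptPattern("care", ("context", "action", "result", "example"), True),
    "rise": PromptPattern("rise", ("role", "input", "steps", "expectation"), False),
    "ciaee": PromptPattern(
        "ciaee", ("context", "input", "action", "expectation", "example"), True
    ),
}


def get_pattern(name: str) -> PromptPattern:
    try:
        return PATTERNS[name.lower()]
    except KeyError:
        raise KeyError(f"unknown prompt pattern {name!r}; known: {sorted(PATTERNS)}")


@dataclass(frozen=True)
class FieldExample:
    field_id: str
    example_input: str
    example_output: str


def _load_template(name: str) -> Template:
    text = resources.files("smpc2idmp.templates").joinpath(f"{name}.txt").read_text(
        encoding="utf-8"
    )
    return Template(text)


def _load_example_bank() -> dict:
    text = resources.files("smpc2idmp.templates").joinpath("examples.json").read_text(
        encoding="utf-8"
    )
    return json.loads(text)


_EXAMPLE_BANK = _load_example_bank()


def default_examples_for(field: FieldSpec) -> list[FieldExample]:
    """The shipped example for a field: per-field entry, else the per-section
    fallback."""
    entry = _EXAMPLE_BANK["fields"].get(field.field_id)
    if entry is None:
        entry = _EXAMPLE_BANK["sections"].get(f"section:{field.section}")
    if entry is None:
        return []
    return [FieldExample(field.field_id, entry["example_input"], entry["example_output"])]


def _render_examples(examples: list[FieldExample]) -> str:
    blocks = []
    for ex in examples:
        blocks.append(
            f"Example input:\n{ex.example_input}\nExample output:\n{ex.example_output}"
        )
    return "\n\n".join(blocks)


def build_prompt(
    pattern: PromptPattern,
    field: FieldSpec,
    context: RetrievedContext,
    examples: list[FieldExample] | None = None,
    mode: str = "semantic",
) -> str:
    """Render a complete prompt for one field; deterministic for fixed inputs.

    CARE and CIAEE require at least one example; RISE forbids them.  In
    rule-based mode an empty context is a contract violation (the mapping is
    supposed to supply the chapter) and raises.
    """
    examples = examples if examples is not None else (
        [] if not pattern.requires_examples else default_examples_for(field)
    )
    if pattern.requires_examples and not examples:
        raise ValueError(f"pattern {pattern.name!r} requires at least one example")
    if not pattern.requires_examples and examples:
        raise ValueError(f"pattern {pattern.name!r} forbids examples")
    if mode == "rule_based" and not context.passages:
        raise ValueError(
            f"rule-based retrieval supplied no context for {field.field_id!r}"
        )

    template = _load_template(pattern.name)
    empty_instruction = EMPTY_STRING_INSTRUCTION if mode == "semantic" else ""
    return template.substitute(
        context=context.text,
        question=field.question_text,
        format_instruction=_FORMAT_INSTRUCTIONS[field.value_kind],
        empty_instruction=empty_instruction,
        examples=_render_examples(examples),
    )
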