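"""End-to-end extraction orchestration: retrieve, prompt, generate, parse,
assemble.

For every field of the minimal-IDMP registry the orchestrator retrieves
context (semantic or rule-based per config), renders the configured prompt
pattern, sends it to a pluggable text-generation backend, parses the reply
into a typed value, and finally assembles the nested record and validates it.
The pipeline is total: content-level failures produce canonical missing
values plus warnings, never an abort.

Generation backends implement a one-method contract (``complete(prompt) ->
reply``).  Hosted LLMs plug in behind it and can be recorded/replayed through
a JSON-lines transcript cache keyed by prompt hash.  The shipped reference
backend is a deterministic pattern matcher built against the synthetic-corpus
grammar: it identifies the field from the question line of the prompt and
applies the grammar's inverse regular expressions to the embedded context.
It exists so the full pipeline can be tested offline with a known answer; it
is not a language model.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Protocol

from .idmp_model import (
    FieldSpec,
    field_registry,
    record_skeleton,
    set_path,
    validate_record,
)
from .prompts import build_prompt, default_examples_for, get_pattern
from .retrieval import (
    RetrievalConfig,
    RetrievedContext,
    build_index,
    chunk_document,
    get_embedding_backend,
    rule_based_retrieve,
    semantic_retrieve,
)
from .smpc_io import SmpcDocument

logger = logging.getLogger(__name__)

__all__ = [
    "LlmBackend",
    "ReferenceBackend",
    "TranscriptCache",
    "ExtractionConfig",
    "parse_llm_output",
    "extract_field",
    "extract_record",
    "get_llm_backend",
    "register_llm_backend",
]


class LlmBackend(Protocol):
    name: str

    def complete(self, prompt: str) -> str: ...


@dataclass(frozen=True)
class ExtractionConfig:
    """One benchmark cell: generation backend x prompt pattern x retrieval."""

    backend: str = "reference"
    prompt_pattern: str = "care"
    retrieval: RetrievalConfig = dc_field(default_factory=RetrievalConfig)
    seed: int = 0
    transcript_cache: str | None = None


# --- reply parsing ----------------------------------------------------------

_JSON_FRAGMENT_RE = re.compile(r"[\[{].*[\]}]", re.DOTALL)


def _missing_value(value_kind: str) -> Any:
    return [] if value_kind in ("list-of-text", "list-of-records") else ""


def parse_llm_output(reply: str, field: FieldSpec) -> Any:
    """Parse a raw backend reply into the field's typed value.

    The first JSON fragment is extracted if one is present; otherwise the
    stripped reply is the scalar value verbatim (semantic cleanup is the
    normalization stage's job, not this parser's).  Empty or malformed
    replies yield the canonical missing value with a warning; this function
    never raises.
    """
    if reply is None:
        return _missing_value(field.value_kind)
    text = reply.strip()
    if not text:
        return _missing_value(field.value_kind)
    if field.value_kind in ("list-of-text", "list-of-records", "nested-record"):
        m = _JSON_FRAGMENT_RE.search(text)
        if m:
            try:
                value = json.loads(m.group(0))
            except json.JSONDecodeError:
                logger.warning(
                    "malformed structured reply for %s; treating as missing",
                    field.field_id,
                )
                return _missing_value(field.value_kind)
            if field.value_kind == "list-of-text" and isinstance(value, list):
                return [str(v) for v in value]
            if field.value_kind == "list-of-records" and isinstance(value, list):
                return [v for v in value if isinstance(v, dict)]
            if field.value_kind == "nested-record" and isinstance(value, dict):
                return value
        logger.warning("no JSON fragment in reply for %s", field.field_id)
        return _missing_value(field.value_kind)
    return text


# --- backends ---------------------------------------------------------------

_QUESTION_RE = re.compile(r"^Question:\s*(.+)$", re.MULTILINE)
_CONTEXT_RE = re.compile(r"<<<CONTEXT\n(.*?)\nCONTEXT>>>", re.DOTALL)

_MATERIALS = ("HDPE", "glass", "polypropylene", "polyethylene", "PVC", "Aluminium")
_CONTAINER_WORDS = ("bottle", "jar", "vial", "blister", "tube")


class ReferenceBackend:
    """Deterministic inverse of the synthetic-corpus grammar.

    Answers a prompt by (1) reading the ``Question:`` line and matching it to
    a registry field, (2) reading the context between the CONTEXT markers,
    and (3) applying the field's inverse surface patterns.  Unknown questions
    or patterns that do not match return the empty string, mirroring the
    empty-string fallback instruction.
    """

    name = "reference"

    def __init__(self) -> None:
        self._by_question = {s.question_text: s for s in field_registry()}

    def complete(self, prompt: str) -> str:
        qm = _QUESTION_RE.search(prompt)
        cm = _CONTEXT_RE.search(prompt)
        if not qm or not cm:
            return ""
        spec = self._by_question.get(qm.group(1).strip())
        if spec is None:
            return ""
        extractor = getattr(self, f"_x_{spec.field_id}", None)
        if extractor is None:
            return ""
        return extractor(cm.group(1))

    # -- per-field inverse patterns (one method per registry field) --

    @staticmethod
    def _x_product_name(s: str) -> str:
        m = re.search(
            r"(?m)^([A-Z][A-Za-z]+ \d+(?:\.\d+)? (?:mg|g|micrograms)(?:/ml)? [a-z][^\n]*)$",
            s,
        )
        return m.group(1).strip() if m else ""

    @staticmethod
    def _x_atc_code(s: str) -> str:
        m = re.search(r"ATC code:\s*([A-Z]\d{2}[A-Z]{2}\d{2})", s)
        return m.group(1) if m else ""

    @staticmethod
    def _x_authorized_pharmaceutical_form(s: str) -> str:
        m = re.search(r"(?m)^([^\n]+?)\.\s*\nThe administrable dose form", s)
        return m.group(1).strip() if m else ""

    @staticmethod
    def _x_marketing_authorization_number(s: str) -> str:
        numbers = re.findall(r"EU/\d+/\d+/\d+/\d+(?:-\d+)?", s)
        return json.dumps(numbers) if numbers else ""

    @staticmethod
    def _x_date_of_first_authorization(s: str) -> str:
        m = re.search(r"Date of first authorisation:\s*([^\n]+)", s)
        return m.group(1).strip() if m else ""

    @staticmethod
    def _x_date_of_latest_renewal(s: str) -> str:
        m = re.search(r"Date of latest renewal:\s*([^\n]+)", s)
        return m.group(1).strip() if m else ""

    @staticmethod
    def _holder_lines(s: str) -> list[str]:
        m = re.search(
            r"MARKETING AUTHORISATION HOLDER\s*\n(.*?)(?:\n\s*\n|\n\d{1,2}[.)]|\Z)",
            s,
            re.DOTALL,
        )
        if not m:
            return []
        return [ln.strip() for ln in m.group(1).splitlines() if ln.strip()]

    def _x_marketing_authorization_holder_name(self, s: str) -> str:
        lines = self._holder_lines(s)
        return lines[0] if len(lines) >= 1 else ""

    def _x_marketing_authorization_holder_address(self, s: str) -> str:
        lines = self._holder_lines(s)
        return lines[1] if len(lines) >= 2 else ""

    def _x_marketing_authorization_holder_postal(self, s: str) -> str:
        lines = self._holder_lines(s)
        return lines[2] if len(lines) >= 3 else ""

    def _x_marketing_authorization_holder_country(self, s: str) -> str:
        lines = self._holder_lines(s)
        return lines[3] if len(lines) >= 4 else ""

    @staticmethod
    def _x_therapeutic_indications_information(s: str) -> str:
        m = re.search(r"([A-Z][^\n.]*? is indicated for the treatment of [^\n]*?\.)", s)
        return m.group(1).strip() if m else ""

    @staticmethod
    def _x_package_description(s: str) -> str:
        m = re.search(r"Pack size:\s*([^\n]+?)\.(?:\s|$)", s)
        return m.group(1).strip() if m else ""

    @staticmethod
    def _container_sentence(s: str) -> str:
        words = "|".join(_CONTAINER_WORDS)
        m = re.search(
            rf"(?:^|\. |\n)((?:White opaque|Amber|Clear)[^.\n]*?(?:{words})[^.\n]*?)\.",
            s,
        )
        return m.group(1).strip() if m else ""

    def _x_container_description(self, s: str) -> str:
        return self._container_sentence(s)

    def _x_container_type(self, s: str) -> str:
        sentence = self._container_sentence(s)
        for word in _CONTAINER_WORDS:
            if re.search(rf"\b{word}\b", sentence):
                return word
        return ""

    def _x_package_item_material(self, s: str) -> str:
        sentence = self._container_sentence(s)
        for mat in _MATERIALS:
            if re.search(rf"\b{re.escape(mat)}\b", sentence):
                return mat
        return ""

    @staticmethod
    def _spoon_components(s: str) -> list[tuple[str, str]]:
        return re.findall(r"The (\w+) measuring spoon dispenses ([^.\n]+)\.", s)

    def _x_package_component_value(self, s: str) -> str:
        comps = self._spoon_components(s)
        return json.dumps([dose.strip() for _, dose in comps]) if comps else ""

    def _x_package_component_component(self, s: str) -> str:
        comps = self._spoon_components(s)
        if not comps:
            return ""
        mm = re.search(r"(\w+) measuring spoons", s)
        material = mm.group(1) if mm else ""
        return json.dumps(
            [
                {"component": f"{color} measuring spoon", "material": material}
                for color, _ in comps
            ]
        )

    @staticmethod
    def _x_shelf_life_value(s: str) -> str:
        m = re.search(r"Shelf life:\s*([^\n.]+)", s)
        return m.group(1).strip() if m else ""

    @staticmethod
    def _x_special_precautions_for_storage(s: str) -> str:
        m = re.search(
            r"precautions for storage\s*\n([^\n]+)", s
        )
        return m.group(1).strip() if m else ""

    _SALT_RE = re.compile(
        r"Each [a-z]+ contains ([\d.]+ (?:mg|g|micrograms)) of ([a-z][a-z ]*?) "
        r"equivalent to ([\d.]+ (?:mg|g|micrograms)) of ([a-z][a-z ]*?)\."
    )
    _BASE_RE = re.compile(
        r"Each [a-z]+ contains ([\d.]+ (?:mg|g|micrograms)) of ([a-z][a-z ]*?)\."
    )

    def _active(self, s: str) -> tuple[str, str, str, str]:
        m = self._SALT_RE.search(s)
        if m:
            return m.group(2), m.group(1), m.group(4), m.group(3)
        m = self._BASE_RE.search(s)
        if m:
            return "", "", m.group(2), m.group(1)
        return "", "", "", ""

    def _x_active_substance_salt_value(self, s: str) -> str:
        return self._active(s)[0]

    def _x_active_substance_salt_dosage(self, s: str) -> str:
        return self._active(s)[1]

    def _x_active_substance_base_value(self, s: str) -> str:
        return self._active(s)[2]

    def _x_active_substance_base_dosage(self, s: str) -> str:
        return self._active(s)[3]

    @staticmethod
    def _excipient_lines(s: str) -> list[tuple[str, str]]:
        return re.findall(r"(?m)^([A-Z][A-Za-z ]+?) \(([^)\n]+)\)$", s)

    def _x_composition_excipient_excipient(self, s: str) -> str:
        pairs = self._excipient_lines(s)
        return json.dumps([name for name, _ in pairs]) if pairs else ""

    def _x_composition_excipient_dosage(self, s: str) -> str:
        pairs = self._excipient_lines(s)
        return json.dumps([dose for _, dose in pairs]) if pairs else ""

    @staticmethod
    def _x_administrable_dose_form(s: str) -> str:
        m = re.search(r"administrable dose form is the ([^,\n]+),", s)
        return m.group(1).strip() if m else ""

    @staticmethod
    def _x_unit_of_presentation(s: str) -> str:
        m = re.search(r"presented as one ([^,\n]+) per dose", s)
        return m.group(1).strip() if m else ""

    @staticmethod
    def _x_route_of_administration(s: str) -> str:
        m = re.search(r"per dose, for ([^.\n]+)\.", s)
        return m.group(1).strip() if m else ""


class TranscriptCache:
    """Record/replay wrapper: JSON-lines of (prompt_hash, reply).

    Replays cached replies byte-identically; on a miss it delegates to the
    wrapped backend (if any) and appends the new transcript line.
    """

    def __init__(self, path: str | Path, inner: LlmBackend | None = None):
        self.path = Path(path)
        self.inner = inner
        self.name = f"cache({inner.name})" if inner else "cache"
        self._cache: dict[str, str] = {}
        if self.path.exists():
            for line in self.path.read_text(encoding="utf-8").splitlines():
                if line.strip():
                    entry = json.loads(line)
                    self._cache[entry["prompt_hash"]] = entry["reply"]

    @staticmethod
    def prompt_hash(prompt: str) -> str:
        return hashlib.sha256(prompt.encode("utf-8")).hexdigest()

    def complete(self, prompt: str) -> str:
        key = self.prompt_hash(prompt)
        if key in self._cache:
            return self._cache[key]
        if self.inner is None:
            raise KeyError(f"prompt hash {key[:12]}... not in transcript cache")
        reply = self.inner.complete(prompt)
        self._cache[key] = reply
        with self.path.open("a", encoding="utf-8") as fh:
            fh.write(json.dumps({"prompt_hash": key, "reply": reply}) + "\n")
        return reply


_LLM_REGISTRY: dict[str, LlmBackend] = {}


def register_llm_backend(backend: LlmBackend) -> None:
    _LLM_REGISTRY[backend.name] = backend


def get_llm_backend(name: str) -> LlmBackend:
    if name not in _LLM_REGISTRY:
        raise KeyError(
            f"unknown generation backend {name!r}; registered: {sorted(_LLM_REGISTRY)}"
        )
    return _LLM_REGISTRY[name]


register_llm_backend(ReferenceBackend())


# --- orchestration ----------------------------------------------------------

def _resolve_backend(config: ExtractionConfig) -> LlmBackend:
    backend = get_llm_backend(config.backend)
    if config.transcript_cache:
        backend = TranscriptCache(config.transcript_cache, backend)
    return backend


def _retrieve(
    doc: SmpcDocument, field: FieldSpec, config: ExtractionConfig, index=None
) -> RetrievedContext:
    if config.retrieval.mode == "rule_based":
        return rule_based_retrieve(field, doc)
    if index is None:
        chunks = chunk_document(doc, config.retrieval)
        index = build_index(chunks, get_embedding_backend(config.retrieval.embedding_backend))
    return semantic_retrieve(field.question_text, index, config.retrieval, field.field_id)


def extract_field(
    doc: SmpcDocument,
    field: FieldSpec,
    config: ExtractionConfig,
    backend: LlmBackend | None = None,
    index=None,
) -> tuple[Any, dict]:
    """Extract one field; returns (typed value, provenance).

    Provenance carries the retrieval mode, passage provenances, prompt hash
    and raw reply — enough to reconstruct any downstream score.
    """
    backend = backend or _resolve_backend(config)
    context = _retrieve(doc, field, config, index)
    pattern = get_pattern(config.prompt_pattern)
    if config.retrieval.mode == "rule_based" and not context.passages:
        logger.warning(
            "mapped chapters absent for %s in %s; value missing",
            field.field_id, doc.doc_id,
        )
        return _missing_value(field.value_kind), {
            "field_id": field.field_id, "mode": "rule_based",
            "passages": [], "prompt_hash": None, "reply": None,
        }
    examples = default_examples_for(field) if pattern.requires_examples else []
    prompt = build_prompt(pattern, field, context, examples, config.retrieval.mode)
    reply = backend.complete(prompt)
    value = parse_llm_output(reply, field)
    provenance = {
        "field_id": field.field_id,
        "mode": config.retrieval.mode,
        "passages": [p.provenance for p in context.passages],
        "prompt_hash": TranscriptCache.prompt_hash(prompt),
        "reply": reply,
    }
    return value, provenance


def _assemble(values: dict[str, Any]) -> dict:
    """Place per-field typed values into the nested record skeleton."""
    record = record_skeleton()
    for spec in field_registry():
        value = values.get(spec.field_id)
        if value is None:
            continue
        if "[]" not in spec.path:
            set_path(record, spec.path, value)
        elif spec.field_id.startswith("active_"):
            # single dosage form: one composition entry
            if value:
                list_path, _, tail = spec.path.partition("[]")
                set_path(record, f"{list_path}[0].{tail.lstrip('.')}", value)

    # zip excipient names and dosages into paired entries
    names = values.get("composition_excipient_excipient") or []
    doses = values.get("composition_excipient_dosage") or []
    record["ingredients"]["composition_excipient"] = [
        {"excipient": str(n), "dosage": str(doses[i]) if i < len(doses) else ""}
        for i, n in enumerate(names)
    ]
    # zip component dose values with component/material records
    comp_values = values.get("package_component_value") or []
    comp_records = values.get("package_component_component") or []
    n = max(len(comp_values), len(comp_records))
    components = []
    for i in range(n):
        rec = comp_records[i] if i < len(comp_records) else {}
        components.append(
            {
                "value": str(comp_values[i]) if i < len(comp_values) else "",
                "component": str(rec.get("component", "")),
                "material": str(rec.get("material", "")),
            }
        )
    record["packaged_medicinal_product"]["package"]["package_composition"][
        "package_component"
    ] = components
    return record


def extract_record(
    doc: SmpcDocument, config: ExtractionConfig
) -> tuple[dict, dict[str, dict]]:
    """Run the full per-field pipeline and assemble the nested record.

    Returns (record, provenance-by-field).  The pipeline is total: a failing
    field contributes its canonical missing value and the record is always
    returned and schema-valid.
    """
    backend = _resolve_backend(config)
    index = None
    if config.retrieval.mode == "semantic":
        chunks = chunk_document(doc, config.retrieval)
        if chunks:
            index = build_index(
                chunks, get_embedding_backend(config.retrieval.embedding_backend)
            )
    values: dict[str, Any] = {}
    provenance: dict[str, dict] = {}
    for spec in field_registry():
        try:
            value, prov = extract_field(doc, spec, config, backend, index)
        except Exception as exc:  # noqa: BLE001 - totality over per-field errors
            logger.warning("field %s failed: %s", spec.field_id, exc)
            value, prov = _missing_value(spec.value_kind), {
                "field_id": spec.field_id, "error": str(exc)
            }
        values[spec.field_id] = value
        provenance[spec.field_id] = prov
    record = _assemble(values)
    violations = validate_record(record)
    if violations:  # assembly guarantees schema shape; belt and braces
        logger.warning("assembled record has %d violations", len(violations))
    return record, provenance
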