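"""Minimal-IDMP schema: the field registry, record skeleton, validation and flattening.

The minimal IDMP is the reduced set of data elements that cannot be recovered
from other structured sources and therefore must be extracted from the SmPC
itself.  It spans six sections (medicinal product, marketing authorization,
therapeutic indications, packaged medicinal product, ingredients and
pharmaceutical product) and grades each field by a nesting level from 1
(directly stated scalars, e.g. the product name) to 4 (deeply nested packaging
narratives that must be reconstructed from free text).

Every other module produces or consumes the nested ``IdmpRecord`` mapping
defined here; a missing value is always the empty string (scalars) or the
empty list (list-valued fields), never an absent key.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Any, Iterable

__all__ = [
    "FieldSpec",
    "Violation",
    "field_registry",
    "field_by_id",
    "record_skeleton",
    "validate_record",
    "flatten_record",
    "rebuild_record",
    "drop_empty_entries",
    "spec_for_leaf",
    "get_path",
    "set_path",
    "DATE_FIELD_IDS",
    "LIST_FIELD_IDS",
]

VALUE_KINDS = {
    "scalar-text",
    "scalar-date",
    "list-of-text",
    "list-of-records",
    "nested-record",
}


@dataclass(frozen=True)
class FieldSpec:
    """One row of the minimal-IDMP field table.

    ``path`` is a dotted key path into the record; ``[]`` marks traversal of a
    list of records (e.g. ``ingredients.composition_active[].active_substance_salt.value``).
    ``chapter_map`` lists the SmPC chapters the rule-based retriever reads for
    this field.  ``default_equivalents`` are phrases semantically equivalent to
    an empty value (e.g. the standard "no special storage conditions" wording).
    """

    field_id: str
    section: int
    level: int
    path: str
    value_kind: str
    question_text: str
    chapter_map: tuple[str, ...]
    default_equivalents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.level not in (1, 2, 3, 4):
            raise ValueError(f"level must be 1-4, got {self.level}")
        if self.section not in range(1, 7):
            raise ValueError(f"section must be 1-6, got {self.section}")


@dataclass(frozen=True)
class Violation:
    """A single schema violation located by path."""

    path: str
    kind: str  # unknown_key | missing_key | wrong_kind
    detail: str = ""


STORAGE_DEFAULT_PHRASE = (
    "This medicinal product does not require any special storage conditions."
)

_REGISTRY: tuple[FieldSpec, ...] = (
    FieldSpec(
        "product_name", 1, 1,
        "medicinal_product.product_name", "scalar-text",
        "What is the full name of the medicinal product, including strength and pharmaceutical form?",
        ("1",),
    ),
    FieldSpec(
        "atc_code", 1, 1,
        "medicinal_product.atc_code", "scalar-text",
        "What is the ATC code of the medicinal product?",
        ("5",),
    ),
    FieldSpec(
        "authorized_pharmaceutical_form", 1, 1,
        "medicinal_product.authorized_pharmaceutical_form", "scalar-text",
        "What is the authorised pharmaceutical form of the medicinal product?",
        ("3",),
    ),
    FieldSpec(
        "marketing_authorization_number", 2, 1,
        "marketing_authorization.marketing_authorization_number", "list-of-text",
        "What are the marketing authorisation numbers of the medicinal product?",
        ("8",),
    ),
    FieldSpec(
        "date_of_first_authorization", 2, 1,
        "marketing_authorization.date_of_first_authorization", "scalar-date",
        "What is the date of first authorisation of the medicinal product?",
        ("9",),
    ),
    FieldSpec(
        "date_of_latest_renewal", 2, 1,
        "marketing_authorization.date_of_latest_renewal", "scalar-date",
        "What is the date of the latest renewal of the authorisation?",
        ("9",),
    ),
    FieldSpec(
        "marketing_authorization_holder_name", 2, 2,
        "marketing_authorization.marketing_authorization_holder.name", "scalar-text",
        "What is the name of the marketing authorisation holder?",
        ("7",),
    ),
    FieldSpec(
        "marketing_authorization_holder_address", 2, 2,
        "marketing_authorization.marketing_authorization_holder.address", "scalar-text",
        "What is the street address of the marketing authorisation holder?",
        ("7",),
    ),
    FieldSpec(
        "marketing_authorization_holder_postal", 2, 2,
        "marketing_authorization.marketing_authorization_holder.postal", "scalar-text",
        "What is the postal code and city of the marketing authorisation holder?",
        ("7",),
    ),
    FieldSpec(
        "marketing_authorization_holder_country", 2, 2,
        "marketing_authorization.marketing_authorization_holder.country", "scalar-text",
        "In which country is the marketing authorisation holder located?",
        ("7",),
    ),
    FieldSpec(
        "therapeutic_indications_information", 3, 1,
        "therapeutic_indications.therapeutic_indications_information", "scalar-text",
        "What are the therapeutic indications of the medicinal product?",
        ("4",),
    ),
    FieldSpec(
        "package_description", 4, 2,
        "packaged_medicinal_product.package.package_description", "scalar-text",
        "What is the pack size and overall description of the package?",
        ("6.5",),
    ),
    FieldSpec(
        "container_description", 4, 3,
        "packaged_medicinal_product.package.package_composition.container_description",
        "scalar-text",
        "How is the immediate container of the medicinal product described?",
        ("6.5",),
    ),
    FieldSpec(
        "container_type", 4, 3,
        "packaged_medicinal_product.package.package_composition.container_type",
        "scalar-text",
        "What type of container holds the medicinal product?",
        ("6.5",),
    ),
    FieldSpec(
        "package_item_material", 4, 3,
        "packaged_medicinal_product.package.package_composition.package_item_material",
        "scalar-text",
        "What material is the immediate container made of?",
        ("6.5",),
    ),
    FieldSpec(
        "package_component_value", 4, 4,
        "packaged_medicinal_product.package.package_composition.package_component[].value",
        "list-of-text",
        "What dose does each packaging component such as a measuring device dispense?",
        ("6.5",),
    ),
    FieldSpec(
        "package_component_component", 4, 4,
        "packaged_medicinal_product.package.package_composition.package_component[]",
        "list-of-records",
        "What packaging components are included in the pack and what material are they made of?",
        ("6.5",),
    ),
    FieldSpec(
        "shelf_life_value", 4, 2,
        "packaged_medicinal_product.shelf_life.value", "scalar-text",
        "What is the shelf life of the medicinal product?",
        ("6.3",),
    ),
    FieldSpec(
        "special_precautions_for_storage", 4, 2,
        "packaged_medicinal_product.shelf_life.special_precautions_for_storage",
        "scalar-text",
        "What special precautions for storage apply to the medicinal product?",
        ("6.4",),
        default_equivalents=(STORAGE_DEFAULT_PHRASE,),
    ),
    FieldSpec(
        "active_substance_salt_value", 5, 3,
        "ingredients.composition_active[].active_substance_salt.value", "scalar-text",
        "What is the salt form of the active substance?",
        ("2", "6.1"),
    ),
    FieldSpec(
        "active_substance_salt_dosage", 5, 3,
        "ingredients.composition_active[].active_substance_salt.dosage", "scalar-text",
        "What is the dosage of the salt form of the active substance?",
        ("2", "6.1"),
    ),
    FieldSpec(
        "active_substance_base_value", 5, 3,
        "ingredients.composition_active[].active_substance_base.value", "scalar-text",
        "What is the base form of the active substance?",
        ("2", "6.1"),
    ),
    FieldSpec(
        "active_substance_base_dosage", 5, 3,
        "ingredients.composition_active[].active_substance_base.dosage", "scalar-text",
        "What is the dosage of the base form of the active substance?",
        ("2", "6.1"),
    ),
    FieldSpec(
        "composition_excipient_excipient", 5, 2,
        "ingredients.composition_excipient[].excipient", "list-of-text",
        "Which excipients does the medicinal product contain?",
        ("2", "6.1"),
    ),
    FieldSpec(
        "composition_excipient_dosage", 5, 2,
        "ingredients.composition_excipient[].dosage", "list-of-text",
        "What are the dosages of the excipients of the medicinal product?",
        ("2", "6.1"),
    ),
    FieldSpec(
        "administrable_dose_form", 6, 1,
        "pharmaceutical_product.administrable_dose_form", "scalar-text",
        "What is the administrable dose form of the medicinal product?",
        ("3", "4.2"),
    ),
    FieldSpec(
        "unit_of_presentation", 6, 1,
        "pharmaceutical_product.unit_of_presentation", "scalar-text",
        "What is the unit of presentation of the medicinal product?",
        ("3", "4.2"),
    ),
    FieldSpec(
        "route_of_administration", 6, 1,
        "pharmaceutical_product.route_of_administration", "scalar-text",
        "What is the route of administration of the medicinal product?",
        ("3", "4.2"),
    ),
)

DATE_FIELD_IDS = frozenset(
    s.field_id for s in _REGISTRY if s.value_kind == "scalar-date"
)
LIST_FIELD_IDS = frozenset(
    s.field_id for s in _REGISTRY if s.value_kind in ("list-of-text", "list-of-records")
)

_BY_ID = {s.field_id: s for s in _REGISTRY}


def field_registry() -> list[FieldSpec]:
    """Return the complete ordered registry of the 28 minimal-IDMP fields."""
    return list(_REGISTRY)


def field_by_id(field_id: str) -> FieldSpec:
    try:
        return _BY_ID[field_id]
    except KeyError:
        raise KeyError(f"unknown field_id {field_id!r}") from None


# --- record skeleton -------------------------------------------------------

def empty_active_entry() -> dict:
    return {
        "active_substance_salt": {"value": "", "dosage": ""},
        "active_substance_base": {"value": "", "dosage": ""},
    }


def empty_excipient_entry() -> dict:
    return {"excipient": "", "dosage": ""}


def empty_component_entry() -> dict:
    return {"value": "", "component": "", "material": ""}


# Element templates for the three list-of-records families, keyed by the
# dotted path of the owning list.
_LIST_TEMPLATES = {
    "packaged_medicinal_product.package.package_composition.package_component":
        empty_component_entry,
    "ingredients.composition_active": empty_active_entry,
    "ingredients.composition_excipient": empty_excipient_entry,
}


def record_skeleton() -> dict:
    """A fresh, canonical empty IdmpRecord (all scalars "", all lists [])."""
    return {
        "medicinal_product": {
            "product_name": "",
            "atc_code": "",
            "authorized_pharmaceutical_form": "",
        },
        "marketing_authorization": {
            "marketing_authorization_number": [],
            "date_of_first_authorization": "",
            "date_of_latest_renewal": "",
            "marketing_authorization_holder": {
                "name": "",
                "address": "",
                "postal": "",
                "country": "",
            },
        },
        "therapeutic_indications": {
            "therapeutic_indications_information": "",
        },
        "packaged_medicinal_product": {
            "package": {
                "package_description": "",
                "package_composition": {
                    "container_description": "",
                    "container_type": "",
                    "package_item_material": "",
                    "package_component": [],
                },
            },
            "shelf_life": {
                "value": "",
                "special_precautions_for_storage": "",
            },
        },
        "ingredients": {
            "composition_active": [],
            "composition_excipient": [],
        },
        "pharmaceutical_product": {
            "administrable_dose_form": "",
            "unit_of_presentation": "",
            "route_of_administration": "",
        },
    }


# --- path helpers ----------------------------------------------------------

_STEP_RE = re.compile(r"([a-z_0-9]+)(?:\[(\d+)\])?$")


def _split_path(path: str) -> list[tuple[str, int | None]]:
    steps = []
    for raw in path.split("."):
        m = _STEP_RE.match(raw)
        if not m:
            raise ValueError(f"bad path step {raw!r} in {path!r}")
        steps.append((m.group(1), int(m.group(2)) if m.group(2) else None))
    return steps


def get_path(record: dict, path: str, default: Any = "") -> Any:
    """Read a value at a dotted (optionally indexed) path; missing -> default."""
    node: Any = record
    for key, idx in _split_path(path):
        if not isinstance(node, dict) or key not in node:
            return default
        node = node[key]
        if idx is not None:
            if not isinstance(node, list) or idx >= len(node):
                return default
            node = node[idx]
    return node


def set_path(record: dict, path: str, value: Any) -> None:
    """Write a value at a dotted path, growing indexed lists as needed."""
    node: Any = record
    steps = _split_path(path)
    for i, (key, idx) in enumerate(steps):
        last = i == len(steps) - 1
        if last and idx is None:
            node[key] = value
            return
        child = node.get(key)
        if idx is not None:
            if not isinstance(child, list):
                child = node[key] = []
            template_path = ".".join(s for s, _ in steps[: i + 1])
            make = _LIST_TEMPLATES.get(template_path, dict)
            while len(child) <= idx:
                child.append(make())
            if last:
                child[idx] = value
                return
            node = child[idx]
        else:
            if not isinstance(child, dict):
                child = node[key] = {}
            node = child


# --- validation ------------------------------------------------------------

def _kind_of(value: Any) -> str:
    if isinstance(value, str):
        return "text"
    if isinstance(value, list):
        return "list"
    if isinstance(value, dict):
        return "record"
    return type(value).__name__


def _validate_node(node: Any, template: Any, path: str, out: list[Violation]) -> None:
    if isinstance(template, dict):
        if not isinstance(node, dict):
            out.append(Violation(path, "wrong_kind",
                                 f"expected nested record, got {_kind_of(node)}"))
            return
        for key in node:
            if key not in template:
                out.append(Violation(f"{path}.{key}".lstrip("."), "unknown_key"))
        for key, sub in template.items():
            if key not in node:
                out.append(Violation(f"{path}.{key}".lstrip("."), "missing_key"))
            else:
                _validate_node(node[key], sub, f"{path}.{key}".lstrip("."), out)
    elif isinstance(template, list):
        if not isinstance(node, list):
            out.append(Violation(path, "wrong_kind",
                                 f"expected list, got {_kind_of(node)}"))
            return
        make = _LIST_TEMPLATES.get(path)
        elem_template: Any = make() if make else ""
        for i, item in enumerate(node):
            _validate_node(item, elem_template, f"{path}[{i}]", out)
    else:  # scalar slot
        if not isinstance(node, str):
            out.append(Violation(path, "wrong_kind",
                                 f"expected text, got {_kind_of(node)}"))


def validate_record(record: Any) -> list[Violation]:
    """Check a mapping against the minimal-IDMP skeleton.

    Returns an empty list iff the record matches the schema; violations name
    the offending path and one of ``unknown_key`` / ``missing_key`` /
    ``wrong_kind``.  Never raises on bad input: a non-mapping input yields a
    single wrong_kind violation at the root.
    """
    if not isinstance(record, dict):
        return [Violation("", "wrong_kind",
                          f"record must be a mapping, got {_kind_of(record)}")]
    out: list[Violation] = []
    _validate_node(record, record_skeleton(), "", out)
    return out


# --- flattening ------------------------------------------------------------

def _validate_or_raise(record: dict) -> None:
    violations = validate_record(record)
    if violations:
        raise ValueError(
            "record does not validate; run validate_record first: "
            + "; ".join(f"{v.path}:{v.kind}" for v in violations[:5])
        )


def flatten_record(record: dict) -> list[tuple[str, Any]]:
    """Flatten a valid record into ordered (path, value) pairs.

    One pair per registry leaf; fields inside lists of records flatten with
    positional indices.  An empty list still contributes index-0 pairs with
    empty values so that every registry field appears at least once.  The
    flatten/rebuild pair round-trips valid records.
    """
    _validate_or_raise(record)
    pairs: list[tuple[str, Any]] = []
    for spec in _REGISTRY:
        if "[]" not in spec.path:
            pairs.append((spec.path, get_path(record, spec.path)))
            continue
        list_path, _, tail = spec.path.partition("[]")
        tail = tail.lstrip(".")
        items = get_path(record, list_path, default=[])
        # every field family appears at least once (index 0, empty value)
        n = max(1, len(items))
        if spec.field_id == "package_component_component":
            for i in range(n):
                for leaf in ("component", "material"):
                    pairs.append((f"{list_path}[{i}].{leaf}",
                                  get_path(record, f"{list_path}[{i}].{leaf}")))
        else:
            for i in range(n):
                pairs.append((f"{list_path}[{i}].{tail}",
                              get_path(record, f"{list_path}[{i}].{tail}")))
    return pairs


def _entry_is_empty(entry: Any) -> bool:
    if isinstance(entry, dict):
        return all(_entry_is_empty(v) for v in entry.values())
    if isinstance(entry, list):
        return all(_entry_is_empty(v) for v in entry)
    return entry == ""


def drop_empty_entries(record: dict) -> dict:
    """Remove fully-empty entries from the three list-of-records families."""
    for list_path in _LIST_TEMPLATES:
        items = get_path(record, list_path, default=[])
        if isinstance(items, list):
            set_path(record, list_path, [e for e in items if not _entry_is_empty(e)])
    return record


def rebuild_record(pairs: Iterable[tuple[str, Any]]) -> dict:
    """Inverse of :func:`flatten_record` on valid records.

    The index-0 placeholder pairs emitted for empty lists rebuild to empty
    lists again; canonical records never contain fully-empty list entries.
    """
    record = record_skeleton()
    for path, value in pairs:
        set_path(record, path, value)
    return drop_empty_entries(record)


def spec_for_leaf(path: str) -> FieldSpec | None:
    """Return the registry field owning a (possibly indexed) leaf path."""
    generic = re.sub(r"\[\d+\]", "[]", path)
    for spec in _REGISTRY:
        if generic == spec.path:
            return spec
        if spec.field_id == "package_component_component" and (
            generic == spec.path + ".component" or generic == spec.path + ".material"
        ):
            return spec
    return None
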