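"""Normalization of extracted and gold records before comparison.

Raw extractions and reference records disagree on surface form far more often
than on substance: authorization numbers are written as ranges, lists arrive
as JSON-looking strings, keys vary in case, dates come in half a dozen
layouts, and some fields use a standard phrase where others leave the value
empty.  The procedures here canonicalize both sides so the similarity metrics
compare content, not formatting:

* range expansion for marketing-authorization numbers
  (``.../001, .../002-004`` becomes four explicit numbers),
* parsing of embedded JSON list/object strings (with a tolerant repair that
  only quotes bare tokens inside flat brackets),
* list cleaning (strip stray brackets/quotes, de-duplicate keeping order),
* recursive lowercasing of dictionary keys,
* default-value equivalence (the standard "no special storage conditions"
  phrase is canonically empty; an empty shelf life is equivalent to standard
  values such as "3 years"),
* date parsing to ISO-8601, day-first for ambiguous numeric forms.

All operations are idempotent, never raise on malformed content, and collect
structured warnings instead.
"""

from __future__ import annotations

import copy
import json
import logging
import re
from dataclasses import dataclass, field as dc_field
from datetime import datetime
from typing import Any

from .idmp_model import (
    DATE_FIELD_IDS,
    drop_empty_entries,
    field_registry,
    get_path,
    set_path,
    spec_for_leaf,
    STORAGE_DEFAULT_PHRASE,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationRules",
    "expand_ranges",
    "parse_embedded_json",
    "clean_list",
    "normalize_keys",
    "canonicalize_default",
    "parse_date_value",
    "normalize_record",
]


@dataclass(frozen=True)
class NormalizationRules:
    """Tunable canonicalization rules, serializable to JSON.

    ``default_equivalents`` maps a record path suffix to phrases equivalent to
    the empty string; ``shelf_life_values`` are the standard shelf-life phrases
    an empty value is considered equivalent to at scoring time.
    """

    range_delimiters: tuple[str, ...] = ("-", "–", "to")
    date_formats: tuple[str, ...] = (
        "%Y-%m-%d",
        "%d %B %Y",
        "%B %d, %Y",
        "%d %b %Y",
        "%b %d, %Y",
        "%d/%m/%Y",
        "%d.%m.%Y",
    )
    default_equivalents: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("special_precautions_for_storage", (STORAGE_DEFAULT_PHRASE,)),
    )
    shelf_life_values: tuple[str, ...] = ("3 years", "6 years")

    def defaults_for(self, field_path: str) -> tuple[str, ...]:
        for suffix, phrases in self.default_equivalents:
            if field_path.endswith(suffix):
                return phrases
        return ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "range_delimiters": list(self.range_delimiters),
                "date_formats": list(self.date_formats),
                "default_equivalents": {k: list(v) for k, v in self.default_equivalents},
                "shelf_life_values": list(self.shelf_life_values),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationRules":
        data = json.loads(text)
        return cls(
            range_delimiters=tuple(data.get("range_delimiters", cls.range_delimiters)),
            date_formats=tuple(data.get("date_formats", cls.date_formats)),
            default_equivalents=tuple(
                (k, tuple(v)) for k, v in data.get("default_equivalents", {}).items()
            ) or cls.default_equivalents,
            shelf_life_values=tuple(data.get("shelf_life_values", cls.shelf_life_values)),
        )


DEFAULT_RULES = NormalizationRules()


# --- range expansion -------------------------------------------------------

def _range_re(rules: NormalizationRules) -> re.Pattern:
    delims = "|".join(re.escape(d) for d in rules.range_delimiters)
    return re.compile(
        rf"^(?P<prefix>.*/)(?P<a>\d+)\s*(?:{delims})\s*(?P<b>\d+)$"
    )


def expand_ranges(values: list[str], rules: NormalizationRules = DEFAULT_RULES) -> list[str]:
    """Expand ranged identifier tails into explicit enumerated values.

    ``[".../001", ".../002-004"]`` becomes ``[".../001", ".../002", ".../003",
    ".../004"]`` with the zero-padding width of the range start preserved.
    Descending or malformed ranges pass through unmodified with a warning.
    """
    pattern = _range_re(rules)
    out: list[str] = []
    for value in values:
        m = pattern.match(value.strip()) if isinstance(value, str) else None
        if not m:
            out.append(value)
            continue
        a, b = m.group("a"), m.group("b")
        width = len(a)
        lo, hi = int(a), int(b)
        if hi < lo:
            logger.warning("descending range %r left unexpanded", value)
            out.append(value)
            continue
        prefix = m.group("prefix")
        out.extend(f"{prefix}{i:0{width}d}" for i in range(lo, hi + 1))
    return out


# --- embedded JSON ---------------------------------------------------------

_BARE_TOKEN = re.compile(r'(?<![\w"])([^\[\]{},"\s][^\[\]{},"]*?)(?=\s*[,\]\}])')


def parse_embedded_json(value: Any) -> Any:
    """Convert strings holding JSON lists/objects into structured values.

    Repair is deliberately shallow: only bare tokens inside flat brackets are
    quoted (``'[ingredientA, ingredientB]'`` parses to a two-item list);
    anything else is returned verbatim.
    """
    if not isinstance(value, str):
        return value
    text = value.strip()
    if not (text.startswith("[") and text.endswith("]")) and not (
        text.startswith("{") and text.endswith("}")
    ):
        return value
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        pass
    repaired = _BARE_TOKEN.sub(lambda m: json.dumps(m.group(1).strip()), text)
    try:
        return json.loads(repaired)
    except json.JSONDecodeError:
        return value


# --- list cleaning ---------------------------------------------------------

_STRIP_CHARS = " \t\r\n[]'\"“”‘’"


def clean_list(values: list) -> list:
    """Strip stray brackets/quotes/whitespace and drop duplicate entries.

    Order is preserved (first occurrence wins); empty elements after cleaning
    are removed.
    """
    out: list = []
    seen: set = set()
    for v in values:
        if isinstance(v, str):
            v = v.strip(_STRIP_CHARS)
            if not v:
                continue
        key = json.dumps(v, sort_keys=True) if isinstance(v, (dict, list)) else v
        if key in seen:
            continue
        seen.add(key)
        out.append(v)
    return out


# --- key normalization -----------------------------------------------------

def normalize_keys(obj: Any) -> Any:
    """Recursively lowercase every dictionary key.

    Collisions after lowercasing keep the first key's value (a warning is
    logged); lists of mappings are handled; leaf values are untouched.
    """
    if isinstance(obj, dict):
        out: dict = {}
        for key, value in obj.items():
            low = key.lower() if isinstance(key, str) else key
            if low in out:
                logger.warning("key collision after lowercasing: %r dropped", key)
                continue
            out[low] = normalize_keys(value)
        return out
    if isinstance(obj, list):
        return [normalize_keys(v) for v in obj]
    return obj


# --- default equivalence ---------------------------------------------------

def canonicalize_default(
    field_path: str, value: str, rules: NormalizationRules = DEFAULT_RULES
) -> str:
    """Map phrases that are semantically equivalent to "no value" to "".

    For the storage-precautions field the standard "does not require any
    special storage conditions" phrase is canonically empty.  For the
    shelf-life value, the empty string and the configured standard phrases
    ("3 years", "6 years" by default) all map to the common canonical token
    (the empty string), expressing their equivalence class.
    """
    if not isinstance(value, str):
        return value
    stripped = value.strip()
    folded = stripped.casefold().rstrip(".")
    for phrase in rules.defaults_for(field_path):
        if folded == phrase.casefold().rstrip("."):
            return ""
    if field_path.endswith("shelf_life.value"):
        if not stripped or folded in {p.casefold() for p in rules.shelf_life_values}:
            return ""
    return stripped


# --- dates -----------------------------------------------------------------

def parse_date_value(
    text: Any, rules: NormalizationRules = DEFAULT_RULES
) -> str | None:
    """Parse a date string into ISO-8601 ``YYYY-MM-DD``; unparseable -> None.

    Accepts ISO, long-form English ("May 1, 2021" / "1 May 2021") and
    day-first numeric forms ("01/05/2021"); calendar validity is enforced
    (``31 February 2021`` is rejected).
    """
    if not isinstance(text, str):
        return None
    cleaned = text.strip().rstrip(".")
    if not cleaned:
        return None
    for fmt in rules.date_formats:
        try:
            return datetime.strptime(cleaned, fmt).date().isoformat()
        except ValueError:
            continue
    return None


# --- full-record normalization --------------------------------------------

def normalize_record(record: dict, rules: NormalizationRules = DEFAULT_RULES) -> dict:
    """Canonicalize a record (or raw extraction mapping) end to end.

    Fixed composition: key lowercasing, embedded-JSON parsing of list fields,
    range expansion of authorization numbers, list cleaning, canonicalization
    of configured default phrases, and ISO date parsing (unparseable date
    strings are kept verbatim).  Idempotent; never raises on content.
    """
    record = normalize_keys(copy.deepcopy(record))
    if not isinstance(record, dict):
        return record

    for spec in field_registry():
        if "[]" in spec.path:
            continue
        value = get_path(record, spec.path, default=None)
        if value is None:
            continue
        if spec.value_kind == "list-of-text":
            if isinstance(value, str):
                parsed = parse_embedded_json(value)
                value = parsed if isinstance(parsed, list) else ([value] if value else [])
            if isinstance(value, list):
                if spec.field_id == "marketing_authorization_number":
                    value = expand_ranges([str(v) for v in value], rules)
                value = clean_list(value)
            set_path(record, spec.path, value)
        elif spec.value_kind == "scalar-date":
            if isinstance(value, str):
                iso = parse_date_value(value, rules)
                set_path(record, spec.path, iso if iso is not None else value.strip())
        elif spec.value_kind == "scalar-text":
            if isinstance(value, str):
                if rules.defaults_for(spec.path):
                    value = canonicalize_default(spec.path, value, rules)
                set_path(record, spec.path, value.strip())

    # string scalars inside list-of-records entries: plain whitespace strip
    for list_path in (
        "ingredients.composition_active",
        "ingredients.composition_excipient",
        "packaged_medicinal_product.package.package_composition.package_component",
    ):
        items = get_path(record, list_path, default=None)
        if isinstance(items, list):
            set_path(record, list_path, [_strip_strings(e) for e in items])

    return drop_empty_entries(record)


def _strip_strings(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _strip_strings(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_strip_strings(v) for v in obj]
    if isinstance(obj, str):
        return obj.strip()
    return obj
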