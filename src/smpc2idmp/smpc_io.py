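"""Parsing of EMA-structured SmPC text and reading/writing of IDMP JSON.

An SmPC follows the EMA QRD template: ten numbered chapters ("1. NAME OF THE
MEDICINAL PRODUCT" ... "10. DATE OF REVISION OF THE TEXT") with dotted
subsections such as 4.1 or 6.5.  The parser detects numbered headings at line
starts and segments the document into ordered, non-overlapping chapter spans
that exactly cover the raw text (a heading line belongs to its chapter's
span; text before the first heading becomes the preamble chapter "0").

Input is plain UTF-8 text; converting PDFs to text is an external
preprocessing concern.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from .idmp_model import validate_record
from .normalize import normalize_keys

logger = logging.getLogger(__name__)

__all__ = [
    "Chapter",
    "SmpcDocument",
    "SmpcParseError",
    "IdmpSchemaError",
    "parse_smpc",
    "get_chapter",
    "read_idmp_json",
    "write_idmp_json",
]


class SmpcParseError(ValueError):
    pass


class IdmpSchemaError(ValueError):
    def __init__(self, violations):
        self.violations = violations
        super().__init__(
            "record violates the minimal-IDMP schema: "
            + "; ".join(f"{v.path}:{v.kind}" for v in violations)
        )


@dataclass(frozen=True)
class Chapter:
    chapter_id: str  # dotted number as text, "0" for the preamble
    title: str
    body: str  # full span text (heading line included), == raw_text[start:end]
    start: int  # 0-based, half-open
    end: int


@dataclass(frozen=True)
class SmpcDocument:
    doc_id: str
    raw_text: str
    chapters: tuple[Chapter, ...]

    def chapter_ids(self) -> list[str]:
        return [c.chapter_id for c in self.chapters]

    def chapter_at(self, offset: int) -> Chapter | None:
        """The chapter whose span contains a character offset."""
        for c in self.chapters:
            if c.start <= offset < c.end:
                return c
        return None


# A heading is a line starting with a 1-2 digit chapter number, optionally a
# 1-2 digit subsection, a separator ('.', ')' or whitespace) and a title.
_HEADING_RE = re.compile(r"^[ \t]{0,8}(\d{1,2}(?:\.\d{1,2})?)(?:[.)]|[ \t])[ \t]*(.*)$")


def _top(chapter_id: str) -> int:
    return int(chapter_id.split(".")[0])


def parse_smpc(text: str, doc_id: str = "") -> SmpcDocument:
    """Segment SmPC text into chapters by numbered headings.

    Headings must be monotonically ascending (top-level numbers strictly
    increasing, subsections ascending under their parent), which keeps body
    lines that happen to start with a number (doses, pack sizes) from being
    misread as headings.  Duplicate or out-of-order numbers stay in the
    current chapter's body with a warning.  A document without any heading
    yields the single preamble chapter "0".
    """
    if not text:
        raise SmpcParseError("empty SmPC text")

    # candidate headings: (offset-of-line-start, chapter_id, title)
    accepted: list[tuple[int, str, str]] = []
    last_top = 0
    last_sub = 0
    offset = 0
    for line in text.splitlines(keepends=True):
        m = _HEADING_RE.match(line.rstrip("\n"))
        if m and (not m.group(2).strip() or not m.group(2).strip()[0].islower()):
            # QRD headings are title- or upper-case; a lowercase "title" is a
            # body line that happens to start with a number ("3 years ...")
            cid, title = m.group(1), m.group(2).strip()
            top = _top(cid)
            if "." in cid:
                sub = int(cid.split(".")[1])
                ok = top == last_top and sub > last_sub
            else:
                # allow small forward jumps (a missing chapter), never repeats;
                # the QRD template has exactly ten top-level chapters
                ok = last_top < top <= min(last_top + 5, 10)
                sub = 0
            if ok:
                accepted.append((offset, cid, title))
                last_top, last_sub = top, sub
            else:
                logger.warning(
                    "ignoring out-of-order heading candidate %r in %s", cid, doc_id
                )
        offset += len(line)

    chapters: list[Chapter] = []
    if not accepted:
        logger.warning("no chapter headings detected in %s", doc_id)
        chapters.append(Chapter("0", "", text, 0, len(text)))
        return SmpcDocument(doc_id, text, tuple(chapters))

    if accepted[0][0] > 0:
        pre = text[: accepted[0][0]]
        chapters.append(Chapter("0", "", pre, 0, accepted[0][0]))

    for i, (start, cid, title) in enumerate(accepted):
        end = accepted[i + 1][0] if i + 1 < len(accepted) else len(text)
        chapters.append(Chapter(cid, title, text[start:end], start, end))

    return SmpcDocument(doc_id, text, tuple(chapters))


def get_chapter(doc: SmpcDocument, chapter_id: str) -> str:
    """Concatenated body of a chapter; a top-level id includes its subsections.

    An unknown id returns the empty string with a warning rather than raising.
    """
    parts = [
        c.body
        for c in doc.chapters
        if c.chapter_id == chapter_id
        or ("." not in chapter_id and c.chapter_id.split(".")[0] == chapter_id)
    ]
    if not parts:
        logger.warning("chapter %r not found in %s", chapter_id, doc.doc_id)
        return ""
    return "".join(parts)


def read_idmp_json(path: str | Path) -> dict:
    """Read one IDMP record from JSON, lowercasing keys and validating."""
    raw = Path(path).read_text(encoding="utf-8")
    try:
        data = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise SmpcParseError(
            f"{path}: not valid JSON at line {exc.lineno} column {exc.colno}"
        ) from exc
    record = normalize_keys(data)
    violations = validate_record(record)
    if violations:
        raise IdmpSchemaError(violations)
    return record


def write_idmp_json(record: dict, path: str | Path) -> None:
    """Write a validated record as UTF-8 JSON (keys lowercase snake_case)."""
    violations = validate_record(record)
    if violations:
        raise IdmpSchemaError(violations)
    Path(path).write_text(
        json.dumps(record, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )
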