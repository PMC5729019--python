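"""Shared plumbing: validation issues, canonical JSON, clocks and errors.

Everything that must be byte-deterministic (registry definitions, store
snapshots, exports) funnels through :func:`canonical_json`: UTF-8 JSON with
lexicographically sorted object keys, two-space indent and a trailing
newline.  Arrays keep their definition order.  Dates are ISO 8601
``YYYY-MM-DD``; timestamps are ISO 8601 UTC with a ``Z`` suffix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from typing import Any, Callable, Iterable

ERROR = "error"
WARNING = "warning"


@dataclass(frozen=True)
class ValidationIssue:
    """One problem found in a definition or a record.

    ``path`` locates the offending element with ``/``-separated segments
    (e.g. ``forms/HAEM/sections/S1/de_codes/3``).  ``error`` issues block
    persistence; ``warning`` issues do not.
    """

    severity: str
    path: str
    message: str

    def __str__(self) -> str:  # CLI rendering: "severity path message"
        return f"{self.severity} {self.path} {self.message}"


def has_errors(issues: Iterable[ValidationIssue]) -> bool:
    return any(i.severity == ERROR for i in issues)


class IrdrError(Exception):
    """Base class for all engine errors."""


class RMLSyntaxError(IrdrError):
    """The definition text is not well-formed in any accepted dialect."""


class DefinitionError(IrdrError):
    """A structurally invalid registry definition (dangling references,
    violated invariants).  Carries the issue list."""

    def __init__(self, issues: list[ValidationIssue], message: str | None = None):
        self.issues = list(issues)
        super().__init__(message or "; ".join(str(i) for i in self.issues))


class MergeConflictError(IrdrError):
    """Two differing definitions claim the same code during a DE-library
    merge; both versions are listed, nothing is overwritten."""

    def __init__(self, conflicts: list[tuple[str, Any, Any]]):
        self.conflicts = conflicts
        lines = [f"{code}: target={a!r} library={b!r}" for code, a, b in conflicts]
        super().__init__("merge conflict: " + "; ".join(lines))


class ValueError_(IrdrError):
    """A clinical value failed validation; the store was not touched."""

    def __init__(self, issues: list[ValidationIssue]):
        self.issues = list(issues)
        super().__init__("; ".join(str(i) for i in self.issues))


class UnknownCodeError(IrdrError):
    """A code (registry, form, DE, question, template...) does not resolve."""


class AccessDeniedError(IrdrError):
    """The acting user is not permitted to perform the operation."""


def canonical_json(obj: Any) -> str:
    """Serialize ``obj`` to the canonical dialect (deterministic bytes)."""
    return json.dumps(obj, sort_keys=True, ensure_ascii=False, indent=2,
                      default=_json_default) + "\n"


def _json_default(o: Any) -> Any:
    if isinstance(o, datetime):
        return format_timestamp(o)
    if isinstance(o, date):
        return o.isoformat()
    raise TypeError(f"not canonically serializable: {type(o).__name__}")


def format_timestamp(ts: datetime) -> str:
    """ISO 8601 UTC with 'Z' (naive datetimes are taken as UTC)."""
    if ts.tzinfo is not None:
        ts = ts.astimezone(timezone.utc).replace(tzinfo=None)
    return ts.isoformat(timespec="seconds") + "Z"


def parse_timestamp(text: str) -> datetime:
    if text.endswith("Z"):
        text = text[:-1]
    return datetime.fromisoformat(text).replace(tzinfo=timezone.utc)


def parse_date(text: str) -> date:
    """Strict ISO 8601 YYYY-MM-DD."""
    try:
        return date.fromisoformat(text)
    except (ValueError, TypeError) as exc:
        raise IrdrError(f"malformed date {text!r}: expected YYYY-MM-DD") from exc


Clock = Callable[[], datetime]


def system_clock() -> datetime:
    return datetime.now(timezone.utc)


class StepClock:
    """Deterministic injectable clock: starts at ``start`` and advances by
    ``step`` on every call.  Used throughout the tests and fixtures so that
    every timestamp in a generated cohort is reproducible."""

    def __init__(self, start: datetime | None = None,
                 step: timedelta = timedelta(minutes=1)):
        self._now = start or datetime(2018, 1, 1, 9, 0, 0, tzinfo=timezone.utc)
        self._step = step

    def __call__(self) -> datetime:
        now = self._now
        self._now = now + self._step
        return now
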