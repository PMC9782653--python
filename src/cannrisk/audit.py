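"""Structured audit trail threaded through every assessment decision."""

from __future__ import annotations

from typing import Any


class AuditLog:
    """Ordered list of decision records.

    Each entry is a plain dict (``step``, ``message``, optional ``data``) so the
    trail serializes directly into the JSON report.
    """

    def __init__(self) -> None:
        self.entries: list[dict[str, Any]] = []

    def add(self, step: str, message: str, **data: Any) -> None:
        entry: dict[str, Any] = {"step": step, "message": message}
        if data:
            entry["data"] = data
        self.entries.append(entry)

    def to_list(self) -> list[dict[str, Any]]:
        return [dict(e) for e in self.entries]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)
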