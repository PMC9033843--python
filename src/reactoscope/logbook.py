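"""Structured JSONL experiment logging and the pluggable notifier.

Every module writes through one :class:`ExperimentLog`; records are
append-only, one JSON object per line, gathered in a single file per
experiment. The notifier mirrors severe records to an external channel; the
file backend appends JSONL to a side file (a webhook backend could be
plugged in the same way, and is deliberately not bundled).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["LogRecord", "ExperimentLog", "Notifier", "FileNotifier"]


@dataclass(frozen=True)
class LogRecord:
    timestamp: float
    frame_index: int
    module: str
    severity: str  # "info" | "warning" | "error"
    message: str
    payload: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "timestamp": self.timestamp,
            "frame_index": self.frame_index,
            "module": self.module,
            "severity": self.severity,
            "message": self.message,
            "payload": self.payload,
        }, sort_keys=True, default=str)


class Notifier:
    """Interface for out-of-band notifications (progress, failures)."""

    def notify(self, record: LogRecord) -> None:  # pragma: no cover - interface
        raise NotImplementedError


class FileNotifier(Notifier):
    """Appends notification records as JSONL to a file."""

    def __init__(self, path):
        self.path = Path(path)

    def notify(self, record: LogRecord) -> None:
        with self.path.open("a") as fh:
            fh.write(record.to_json() + "\n")


class ExperimentLog:
    """Append-only experiment log; optionally mirrored to disk and notifier.

    ``frame_index`` is stamped from the attached experiment state (set by the
    acquisition loop); warnings and errors are forwarded to the notifier.
    """

    def __init__(self, path=None, notifier: Notifier | None = None,
                 wall_clock: bool = False):
        self.records: list[LogRecord] = []
        self.path = Path(path) if path else None
        self.notifier = notifier
        self.frame_index = 0
        self._wall_clock = wall_clock
        self._fh = self.path.open("a") if self.path else None

    def _emit(self, severity: str, module: str, message: str, **payload):
        rec = LogRecord(
            timestamp=time.time() if self._wall_clock else float(len(self.records)),
            frame_index=self.frame_index,
            module=module, severity=severity, message=message, payload=payload,
        )
        self.records.append(rec)
        if self._fh is not None:
            self._fh.write(rec.to_json() + "\n")
            self._fh.flush()
        if self.notifier is not None and severity in ("warning", "error"):
            self.notifier.notify(rec)
        return rec

    def info(self, module: str, message: str, **payload):
        return self._emit("info", module, message, **payload)

    def warning(self, module: str, message: str, **payload):
        return self._emit("warning", module, message, **payload)

    def error(self, module: str, message: str, **payload):
        return self._emit("error", module, message, **payload)

    def count(self, severity: str | None = None, message: str | None = None) -> int:
        return sum(1 for r in self.records
                   if (severity is None or r.severity == severity)
                   and (message is None or r.message == message))

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None
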