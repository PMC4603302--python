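"""Append-only pipeline log.

Every pipeline step (poll, detect, event, deliver) appends at least one
entry carrying a timestamp, the origin and destination of the step and a
short message — enough to re-enact a transaction when debugging an
integration.  Entries are mirrored to the standard :mod:`logging` stream
and optionally persisted to the relational store.
"""

from __future__ import annotations

import logging as _stdlog
import sqlite3
import threading
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Literal, Optional

_logger = _stdlog.getLogger("feedwire")

Status = Literal["ok", "warning", "error"]


@dataclass
class LogEntry:
    timestamp: datetime
    origin: str
    destination: str
    message: str
    status: Status = "ok"


class LogStore:
    """Thread-safe append-only log, optionally persisted to sqlite."""

    def __init__(self, db_path: Optional[str] = None) -> None:
        self.entries: list[LogEntry] = []
        self._lock = threading.Lock()
        self._db_path = db_path
        if db_path:
            with sqlite3.connect(db_path) as con:
                con.execute(
                    "CREATE TABLE IF NOT EXISTS log_entries ("
                    " timestamp TEXT, origin TEXT, destination TEXT,"
                    " message TEXT, status TEXT)"
                )

    def append(self, origin: str, destination: str, message: str,
               status: Status = "ok") -> LogEntry:
        entry = LogEntry(
            timestamp=datetime.now(timezone.utc),
            origin=origin,
            destination=destination,
            message=message,
            status=status,
        )
        with self._lock:
            self.entries.append(entry)
            if self._db_path:
                with sqlite3.connect(self._db_path) as con:
                    con.execute(
                        "INSERT INTO log_entries VALUES (?,?,?,?,?)",
                        (entry.timestamp.isoformat(), origin, destination,
                         message, status),
                    )
        level = {"ok": _stdlog.INFO, "warning": _stdlog.WARNING,
                 "error": _stdlog.ERROR}[status]
        _logger.log(level, "%s -> %s: %s", origin, destination, message)
        return entry

    def by_status(self, status: Status) -> list[LogEntry]:
        with self._lock:
            return [e for e in self.entries if e.status == status]

    def __len__(self) -> int:
        return len(self.entries)


def log_step(log: LogStore | None, origin: str, destination: str,
             message: str, status: Status = "ok") -> None:
    """Append to the store if one is wired in; always mirror to stdlib logging."""
    if log is not None:
        log.append(origin, destination, message, status)
    else:
        _logger.debug("%s -> %s: %s", origin, destination, message)
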