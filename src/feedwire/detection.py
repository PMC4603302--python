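"""Atomic change detection: fingerprints and the check-and-insert cache.

A record's *fingerprint* is either the value of a user-designated
identifier selector (the agent's ``cache_key``), or — when no field
identifies a record unequivocally — the MD5 digest of a canonical
serialization of the whole record.  Fingerprints are stored once per agent
scope; a record is "new" exactly when its fingerprint was absent, and the
check and the insert happen atomically so concurrent runs of the same agent
cannot double-fire an event.

Entries are never mutated or evicted: the cache is the system's complete
memory of what has already been integrated.
"""

from __future__ import annotations

import hashlib
import sqlite3
import threading
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Optional, Protocol

from .agents import AgentConfig, Record, cache_scope
from .errors import ConfigError, DetectionError
from .logging import LogStore, log_step


def fingerprint(record: Record, cache_key: Optional[str] = None) -> str:
    """Compute a record's cache fingerprint.

    With ``cache_key`` set, returns that selector's value verbatim (the
    user promises it identifies the record).  Otherwise returns the
    lowercase MD5 hex digest of the canonical serialization: ``key=value``
    lines, keys sorted lexicographically, joined by newlines, UTF-8.
    """
    if cache_key is not None:
        if cache_key not in record.values:
            raise ConfigError(f"cache_key {cache_key!r} absent from record")
        return record.values[cache_key]
    canonical = "\n".join(
        f"{k}={record.values[k]}" for k in sorted(record.values)
    )
    return hashlib.md5(canonical.encode("utf-8")).hexdigest()


@dataclass
class CacheEntry:
    scope: str
    fingerprint: str
    first_seen: datetime


class CacheBackend(Protocol):
    """Pluggable atomic fingerprint store.

    ``add_new`` is the single primitive: given a scope and an ordered batch
    of fingerprints it must atomically insert the unseen ones and report
    which they were, first occurrence winning within the batch.
    """

    def add_new(self, scope: str, fingerprints: list[str]) -> list[str]: ...

    def size(self, scope: str) -> int: ...


class MemoryCache:
    """In-process cache backend (tests, single-process deployments)."""

    def __init__(self) -> None:
        self._seen: dict[str, set[str]] = {}
        self._lock = threading.Lock()

    def add_new(self, scope: str, fingerprints: list[str]) -> list[str]:
        with self._lock:
            seen = self._seen.setdefault(scope, set())
            fresh = []
            for fp in fingerprints:
                if fp not in seen:
                    seen.add(fp)
                    fresh.append(fp)
            return fresh

    def size(self, scope: str) -> int:
        with self._lock:
            return len(self._seen.get(scope, set()))


class SqliteCache:
    """Cache backend persisted in the relational store.

    One table of (scope, fingerprint, first_seen) with a uniqueness
    constraint; the batch check-and-insert runs in a single IMMEDIATE
    transaction so it is atomic across processes sharing the file.
    """

    def __init__(self, path: str) -> None:
        self._path = path
        self._lock = threading.Lock()
        with self._connect() as con:
            con.execute(
                "CREATE TABLE IF NOT EXISTS cache_entries ("
                " scope TEXT NOT NULL,"
                " fingerprint TEXT NOT NULL,"
                " first_seen TEXT NOT NULL,"
                " UNIQUE (scope, fingerprint))"
            )

    def _connect(self) -> sqlite3.Connection:
        con = sqlite3.connect(self._path, timeout=30.0)
        con.execute("PRAGMA busy_timeout = 30000")
        return con

    def add_new(self, scope: str, fingerprints: list[str]) -> list[str]:
        now = datetime.now(timezone.utc).isoformat()
        try:
            with self._lock, self._connect() as con:
                con.execute("BEGIN IMMEDIATE")
                fresh = []
                for fp in fingerprints:
                    cur = con.execute(
                        "INSERT OR IGNORE INTO cache_entries VALUES (?,?,?)",
                        (scope, fp, now),
                    )
                    if cur.rowcount == 1:
                        fresh.append(fp)
                return fresh
        except sqlite3.Error as exc:
            raise DetectionError(f"cache backend failure: {exc}") from exc

    def size(self, scope: str) -> int:
        with self._connect() as con:
            (n,) = con.execute(
                "SELECT COUNT(*) FROM cache_entries WHERE scope = ?", (scope,)
            ).fetchone()
        return n


def detect_new(agent: AgentConfig, records: list[Record], cache: CacheBackend,
               log: LogStore | None = None) -> list[Record]:
    """Return the records whose fingerprints are new to the agent's scope.

    The returned sub-list preserves source order; the new fingerprints are
    inserted as part of the same atomic operation, so an immediate re-run
    sees nothing new.  Duplicate fingerprints within one batch count once
    (first occurrence wins).
    """
    scope = cache_scope(agent)
    fps = [fingerprint(r, agent.cache_key) for r in records]
    fresh = set(cache.add_new(scope, fps))
    out = []
    taken: set[str] = set()
    for record, fp in zip(records, fps):
        if fp in fresh and fp not in taken:
            taken.add(fp)
            out.append(record)
    log_step(log, "detector", "cache",
             f"{scope}: {len(out)} new of {len(records)} records")
    return out


def check_fingerprints(agent_id: str, fingerprints: list[str],
                       cache: CacheBackend,
                       log: LogStore | None = None) -> list[str]:
    """Bare-fingerprint variant of :func:`detect_new` for remote agents.

    Remote agents hash locally and ask the server which fingerprints are
    unseen; the server inserts them in the same atomic step.
    """
    fresh = cache.add_new(agent_id, fingerprints)
    log_step(log, "api", "cache",
             f"{agent_id}: {len(fresh)} new of {len(fingerprints)} fingerprints")
    return fresh
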