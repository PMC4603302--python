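"""Scheduling and the FIFO monitoring queue.

Agents name a schedule drawn from a configurable list (nothing is
hard-coded); the default list's smallest interval is five minutes — the
floor below which polling cost outweighs freshness for typical sources.
Due agents are enqueued as jobs on a single homogeneous queue with no
priority ordering, and a bounded worker pool drains it strictly in order
of arrival: with a limit of two workers and four queued jobs, the jobs are
processed two at a time, first come first served.

All timing goes through an injectable clock so tests run on simulated
time; the worker pool is real threads, since monitoring jobs are I/O bound.
"""

from __future__ import annotations

import json
import threading
import time
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Callable, Literal, Optional

from .agents import AgentConfig
from .errors import ConfigError
from .logging import LogStore, log_step

MINIMUM_INTERVAL = timedelta(minutes=5)


@dataclass(frozen=True)
class Schedule:
    name: str
    interval: timedelta


def default_schedules() -> dict[str, Schedule]:
    """The stock schedule list; deployments may replace it via settings."""
    table = {
        "every_5_minutes": timedelta(minutes=5),
        "every_15_minutes": timedelta(minutes=15),
        "hourly": timedelta(hours=1),
        "daily": timedelta(days=1),
        "weekly": timedelta(weeks=1),
    }
    return {name: Schedule(name, iv) for name, iv in table.items()}


def load_settings(path: str | Path) -> tuple[dict[str, Schedule], int]:
    """Read the schedule list and worker limit from a JSON settings file.

    Expected shape: ``{"schedules": {"name": <seconds>, ...},
    "worker_limit": <int>}``; both keys optional, defaults apply.
    """
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    schedules = default_schedules()
    if "schedules" in doc:
        schedules = {
            name: Schedule(name, timedelta(seconds=float(seconds)))
            for name, seconds in doc["schedules"].items()
        }
    worker_limit = int(doc.get("worker_limit", 2))
    if worker_limit < 1:
        raise ConfigError("worker_limit must be >= 1")
    return schedules, worker_limit


def due_agents(now: datetime, agents: list[AgentConfig],
               last_runs: dict[str, datetime],
               schedules: Optional[dict[str, Schedule]] = None) -> list[AgentConfig]:
    """Agents whose schedule interval has elapsed since their last run.

    Never-run agents are due immediately.  Order is the stable input
    order.  Unknown schedule names are configuration errors.
    """
    table = schedules if schedules is not None else default_schedules()
    due = []
    for agent in agents:
        if not agent.enabled:
            continue
        if agent.schedule not in table:
            raise ConfigError(f"agent {agent.id}: unknown schedule {agent.schedule!r}")
        last = last_runs.get(agent.id)
        if last is None or now - last >= table[agent.schedule].interval:
            due.append(agent)
    return due


@dataclass
class Job:
    id: str
    agent_id: str
    enqueued_at: datetime
    state: Literal["queued", "running", "done", "failed"] = "queued"


@dataclass
class TraceEntry:
    """Observed execution of one job (wall-clock floats from the pool clock)."""

    job_id: str
    agent_id: str
    started: float
    finished: float
    error: str = ""
    seq: int = 0  # global start order (ties in `started` are resolved by this)


@dataclass
class Trace:
    entries: list[TraceEntry] = field(default_factory=list)

    def start_order(self) -> list[str]:
        return [e.job_id for e in sorted(self.entries, key=lambda e: e.seq)]

    def peak_concurrency(self) -> int:
        """Max number of jobs simultaneously running over the trace."""
        points = [(e.started, 1) for e in self.entries]
        points += [(e.finished, -1) for e in self.entries]
        # finishes sort before starts at the same instant
        points.sort(key=lambda p: (p[0], p[1]))
        peak = cur = 0
        for _, delta in points:
            cur += delta
            peak = max(peak, cur)
        return peak


class JobQueue:
    """Homogeneous FIFO queue with at most one pending job per agent."""

    def __init__(self, now: Callable[[], datetime] | None = None) -> None:
        self._jobs: list[Job] = []
        self._pending: set[str] = set()
        self._lock = threading.Lock()
        self._counter = 0
        self._now = now or (lambda: datetime.now(timezone.utc))

    def enqueue(self, agent_id: str) -> Optional[Job]:
        """Append a job unless one is already pending for this agent."""
        with self._lock:
            if agent_id in self._pending:
                return None
            self._counter += 1
            job = Job(id=f"job-{self._counter}", agent_id=agent_id,
                      enqueued_at=self._now())
            self._jobs.append(job)
            self._pending.add(agent_id)
            return job

    def __len__(self) -> int:
        with self._lock:
            return len(self._jobs)

    def drain(self) -> list[Job]:
        with self._lock:
            jobs, self._jobs = self._jobs, []
            self._pending.clear()
            return jobs


def process(queue: JobQueue, worker: Callable[[Job], None],
            worker_limit: int = 2, log: LogStore | None = None,
            clock: Callable[[], float] = time.monotonic) -> Trace:
    """Drain the queue with at most *worker_limit* concurrent workers.

    Jobs start strictly in arrival order; a failing job is marked failed
    and logged but never blocks the jobs behind it.  Returns the execution
    trace (start/finish instants per job) for inspection.
    """
    if worker_limit < 1:
        raise ConfigError("worker_limit must be >= 1")
    jobs = queue.drain()
    trace = Trace()
    trace_lock = threading.Lock()
    slots = threading.Semaphore(worker_limit)
    start_gate = threading.Lock()  # serializes starts so FIFO order is exact
    seq_counter = [0]

    def run(job: Job) -> None:
        try:
            started = clock()
            seq_counter[0] += 1
            seq = seq_counter[0]
            job.state = "running"
        finally:
            start_gate.release()
        error = ""
        try:
            worker(job)
            job.state = "done"
        except Exception as exc:  # failure isolation: log and continue
            job.state = "failed"
            error = str(exc)
            log_step(log, "queue", f"job:{job.id}", f"failed: {exc}", "error")
        finally:
            finished = clock()
            with trace_lock:
                trace.entries.append(TraceEntry(job.id, job.agent_id,
                                                started, finished, error, seq))
            slots.release()

    threads = []
    for job in jobs:
        slots.acquire()      # bounded concurrency
        start_gate.acquire()  # released by the worker once it has started
        t = threading.Thread(target=run, args=(job,), daemon=True)
        t.start()
        threads.append(t)
    for t in threads:
        t.join()
    return trace
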