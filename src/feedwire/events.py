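"""Events, integrations and the central router.

A detected change becomes an :class:`Event` — an atomic unit carrying the
extracted key→value payload, its fingerprint and a timestamp: everything a
delivery needs, with no later lookups into the source.  *Integrations*
bind sets of agents to sets of templates, giving many-to-many data
distribution; the :class:`Router` is the flow controller that fans each
event out to every template of every enabled integration its agent belongs
to, one delivery at a time, and also accepts events pushed from outside
(the passive pipeline that skips change detection).
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field
from datetime import datetime, timezone

from pydantic import BaseModel, model_validator

from .agents import AgentConfig, Record, cache_scope
from .detection import CacheBackend, fingerprint
from .errors import ValidationError
from .logging import LogStore, log_step
from .postman import DeliveryReport, Postman
from .templates import Template


@dataclass
class Event:
    """One atomic detected change, ready for delivery."""

    id: str
    agent_id: str
    created_at: datetime
    payload: dict[str, str]
    fingerprint: str

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "agent_id": self.agent_id,
            "created_at": self.created_at.isoformat(),
            "payload": dict(self.payload),
            "fingerprint": self.fingerprint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Event":
        return cls(
            id=d["id"],
            agent_id=d["agent_id"],
            created_at=datetime.fromisoformat(d["created_at"]),
            payload=dict(d["payload"]),
            fingerprint=d["fingerprint"],
        )


class Integration(BaseModel):
    """Many-to-many binding of agents (origins) to templates (destinations)."""

    id: str
    name: str = ""
    agent_ids: set[str]
    template_ids: set[str]
    enabled: bool = True

    @model_validator(mode="after")
    def _non_empty_when_enabled(self) -> "Integration":
        if self.enabled and (not self.agent_ids or not self.template_ids):
            raise ValueError(
                f"integration {self.id}: enabled integrations need agents and templates"
            )
        return self


def create_events(agent: AgentConfig, new_records: list[Record],
                  now: datetime | None = None,
                  log: LogStore | None = None) -> list[Event]:
    """Wrap records already deemed new into events, preserving order."""
    stamp = now or datetime.now(timezone.utc)
    events = [
        Event(
            id=uuid.uuid4().hex,
            agent_id=agent.id,
            created_at=stamp,
            payload=dict(r.values),
            fingerprint=fingerprint(r, agent.cache_key),
        )
        for r in new_records
    ]
    if events:
        log_step(log, "detector", "router", f"{agent.id}: {len(events)} events")
    return events


class Router:
    """Central flow controller: matches events to integrations and delivers.

    Deliveries for one event run sequentially in template-id order within
    each integration (integrations in id order); a failing template never
    aborts its siblings.  An agent belonging to two integrations that share
    a template gets that template fired once per integration — routing is
    per integration membership.
    """

    def __init__(self, integrations: dict[str, Integration],
                 templates: dict[str, Template], postman: Postman,
                 log: LogStore | None = None) -> None:
        self.integrations = integrations
        self.templates = templates
        self.postman = postman
        self.log = log

    def targets_for(self, agent_id: str) -> list[Template]:
        """Templates to fire for one event of *agent_id*, route order."""
        out: list[Template] = []
        for integration in sorted(self.integrations.values(), key=lambda i: i.id):
            if not integration.enabled:
                continue
            # membership matches either the concrete agent or its seed parent
            if agent_id not in integration.agent_ids and \
               agent_id.split("[", 1)[0] not in integration.agent_ids:
                continue
            for tid in sorted(integration.template_ids):
                template = self.templates.get(tid)
                if template is not None:
                    out.append(template)
        return out

    def route(self, event: Event) -> list[DeliveryReport]:
        """Deliver *event* once per template of every enabled integration
        containing its agent; individual failures do not abort the rest."""
        targets = self.targets_for(event.agent_id)
        if not targets:
            log_step(self.log, "router", f"agent:{event.agent_id}",
                     "event matched no enabled integration", "warning")
            return []
        reports = []
        for template in targets:
            log_step(self.log, "router", f"template:{template.id}",
                     f"dispatching event {event.id}")
            reports.append(self.postman.deliver(event, template))
        return reports

    def push_event(self, agent: AgentConfig, payload: dict[str, str],
                   cache: CacheBackend) -> list[DeliveryReport]:
        """Accept an externally pushed payload and route it like a detected
        event (the detection sub-sequence is skipped).

        The payload's fingerprint is still registered in the agent's cache
        scope, so a later poll of the same source does not re-deliver the
        same record.  Payload keys must match the agent's declared
        selectors exactly... unknown keys are a :class:`ValidationError`.
        """
        declared = set(agent.selector_keys)
        unknown = set(payload) - declared
        if unknown:
            raise ValidationError(
                f"agent {agent.id}: pushed payload has undeclared keys {sorted(unknown)}"
            )
        record = Record(values={k: str(v) for k, v in payload.items()},
                        source_agent=agent.id)
        fp = fingerprint(record, agent.cache_key)
        cache.add_new(cache_scope(agent), [fp])
        event = Event(
            id=uuid.uuid4().hex,
            agent_id=agent.id,
            created_at=datetime.now(timezone.utc),
            payload=record.values,
            fingerprint=fp,
        )
        log_step(self.log, f"agent:{agent.id}", "router",
                 f"pushed event {event.id}")
        return self.route(event)
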