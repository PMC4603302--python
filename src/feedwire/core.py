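"""The hub: registries plus the end-to-end monitoring pipeline.

The :class:`Hub` is the in-process equivalent of the server: it owns the
agent/seed/template/integration registries, the fingerprint cache, the log
store, the delivery executor and the router, and exposes the complete
pipeline — poll, extract, detect, create events, route, deliver — as
:meth:`run_agent` / :meth:`run_integration`.  The HTTP service layer and
the CLI are thin shells over this object.
"""

from __future__ import annotations

from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from .agents import (
    AgentConfig, SeedConfig, Record, expand_seeds, extract, poll,
)
from .detection import CacheBackend, MemoryCache, detect_new
from .errors import NotFoundError
from .events import Event, Integration, Router, create_events
from .logging import LogStore, log_step
from .postman import DeliveryReport, Postman
from .templates import Template


def monitor(agent: AgentConfig, cache: CacheBackend,
            log: LogStore | None = None) -> list[Event]:
    """Run one monitoring pass: poll, extract, detect, create events.

    Exactly the records whose fingerprints are new to the agent's cache
    scope become events.  Poll or extraction failures propagate and leave
    the cache untouched (a failed run never caches partial content).
    """
    content = poll(agent, log)
    records = extract(content, agent, log)
    new_records = detect_new(agent, records, cache, log)
    return create_events(agent, new_records, log=log)


class Hub:
    """Everything one deployment needs, wired together."""

    def __init__(self, cache: Optional[CacheBackend] = None,
                 postman: Optional[Postman] = None,
                 log: Optional[LogStore] = None,
                 workspace: str | Path = ".") -> None:
        self.log = log if log is not None else LogStore()
        self.cache = cache if cache is not None else MemoryCache()
        self.postman = postman or Postman(workspace=workspace, log=self.log)
        self.agents: dict[str, AgentConfig] = {}
        self.seeds: dict[str, SeedConfig] = {}
        self.templates: dict[str, Template] = {}
        self.integrations: dict[str, Integration] = {}
        self.owners: dict[str, str] = {}  # agent id -> owning user
        self.last_runs: dict[str, datetime] = {}
        self.router = Router(self.integrations, self.templates,
                             self.postman, self.log)

    # -- registry ---------------------------------------------------------

    def register_agent(self, agent: AgentConfig, owner: str = "default") -> None:
        self.agents[agent.id] = agent
        self.owners[agent.id] = owner

    def register_seed(self, seed: SeedConfig) -> None:
        self.seeds[seed.id] = seed

    def register_template(self, template: Template) -> None:
        self.templates[template.id] = template

    def register_integration(self, integration: Integration) -> None:
        self.integrations[integration.id] = integration

    def get_agent(self, agent_id: str) -> AgentConfig:
        try:
            return self.agents[agent_id]
        except KeyError:
            raise NotFoundError(f"no such agent: {agent_id}") from None

    # -- pipeline ---------------------------------------------------------

    def concrete_agents(self, agent: AgentConfig) -> list[AgentConfig]:
        """Resolve seed references and expand placeholders."""
        seeds = [self.seeds[sid] for sid in agent.seed_refs if sid in self.seeds]
        if not seeds:
            seeds = list(self.seeds.values())
        return expand_seeds(agent, seeds, self.log)

    def run_agent(self, agent_id: str) -> list[DeliveryReport]:
        """Full pipeline for one agent definition (seed-expanded)."""
        agent = self.get_agent(agent_id)
        if not agent.enabled:
            log_step(self.log, f"agent:{agent_id}", "queue",
                     "agent disabled, skipped", "warning")
            return []
        reports: list[DeliveryReport] = []
        for concrete in self.concrete_agents(agent):
            for event in monitor(concrete, self.cache, self.log):
                reports.extend(self.router.route(event))
        self.last_runs[agent_id] = datetime.now(timezone.utc)
        return reports

    def run_integration(self, integration_id: str) -> list[DeliveryReport]:
        """Run the pipeline once for every member agent of an integration."""
        try:
            integration = self.integrations[integration_id]
        except KeyError:
            raise NotFoundError(f"no such integration: {integration_id}") from None
        if not integration.enabled:
            log_step(self.log, f"integration:{integration_id}", "queue",
                     "integration disabled, nothing delivered", "warning")
            return []
        reports: list[DeliveryReport] = []
        for agent_id in sorted(integration.agent_ids):
            if agent_id in self.agents:
                reports.extend(self.run_agent(agent_id))
        return reports

    def push_event(self, agent_id: str, payload: dict[str, str]) -> list[DeliveryReport]:
        """Passive pipeline: accept a pushed payload for *agent_id*."""
        agent = self.get_agent(agent_id)
        return self.router.push_event(agent, payload, self.cache)
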