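"""JSON (de)serialization of configurations.

Everything a deployment or a remote agent needs is expressed as one JSON
document — the same shared shape on the server and in the client's private
local file.  Server-side documents list agents, seeds, templates and
integrations; client-side documents add the server URL and the access
token (which is never logged).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pydantic
from pydantic import BaseModel

from .agents import AgentConfig, SeedConfig
from .core import Hub
from .detection import SqliteCache
from .errors import ConfigError
from .events import Integration
from .logging import LogStore
from .postman import Postman
from .templates import Template


class ClientConfig(BaseModel):
    """A remote/local agent runner's private configuration file."""

    server_url: Optional[str] = None
    token: Optional[str] = None
    local_only: bool = False
    agents: list[AgentConfig] = []
    seeds: list[SeedConfig] = []
    # used only in local mode, where delivery happens in-process
    templates: list[Template] = []
    integrations: list[Integration] = []
    workspace: str = "."
    cache_db: Optional[str] = None

    def validate_mode(self) -> None:
        if not self.local_only:
            if not self.server_url:
                raise ConfigError("remote mode requires server_url")
            if not self.token:
                raise ConfigError("remote mode requires an access token")


def load_client_config(path: str | Path) -> ClientConfig:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config {path} is not valid JSON: {exc}") from exc
    try:
        return ClientConfig.model_validate(doc)
    except pydantic.ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def hub_from_config(config: ClientConfig, log: LogStore | None = None) -> Hub:
    """Build a ready-to-run in-process hub from a configuration document."""
    log = log if log is not None else LogStore()
    cache = SqliteCache(config.cache_db) if config.cache_db else None
    hub = Hub(cache=cache, log=log,
              postman=Postman(workspace=config.workspace, log=log))
    for seed in config.seeds:
        hub.register_seed(seed)
    for agent in config.agents:
        hub.register_agent(agent)
    for template in config.templates:
        hub.register_template(template)
    for integration in config.integrations:
        hub.register_integration(integration)
    return hub


def dump_client_config(config: ClientConfig, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(config.model_dump(mode="json"), indent=2) + "\n",
        encoding="utf-8",
    )
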