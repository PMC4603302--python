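"""Remote-agent runner: monitor locally, verify and deliver via the API.

A remote agent has direct access to a resource the server cannot reach (a
private database, a file behind a firewall).  It polls and extracts
in-process, hashes each record, asks the server which fingerprints are new
(``/api/agents/<id>/check``) and pushes only those records' payloads
(``/api/agents/<id>/events``); the server routes them through the normal
delivery pipeline.  Credentials stay in the client's private config file.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.request
from typing import Callable

from .agents import AgentConfig, SeedConfig, expand_seeds, extract, poll
from .detection import fingerprint
from .errors import AuthError, NotFoundError, PollError, ValidationError
from .logging import LogStore, log_step

HTTP_TIMEOUT = 15.0

#: (method, url, headers, body) -> (status, parsed JSON body)
ApiCall = Callable[[str, str, dict, bytes], tuple[int, dict]]


def _default_api_call(method: str, url: str, headers: dict,
                      body: bytes) -> tuple[int, dict]:
    req = urllib.request.Request(url, method=method, data=body, headers=headers)
    try:
        with urllib.request.urlopen(req, timeout=HTTP_TIMEOUT) as resp:
            return resp.status, json.loads(resp.read().decode("utf-8"))
    except urllib.error.HTTPError as exc:
        try:
            doc = json.loads(exc.read().decode("utf-8"))
        except Exception:
            doc = {}
        return exc.code, doc


class RemoteClient:
    """Drives one agent's check/push cycle against a server."""

    def __init__(self, server_url: str, token: str,
                 api_call: ApiCall = _default_api_call,
                 log: LogStore | None = None) -> None:
        self.server_url = server_url.rstrip("/")
        self.token = token
        self.api_call = api_call
        self.log = log

    def _post(self, route: str, doc: dict) -> dict:
        status, body = self.api_call(
            "POST",
            f"{self.server_url}{route}",
            {"Authorization": f"Token {self.token}",
             "Content-Type": "application/json"},
            json.dumps(doc).encode("utf-8"),
        )
        if status == 401 or status == 403:
            raise AuthError(body.get("error", f"HTTP {status}"))
        if status == 404:
            raise NotFoundError(body.get("error", "not found"))
        if status == 400:
            raise ValidationError(body.get("error", "bad request"))
        if status >= 500:
            raise PollError(f"server error HTTP {status}")
        return body

    def check(self, agent_id: str, fingerprints: list[str]) -> list[str]:
        body = self._post(f"/api/agents/{agent_id}/check",
                          {"fingerprints": fingerprints})
        return list(body.get("new", []))

    def push(self, agent_id: str, payload: dict[str, str]) -> list[dict]:
        body = self._post(f"/api/agents/{agent_id}/events",
                          {"payload": payload})
        return list(body.get("deliveries", []))

    def run_agent(self, agent: AgentConfig,
                  seeds: list[SeedConfig] | None = None) -> int:
        """One remote monitoring pass; returns the number of pushed events.

        The server-side scope is the configured agent id, so local and
        remote monitoring of the same resource share one cache scope.
        """
        pushed = 0
        for concrete in expand_seeds(agent, seeds or [], self.log):
            records = extract(poll(concrete, self.log), concrete, self.log)
            fps = [fingerprint(r, concrete.cache_key) for r in records]
            new = set(self.check(agent.id, fps))
            seen: set[str] = set()
            for record, fp in zip(records, fps):
                if fp in new and fp not in seen:
                    seen.add(fp)
                    self.push(agent.id, record.values)
                    pushed += 1
        log_step(self.log, f"agent:{agent.id}", "api",
                 f"remote run pushed {pushed} events")
        return pushed
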