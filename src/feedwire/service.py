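"""Token-authenticated HTTP surface for remote agents.

Remote agents never touch the cache or the router directly; they call two
JSON endpoints on the server:

* ``POST /api/agents/<id>/check`` — body ``{"fingerprints": [...]}``;
  returns ``{"new": [...]}``, the subset never seen in that agent's scope
  (inserting them atomically, exactly like local detection).
* ``POST /api/agents/<id>/events`` — body ``{"payload": {...}}``; pushes
  one event through the delivery pipeline, skipping detection, and returns
  the per-template delivery statuses.

Every route requires an ``Authorization: Token <value>`` header carrying a
32-character access token; a token only reaches its owner's agents.  The
app is plain WSGI, so it runs under any compliant server and is callable
in-process for tests.
"""

from __future__ import annotations

import json
import re
import secrets
import string
import threading
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Iterable, Optional
from wsgiref.simple_server import WSGIServer, WSGIRequestHandler, make_server

from .core import Hub
from .errors import AuthError, NotFoundError, ValidationError

TOKEN_LENGTH = 32
_TOKEN_ALPHABET = string.ascii_lowercase + string.digits


@dataclass
class AccessToken:
    token: str
    owner: str
    revoked: bool = False
    created_at: datetime = field(
        default_factory=lambda: datetime.now(timezone.utc)
    )


class TokenStore:
    """Issues, revokes and verifies user access tokens."""

    def __init__(self) -> None:
        self._tokens: dict[str, AccessToken] = {}
        self._lock = threading.Lock()

    def generate(self, owner: str) -> AccessToken:
        """Mint a unique 32-character token for *owner* from a
        cryptographically strong source."""
        with self._lock:
            while True:
                value = "".join(
                    secrets.choice(_TOKEN_ALPHABET) for _ in range(TOKEN_LENGTH)
                )
                if value not in self._tokens:
                    break
            token = AccessToken(token=value, owner=owner)
            self._tokens[value] = token
            return token

    def revoke(self, value: str) -> None:
        with self._lock:
            if value in self._tokens:
                self._tokens[value].revoked = True

    def authenticate(self, value: Optional[str]) -> str:
        """Return the owning user or raise :class:`AuthError`."""
        if not value:
            raise AuthError("missing access token")
        with self._lock:
            token = self._tokens.get(value)
            if token is None or token.revoked:
                raise AuthError("unknown or revoked access token")
            return token.owner


_ROUTE = re.compile(r"^/api/agents/(?P<agent_id>[^/]+)/(?P<action>check|events)$")


class ServiceApp:
    """WSGI application exposing the remote-agent API of a :class:`Hub`."""

    def __init__(self, hub: Hub, tokens: Optional[TokenStore] = None) -> None:
        self.hub = hub
        self.tokens = tokens or TokenStore()

    # -- request handling -------------------------------------------------

    def __call__(self, environ: dict, start_response: Callable) -> Iterable[bytes]:
        status, doc = self.handle(
            method=environ.get("REQUEST_METHOD", "GET"),
            path=environ.get("PATH_INFO", "/"),
            auth_header=environ.get("HTTP_AUTHORIZATION"),
            body=self._read_body(environ),
        )
        payload = json.dumps(doc).encode("utf-8")
        start_response(
            f"{status} {_REASONS.get(status, '')}".strip(),
            [("Content-Type", "application/json"),
             ("Content-Length", str(len(payload)))],
        )
        return [payload]

    @staticmethod
    def _read_body(environ: dict) -> bytes:
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
        except ValueError:
            length = 0
        if length <= 0:
            return b""
        return environ["wsgi.input"].read(length)

    def handle(self, method: str, path: str, auth_header: Optional[str],
               body: bytes) -> tuple[int, dict]:
        """Transport-independent request handler (used directly in tests)."""
        token_value = None
        if auth_header and auth_header.startswith("Token "):
            token_value = auth_header[len("Token "):].strip()
        try:
            owner = self.tokens.authenticate(token_value)
        except AuthError as exc:
            return 401, {"error": str(exc)}

        match = _ROUTE.match(path)
        if match is None:
            return 404, {"error": f"no such route: {path}"}
        if method != "POST":
            return 405, {"error": "POST required"}

        agent_id = match["agent_id"]
        try:
            self.hub.get_agent(agent_id)
        except NotFoundError as exc:
            return 404, {"error": str(exc)}
        if self.hub.owners.get(agent_id) != owner:
            return 403, {"error": f"agent {agent_id} belongs to another user"}

        try:
            doc = json.loads(body.decode("utf-8")) if body else {}
        except (json.JSONDecodeError, UnicodeDecodeError):
            return 400, {"error": "request body is not valid JSON"}

        if match["action"] == "check":
            return self._do_check(agent_id, doc)
        return self._do_push(agent_id, doc)

    # -- endpoints --------------------------------------------------------

    def _do_check(self, agent_id: str, doc: dict) -> tuple[int, dict]:
        fingerprints = doc.get("fingerprints")
        if not isinstance(fingerprints, list) or \
           not all(isinstance(f, str) for f in fingerprints):
            return 400, {"error": "'fingerprints' must be a list of strings"}
        from .detection import check_fingerprints

        new = check_fingerprints(agent_id, fingerprints, self.hub.cache,
                                 self.hub.log)
        return 200, {"new": new}

    def _do_push(self, agent_id: str, doc: dict) -> tuple[int, dict]:
        payload = doc.get("payload")
        if not isinstance(payload, dict):
            return 400, {"error": "'payload' must be an object"}
        try:
            reports = self.hub.push_event(
                agent_id, {str(k): str(v) for k, v in payload.items()}
            )
        except ValidationError as exc:
            return 400, {"error": str(exc)}
        return 200, {
            "deliveries": [
                {"template_id": r.template_id, "status": r.status,
                 "detail": r.detail}
                for r in reports
            ]
        }


class _QuietHandler(WSGIRequestHandler):
    def log_message(self, *args) -> None:  # keep test output clean
        pass


def serve(app: ServiceApp, host: str = "127.0.0.1", port: int = 0) -> WSGIServer:
    """Bind a wsgiref server (port 0 = ephemeral); caller drives it."""
    return make_server(host, port, app, handler_class=_QuietHandler)


_REASONS = {200: "OK", 400: "Bad Request", 401: "Unauthorized",
            403: "Forbidden", 404: "Not Found", 405: "Method Not Allowed"}
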