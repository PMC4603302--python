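"""Delivery execution: apply one event to one template.

The delivery executor renders the template's text fields against the event
payload and dispatches to a type-specific backend: execute a SQL statement
on the destination database, compose and send an email, create/append/
delete a file inside the user workspace, or issue an HTTP GET/POST.

Failure semantics are deliberately simple: one attempt, one timeout, no
retries, and a failed delivery never rolls back the detection cache (the
record stays "seen"; delivery verification is out of scope).  Each attempt
yields exactly one :class:`DeliveryReport` and one log entry.
"""

from __future__ import annotations

import sqlite3
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from datetime import datetime, timezone
from email.message import EmailMessage
from pathlib import Path
from typing import Callable, Literal, Optional, Protocol

from .agents import sqlite_path
from .errors import DeliveryError, RenderError
from .logging import LogStore, log_step
from .templates import (
    FileMode, HttpMethod, PayloadFormat, RenderContext, Template,
    TemplateType, quote_sql, render,
)

HTTP_TIMEOUT = 15.0  # one network timeout per delivery, zero retries

CONTENT_TYPES = {
    PayloadFormat.text: "text/plain",
    PayloadFormat.json: "application/json",
    PayloadFormat.xml: "application/xml",
}


@dataclass
class DeliveryReport:
    event_id: str
    template_id: str
    status: Literal["delivered", "failed"]
    detail: str = ""
    timestamp: datetime = field(
        default_factory=lambda: datetime.now(timezone.utc)
    )


class EmailTransport(Protocol):
    def send(self, message: EmailMessage) -> None: ...


class CaptureEmailTransport:
    """In-process transport collecting messages (tests, dry runs)."""

    def __init__(self) -> None:
        self.sent: list[EmailMessage] = []

    def send(self, message: EmailMessage) -> None:
        self.sent.append(message)


class SmtpEmailTransport:
    """Hands messages to an SMTP relay."""

    def __init__(self, host: str = "localhost", port: int = 25,
                 sender: str = "feedwire@localhost") -> None:
        self.host, self.port, self.sender = host, port, sender

    def send(self, message: EmailMessage) -> None:
        import smtplib

        if "From" not in message:
            message["From"] = self.sender
        with smtplib.SMTP(self.host, self.port, timeout=HTTP_TIMEOUT) as smtp:
            smtp.send_message(message)


#: request -> (status code, response body); injectable for tests
HttpSend = Callable[[urllib.request.Request], tuple[int, bytes]]


def _default_http_send(req: urllib.request.Request) -> tuple[int, bytes]:
    with urllib.request.urlopen(req, timeout=HTTP_TIMEOUT) as resp:
        return resp.status, resp.read()


class Postman:
    """Executes final deliveries for rendered templates."""

    def __init__(self, workspace: str | Path = ".",
                 email_transport: Optional[EmailTransport] = None,
                 http_send: HttpSend = _default_http_send,
                 log: LogStore | None = None) -> None:
        self.workspace = Path(workspace).resolve()
        self.email_transport = email_transport or CaptureEmailTransport()
        self.http_send = http_send
        self.log = log

    # -- dispatch ---------------------------------------------------------

    def deliver(self, event: "Event", template: Template) -> DeliveryReport:
        """Render *template* with *event*'s payload and execute it."""
        ctx = RenderContext(variables=dict(event.payload),
                            now=datetime.now(timezone.utc))
        try:
            if template.type == TemplateType.sql:
                detail = self._deliver_sql(template, ctx)
            elif template.type == TemplateType.email:
                detail = self._deliver_email(template, ctx)
            elif template.type == TemplateType.file:
                detail = self._deliver_file(template, ctx)
            elif template.type == TemplateType.url:
                detail = self._deliver_url(template, ctx)
            else:  # pragma: no cover - enum is closed
                raise DeliveryError(f"unsupported template type {template.type}")
            report = DeliveryReport(event.id, template.id, "delivered", detail)
        except (DeliveryError, RenderError, OSError) as exc:
            report = DeliveryReport(event.id, template.id, "failed", str(exc))
        log_step(self.log, f"event:{event.id}", f"template:{template.id}",
                 report.detail or report.status,
                 "ok" if report.status == "delivered" else "error")
        return report

    # -- executors --------------------------------------------------------

    def _deliver_sql(self, template: Template, ctx: RenderContext) -> str:
        if template.escape_sql:
            ctx.value_filter = quote_sql
        statement = render(template.statement, ctx)
        path = sqlite_path(template.connection)
        try:
            con = sqlite3.connect(path, timeout=HTTP_TIMEOUT)
            try:
                # rendered text runs as a single statement batch
                con.executescript(statement)
                con.commit()
            finally:
                con.close()
        except sqlite3.Error as exc:
            raise DeliveryError(f"sql delivery failed: {exc}") from exc
        return f"executed on {path}"

    def _deliver_email(self, template: Template, ctx: RenderContext) -> str:
        msg = EmailMessage()
        msg["To"] = render(template.to, ctx)
        if template.cc:
            msg["Cc"] = render(template.cc, ctx)
        if template.bcc:
            msg["Bcc"] = render(template.bcc, ctx)
        msg["Subject"] = render(template.subject, ctx)
        msg.set_content(render(template.message, ctx))
        self.email_transport.send(msg)
        return f"mailed to {msg['To']}"

    def _resolve_in_workspace(self, rendered: str) -> Path:
        candidate = (self.workspace / rendered).resolve()
        if candidate != self.workspace and self.workspace not in candidate.parents:
            raise DeliveryError(
                f"path {rendered!r} escapes the workspace root"
            )
        return candidate

    def _deliver_file(self, template: Template, ctx: RenderContext) -> str:
        target = self._resolve_in_workspace(render(template.path, ctx))
        mode = template.file_mode
        if mode == FileMode.delete:
            if target.exists():
                target.unlink()
                return f"deleted {target.name}"
            return f"delete: {target.name} did not exist (ignored)"
        text = render(template.content or "", ctx)
        target.parent.mkdir(parents=True, exist_ok=True)
        if mode == FileMode.create:
            target.write_text(text, encoding="utf-8")
            return f"created {target.name}"
        with open(target, "a", encoding="utf-8") as fh:
            fh.write(text)
        return f"appended to {target.name}"

    def _deliver_url(self, template: Template, ctx: RenderContext) -> str:
        if template.method == HttpMethod.GET:
            # variables render into the address itself; substituted values
            # are percent-escaped so they cannot mangle the URL structure
            ctx.value_filter = lambda v: urllib.parse.quote(v, safe="")
            address = render(template.address, ctx)
            req = urllib.request.Request(address, method="GET",
                                         headers={"User-Agent": "feedwire"})
        else:
            address = render(template.address, ctx)
            body = render(template.body or "", ctx)
            req = urllib.request.Request(
                address, method="POST", data=body.encode("utf-8"),
                headers={
                    "User-Agent": "feedwire",
                    "Content-Type": CONTENT_TYPES[template.payload_format],
                },
            )
        try:
            status, _ = self.http_send(req)
        except urllib.error.HTTPError as exc:
            raise DeliveryError(f"url delivery got HTTP {exc.code}") from exc
        except (urllib.error.URLError, OSError) as exc:
            raise DeliveryError(f"url delivery failed: {exc}") from exc
        if status >= 400:
            raise DeliveryError(f"url delivery got HTTP {status}")
        return f"{template.method.value} {address} -> {status}"
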