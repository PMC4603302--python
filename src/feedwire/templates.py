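"""Delivery templates and the placeholder rendering engine.

Template text mixes three constructs with literal text:

* ``%{name}`` — substituted with the event payload value for ``name``;
  every variable used in a template must have a corresponding selector in
  the agent, and a variable may appear any number of times.
* ``${fn}`` — a built-in function; ``${datetime}`` renders the delivery
  timestamp as ISO-8601 UTC.
* ``${code(...)}`` — an embedded script evaluated at delivery time with the
  payload variables bound as named string values; its returned value is
  stringified into the output.  Scripts run in a sandboxed expression
  evaluator (AST-whitelisted, bounded wall-clock time) and support
  arithmetic, conditionals, string manipulation and mapping tables.

Rendering is a single-pass left-to-right scan; constructs do not nest.
"""

from __future__ import annotations

import ast
import textwrap
import threading
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from typing import Any, Callable, Optional

from pydantic import BaseModel, model_validator

from .errors import RenderError

CODE_TIMEOUT = 5.0  # seconds of wall-clock per embedded script


class TemplateType(str, Enum):
    sql = "sql"
    email = "email"
    file = "file"
    url = "url"


#: The delivery registry: one executor per template type.
DELIVERY_TYPES = ("sql", "email", "file", "url")


class FileMode(str, Enum):
    create = "create"
    append = "append"
    delete = "delete"


class HttpMethod(str, Enum):
    GET = "GET"
    POST = "POST"


class PayloadFormat(str, Enum):
    text = "text"
    json = "json"
    xml = "xml"


class Template(BaseModel):
    """A typed delivery action whose text fields may contain placeholders."""

    id: str
    name: str = ""
    type: TemplateType
    # sql
    connection: Optional[str] = None
    statement: Optional[str] = None
    # email
    to: Optional[str] = None
    cc: Optional[str] = None
    bcc: Optional[str] = None
    subject: Optional[str] = None
    message: Optional[str] = None
    # file
    path: Optional[str] = None
    file_mode: FileMode = FileMode.append
    content: Optional[str] = None
    # url
    address: Optional[str] = None
    method: HttpMethod = HttpMethod.POST
    payload_format: PayloadFormat = PayloadFormat.text
    body: Optional[str] = None
    # escape single quotes in values substituted into sql statements
    escape_sql: bool = False

    @model_validator(mode="after")
    def _required_fields(self) -> "Template":
        required = {
            TemplateType.sql: ("connection", "statement"),
            TemplateType.email: ("to", "subject", "message"),
            TemplateType.file: ("path",),
            TemplateType.url: ("address",),
        }[self.type]
        for name in required:
            if getattr(self, name) is None:
                raise ValueError(f"template {self.id}: {self.type.value} needs {name!r}")
        return self


def builtin_datetime(ctx: "RenderContext") -> str:
    return ctx.now.strftime("%Y-%m-%dT%H:%M:%SZ")


DEFAULT_FUNCTIONS: dict[str, Callable[["RenderContext"], str]] = {
    "datetime": builtin_datetime,
}


@dataclass
class RenderContext:
    """Everything a template needs at delivery time."""

    variables: dict[str, str]
    now: datetime = field(default_factory=lambda: datetime.now(timezone.utc))
    functions: dict[str, Callable[["RenderContext"], str]] = field(
        default_factory=lambda: dict(DEFAULT_FUNCTIONS)
    )
    # applied to each substituted %{var} value (e.g. sql quoting, URL escaping)
    value_filter: Optional[Callable[[str], str]] = None


_ALLOWED_NODES = (
    ast.Module, ast.Expr, ast.Assign, ast.AugAssign, ast.If, ast.For,
    ast.While, ast.Break, ast.Continue, ast.Pass,
    ast.BoolOp, ast.BinOp, ast.UnaryOp, ast.IfExp, ast.Compare, ast.Call,
    ast.Constant, ast.Name, ast.Load, ast.Store, ast.Subscript, ast.Index,
    ast.Slice, ast.Tuple, ast.List, ast.Dict, ast.Set, ast.ListComp,
    ast.DictComp, ast.SetComp, ast.GeneratorExp, ast.comprehension,
    ast.JoinedStr, ast.FormattedValue, ast.Starred, ast.keyword,
    ast.And, ast.Or, ast.Not, ast.Invert, ast.UAdd, ast.USub,
    ast.Add, ast.Sub, ast.Mult, ast.Div, ast.FloorDiv, ast.Mod, ast.Pow,
    ast.Eq, ast.NotEq, ast.Lt, ast.LtE, ast.Gt, ast.GtE, ast.In, ast.NotIn,
    ast.Is, ast.IsNot, ast.Attribute,
)

_SAFE_BUILTINS = {
    "abs": abs, "bool": bool, "dict": dict, "enumerate": enumerate,
    "float": float, "int": int, "len": len, "list": list, "max": max,
    "min": min, "range": range, "round": round, "set": set, "sorted": sorted,
    "str": str, "sum": sum, "tuple": tuple, "zip": zip,
}


def _check_script(tree: ast.Module, script: str) -> None:
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise RenderError(
                f"code block uses forbidden construct "
                f"{type(node).__name__} in {script!r}"
            )
        if isinstance(node, ast.Attribute) and node.attr.startswith("_"):
            raise RenderError(f"code block accesses private attribute in {script!r}")
        if isinstance(node, ast.Name) and node.id.startswith("__"):
            raise RenderError(f"code block uses dunder name in {script!r}")


def eval_code(script: str, ctx: RenderContext) -> str:
    """Evaluate an embedded script and return its value as a string.

    The payload variables are bound as named string values (they are never
    textually spliced into the script).  The script's last statement must
    be an expression — its value is the result.  Syntax errors, raised
    exceptions, a missing final value and scripts exceeding the wall-clock
    bound all raise :class:`RenderError` with diagnostics.
    """
    script = textwrap.dedent(script).strip()
    if not script:
        raise RenderError("empty code block")
    try:
        tree = ast.parse(script, mode="exec")
    except SyntaxError as exc:
        raise RenderError(f"code block syntax error: {exc}") from exc
    if not tree.body:
        raise RenderError("empty code block")
    _check_script(tree, script)
    if not isinstance(tree.body[-1], ast.Expr):
        raise RenderError(
            f"code block must finish with a value-returning expression: {script!r}"
        )

    namespace: dict[str, Any] = dict(ctx.variables)
    result: list[Any] = []
    error: list[BaseException] = []

    def run() -> None:
        try:
            body = ast.Module(body=tree.body[:-1], type_ignores=[])
            exec(compile(body, "<code>", "exec"),
                 {"__builtins__": _SAFE_BUILTINS}, namespace)
            final = ast.Expression(body=tree.body[-1].value)
            result.append(eval(compile(final, "<code>", "eval"),
                               {"__builtins__": _SAFE_BUILTINS}, namespace))
        except BaseException as exc:  # reported to the caller as RenderError
            error.append(exc)

    worker = threading.Thread(target=run, daemon=True)
    worker.start()
    worker.join(CODE_TIMEOUT)
    if worker.is_alive():
        raise RenderError(f"code block exceeded {CODE_TIMEOUT:.0f}s: {script!r}")
    if error:
        raise RenderError(f"code block failed: {error[0]!r} in {script!r}")
    value = result[0]
    if value is None:
        raise RenderError(f"code block returned no value: {script!r}")
    return str(value)


def _find_code_end(text: str, start: int) -> int:
    """Index just past the ``)}`` closing a ``${code(`` opened at *start*
    (which points at the character after ``${code(``)."""
    depth = 1
    i = start
    while i < len(text):
        c = text[i]
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth == 0:
                if i + 1 < len(text) and text[i + 1] == "}":
                    return i + 2
                raise RenderError("malformed ${code(...)} block: expected '}' after ')'")
        i += 1
    raise RenderError("unterminated ${code(...)} block")


def render(text: str, ctx: RenderContext) -> str:
    """Substitute all placeholders in *text*; literal text is kept verbatim.

    Unknown variables and functions raise :class:`RenderError` naming the
    offender.  The context is not modified.
    """
    out: list[str] = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c == "%" and text.startswith("%{", i):
            end = text.find("}", i + 2)
            if end == -1:
                raise RenderError("unterminated %{...} placeholder")
            name = text[i + 2:end]
            if name not in ctx.variables:
                raise RenderError(f"unknown template variable {name!r}")
            value = ctx.variables[name]
            if ctx.value_filter is not None:
                value = ctx.value_filter(value)
            out.append(value)
            i = end + 1
        elif c == "$" and text.startswith("${", i):
            if text.startswith("${code(", i):
                end = _find_code_end(text, i + len("${code("))
                script = text[i + len("${code("):end - 2]
                out.append(eval_code(script, ctx))
                i = end
            else:
                end = text.find("}", i + 2)
                if end == -1:
                    raise RenderError("unterminated ${...} function call")
                name = text[i + 2:end]
                fn = ctx.functions.get(name)
                if fn is None:
                    raise RenderError(f"unknown template function {name!r}")
                out.append(fn(ctx))
                i = end + 1
        else:
            out.append(c)
            i += 1
    return "".join(out)


def quote_sql(value: str) -> str:
    """Double single quotes so substituted values cannot break SQL strings."""
    return value.replace("'", "''")
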