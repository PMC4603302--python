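"""Agents, seeds and format-specific record extraction.

An *agent* watches one origin resource — a delimited text file, an XML
document (e.g. an Atom variant feed), a JSON document, or a SQL query over a
database — and turns its current content into an ordered list of flat
string records via *selectors*.  A *seed* is a secondary extraction whose
harvested values are substituted into an agent definition, fanning one
abstract agent out into many concrete ones (one per gene in a gene list,
for instance).

The extraction contract is deliberately lossy-but-total: a selector that
matches nothing yields the empty string and a warning, never an error, so a
single malformed row cannot wedge a scheduled pipeline.
"""

from __future__ import annotations

import csv
import io
import json
import re
import sqlite3
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Optional

from lxml import etree
from pydantic import BaseModel, field_validator, model_validator

from .errors import ConfigError, ExtractError, PollError
from .logging import LogStore, log_step

_SELECTOR_KEY_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_SEED_PLACEHOLDER_RE = re.compile(r"%\{seed\.([A-Za-z_][A-Za-z0-9_]*)\}")

HTTP_TIMEOUT = 15.0  # seconds per source fetch, no retries


class SourceFormat(str, Enum):
    """The four origin formats the detector registry understands."""

    csv = "csv"
    tsv = "tsv"
    xml = "xml"
    json = "json"
    sql = "sql"


#: Distinct detector algorithms; csv and tsv share the delimited-text one.
DETECTOR_FORMATS = ("csv/tsv", "sql", "xml", "json")


class Selector(BaseModel):
    """Maps a variable name to a format-specific extraction expression.

    The expression is a 1-based column number for csv/tsv, an XPath string
    for xml, a dotted key path for json, and a result-column name for sql.
    """

    key: str
    value: str

    @field_validator("key")
    @classmethod
    def _key_is_identifier(cls, v: str) -> str:
        if not _SELECTOR_KEY_RE.match(v):
            raise ValueError(f"selector key {v!r} is not a valid identifier")
        return v


class SeedConfig(BaseModel):
    """A secondary extraction feeding placeholder values into agents.

    Harvest machinery is identical to an agent's: format, endpoint, an
    optional record-splitting expression and selectors.  The ``placeholder``
    is the name referenced as ``%{seed.<placeholder>}`` inside the parent
    agent's endpoint, query, items or selector values; it is substituted
    with the value of the seed's first selector for each harvested record.
    """

    id: str
    placeholder: str
    format: SourceFormat
    endpoint: str
    query: Optional[str] = None
    items: Optional[str] = None
    selectors: list[Selector]
    has_header: bool = True
    delimiter: Optional[str] = None

    @field_validator("placeholder")
    @classmethod
    def _placeholder_is_identifier(cls, v: str) -> str:
        if not _SELECTOR_KEY_RE.match(v):
            raise ValueError(f"seed placeholder {v!r} is not a valid identifier")
        return v


class AgentConfig(BaseModel):
    """One monitored resource plus its selectors, schedule and cache policy."""

    id: str
    name: str = ""
    format: SourceFormat
    endpoint: str
    query: Optional[str] = None
    items: Optional[str] = None
    selectors: list[Selector]
    cache_key: Optional[str] = None
    schedule: str = "every_5_minutes"
    seed_refs: list[str] = []
    enabled: bool = True
    has_header: bool = True
    delimiter: Optional[str] = None
    # XPath prefix -> namespace URI bindings (xml format; Atom feeds etc.)
    namespaces: dict[str, str] = {}
    # Doubles single quotes in values substituted into sql templates when
    # routed; plain textual substitution is the default.
    escape_sql: bool = False

    @model_validator(mode="after")
    def _check_invariants(self) -> "AgentConfig":
        keys = [s.key for s in self.selectors]
        if len(set(keys)) != len(keys):
            raise ValueError(f"agent {self.id}: duplicate selector keys")
        if self.cache_key is not None and self.cache_key not in keys:
            raise ValueError(
                f"agent {self.id}: cache_key {self.cache_key!r} is not a declared selector"
            )
        if (self.query is not None) != (self.format == SourceFormat.sql):
            raise ValueError(f"agent {self.id}: query is required iff format is sql")
        if (self.items is not None) != (
            self.format in (SourceFormat.xml, SourceFormat.json)
        ):
            raise ValueError(
                f"agent {self.id}: items is required iff format is xml or json"
            )
        return self

    @property
    def selector_keys(self) -> list[str]:
        return [s.key for s in self.selectors]


@dataclass
class SqlResult:
    """A polled SQL result set: column names plus rows in cursor order."""

    columns: list[str]
    rows: list[tuple]


@dataclass
class Record:
    """One extracted data element: selector-key -> string value."""

    values: dict[str, str]
    source_agent: str = ""
    ordinal: int = 0


def sqlite_path(connection_string: str) -> str:
    """Resolve a connection string to a sqlite database path.

    Accepted forms: ``sqlite:///relative/or/absolute/path``, ``sqlite://``
    followed by ``:memory:``, or a bare filesystem path.  Anything carrying
    another scheme is a configuration error.
    """
    if connection_string.startswith("sqlite:///"):
        return connection_string[len("sqlite:///"):]
    if connection_string.startswith("sqlite://"):
        rest = connection_string[len("sqlite://"):]
        if rest == ":memory:" or rest == "/:memory:":
            return ":memory:"
        raise ConfigError(f"malformed sqlite connection string: {connection_string!r}")
    if "://" in connection_string:
        raise ConfigError(
            f"unsupported database connection string: {connection_string!r}"
        )
    return connection_string


def poll(agent: AgentConfig, log: LogStore | None = None) -> str | SqlResult:
    """Fetch the current content of the agent's origin resource (read-only).

    Returns text for file/URL endpoints and a :class:`SqlResult` for sql
    agents.  Unreachable endpoints raise :class:`PollError` (retriable);
    malformed connection strings raise :class:`ConfigError`.
    """
    if agent.format == SourceFormat.sql:
        path = sqlite_path(agent.endpoint)
        try:
            con = sqlite3.connect(path)
            try:
                cur = con.execute(agent.query)
                columns = [c[0] for c in cur.description] if cur.description else []
                rows = cur.fetchall()
            finally:
                con.close()
        except sqlite3.Error as exc:
            log_step(log, agent.id, "detector", f"sql poll failed: {exc}", "error")
            raise PollError(f"agent {agent.id}: sql poll failed: {exc}") from exc
        log_step(log, agent.id, "detector", f"polled {len(rows)} sql rows")
        return SqlResult(columns=columns, rows=rows)

    if agent.endpoint.startswith(("http://", "https://")):
        req = urllib.request.Request(agent.endpoint, headers={"User-Agent": "feedwire"})
        try:
            with urllib.request.urlopen(req, timeout=HTTP_TIMEOUT) as resp:
                body = resp.read()
        except urllib.error.HTTPError as exc:
            log_step(log, agent.id, "detector", f"http {exc.code} from {agent.endpoint}", "error")
            raise PollError(f"agent {agent.id}: HTTP {exc.code}") from exc
        except (urllib.error.URLError, OSError) as exc:
            log_step(log, agent.id, "detector", f"unreachable: {agent.endpoint}", "error")
            raise PollError(f"agent {agent.id}: unreachable endpoint") from exc
        log_step(log, agent.id, "detector", f"polled {len(body)} bytes")
        return body.decode("utf-8", errors="replace")

    path = Path(agent.endpoint)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        log_step(log, agent.id, "detector", f"unreadable file: {path}", "error")
        raise PollError(f"agent {agent.id}: cannot read {path}") from exc
    log_step(log, agent.id, "detector", f"polled {len(text)} chars from {path.name}")
    return text


def _norm(value: Any) -> str:
    if value is None:
        return ""
    return str(value).strip()


def _extract_delimited(content: str, agent: AgentConfig,
                       log: LogStore | None) -> list[Record]:
    delim = agent.delimiter or ("\t" if agent.format == SourceFormat.tsv else ",")
    reader = csv.reader(io.StringIO(content), delimiter=delim)
    rows = [r for r in reader if r]
    if agent.has_header and rows:
        rows = rows[1:]
    records = []
    for i, row in enumerate(rows):
        values = {}
        for sel in agent.selectors:
            try:
                col = int(sel.value)
            except ValueError as exc:
                raise ConfigError(
                    f"agent {agent.id}: selector {sel.key!r} needs a column number"
                ) from exc
            if col < 1 or col > len(row):
                log_step(log, agent.id, "detector",
                         f"row {i}: no column {col} for {sel.key!r}", "warning")
                values[sel.key] = ""
            else:
                values[sel.key] = _norm(row[col - 1])
        records.append(Record(values=values, source_agent=agent.id, ordinal=i))
    return records


def _xpath_to_string(result: Any) -> str:
    # XPath can return a node-set, a string, a number or a boolean.
    # Node-sets are string-joined with ';' (multiple matches per item).
    if isinstance(result, list):
        parts = []
        for node in result:
            if isinstance(node, etree._Element):
                parts.append("".join(node.itertext()))
            else:
                parts.append(str(node))
        return ";".join(p.strip() for p in parts)
    return str(result)


def _extract_xml(content: str, agent: AgentConfig,
                 log: LogStore | None) -> list[Record]:
    try:
        root = etree.fromstring(content.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ExtractError(f"agent {agent.id}: unparseable XML: {exc}") from exc
    try:
        items = root.xpath(agent.items, namespaces=agent.namespaces or None)
    except etree.XPathError as exc:
        raise ConfigError(f"agent {agent.id}: invalid items XPath {agent.items!r}") from exc
    if not isinstance(items, list):
        raise ConfigError(f"agent {agent.id}: items XPath must select a node-set")
    records = []
    for i, node in enumerate(items):
        values = {}
        for sel in agent.selectors:
            try:
                res = node.xpath(sel.value, namespaces=agent.namespaces or None)
            except etree.XPathError as exc:
                raise ConfigError(
                    f"agent {agent.id}: invalid XPath {sel.value!r} for {sel.key!r}"
                ) from exc
            text = _norm(_xpath_to_string(res))
            if text == "" and isinstance(res, list) and not res:
                log_step(log, agent.id, "detector",
                         f"item {i}: selector {sel.key!r} matched nothing", "warning")
            values[sel.key] = text
        records.append(Record(values=values, source_agent=agent.id, ordinal=i))
    return records


def _walk_path(obj: Any, dotted: str) -> Any:
    """Follow a dot-separated key path; missing keys return None."""
    cur = obj
    for part in dotted.split("."):
        if isinstance(cur, dict) and part in cur:
            cur = cur[part]
        elif isinstance(cur, list):
            try:
                cur = cur[int(part)]
            except (ValueError, IndexError):
                return None
        else:
            return None
    return cur


def _extract_json(content: str, agent: AgentConfig,
                  log: LogStore | None) -> list[Record]:
    try:
        doc = json.loads(content)
    except json.JSONDecodeError as exc:
        raise ExtractError(f"agent {agent.id}: unparseable JSON: {exc}") from exc
    items = _walk_path(doc, agent.items)
    if not isinstance(items, list):
        raise ConfigError(
            f"agent {agent.id}: items path {agent.items!r} must address an array"
        )
    records = []
    for i, element in enumerate(items):
        values = {}
        for sel in agent.selectors:
            got = _walk_path(element, sel.value)
            if got is None:
                log_step(log, agent.id, "detector",
                         f"element {i}: path {sel.value!r} missing for {sel.key!r}",
                         "warning")
                values[sel.key] = ""
            else:
                values[sel.key] = _norm(got)
        records.append(Record(values=values, source_agent=agent.id, ordinal=i))
    return records


def _extract_sql(content: SqlResult, agent: AgentConfig,
                 log: LogStore | None) -> list[Record]:
    col_index = {name: i for i, name in enumerate(content.columns)}
    records = []
    for i, row in enumerate(content.rows):
        values = {}
        for sel in agent.selectors:
            if sel.value not in col_index:
                log_step(log, agent.id, "detector",
                         f"row {i}: no result column {sel.value!r} for {sel.key!r}",
                         "warning")
                values[sel.key] = ""
            else:
                values[sel.key] = _norm(row[col_index[sel.value]])
        records.append(Record(values=values, source_agent=agent.id, ordinal=i))
    return records


def extract(content: str | SqlResult, agent: AgentConfig,
            log: LogStore | None = None) -> list[Record]:
    """Split polled content into records and apply the agent's selectors.

    One record per CSV data row, XML item node, JSON array element or SQL
    result row, in source order.  A selector that matches nothing in a given
    record yields the empty string (with a warning log entry).
    """
    if agent.format in (SourceFormat.csv, SourceFormat.tsv):
        return _extract_delimited(content, agent, log)
    if agent.format == SourceFormat.xml:
        return _extract_xml(content, agent, log)
    if agent.format == SourceFormat.json:
        return _extract_json(content, agent, log)
    if agent.format == SourceFormat.sql:
        if not isinstance(content, SqlResult):
            raise ExtractError(f"agent {agent.id}: sql extraction needs a result set")
        return _extract_sql(content, agent, log)
    raise ConfigError(f"agent {agent.id}: unsupported format {agent.format}")


def harvest_seed(seed: SeedConfig, log: LogStore | None = None) -> list[str]:
    """Run a seed's own poll+extract and return its placeholder values.

    The value substituted for ``%{seed.<placeholder>}`` is the seed's first
    selector, evaluated per harvested record; empty values are dropped.
    """
    shim = AgentConfig(
        id=f"seed:{seed.id}",
        format=seed.format,
        endpoint=seed.endpoint,
        query=seed.query,
        items=seed.items,
        selectors=seed.selectors,
        has_header=seed.has_header,
        delimiter=seed.delimiter,
    )
    records = extract(poll(shim, log), shim, log)
    key = seed.selectors[0].key
    return [r.values[key] for r in records if r.values.get(key)]


def _substitute(text: str | None, mapping: dict[str, str]) -> str | None:
    if text is None:
        return None

    def repl(m: re.Match) -> str:
        name = m.group(1)
        if name not in mapping:
            raise ConfigError(f"unresolvable seed placeholder %{{seed.{name}}}")
        return mapping[name]

    return _SEED_PLACEHOLDER_RE.sub(repl, text)


def expand_seeds(agent: AgentConfig, seeds: list[SeedConfig],
                 log: LogStore | None = None) -> list[AgentConfig]:
    """Fan an abstract agent out into one concrete agent per seed value.

    An agent without ``%{seed.*}`` placeholders expands to itself.  Concrete
    agents keep the parent's id as their cache scope (``parent_scope``
    attribute) so that the same variant seen through two seed values is
    still deduplicated per parent definition... see the change-detection
    module for how scopes are applied.
    """
    texts = [agent.endpoint, agent.query or "", agent.items or ""] + [
        s.value for s in agent.selectors
    ]
    used = set()
    for t in texts:
        used.update(_SEED_PLACEHOLDER_RE.findall(t))
    if not used:
        return [agent]

    by_placeholder = {s.placeholder: s for s in seeds}
    missing = used - set(by_placeholder)
    if missing:
        raise ConfigError(
            f"agent {agent.id}: undeclared seed placeholder(s) {sorted(missing)}"
        )
    if len(used) > 1:
        # Multiple distinct placeholders would need a cross-product policy;
        # one placeholder per agent covers the gene-list scenario.
        raise ConfigError(f"agent {agent.id}: more than one seed placeholder used")

    (name,) = used
    values = harvest_seed(by_placeholder[name], log)
    concrete = []
    for i, value in enumerate(values):
        mapping = {name: value}
        child = agent.model_copy(
            update={
                "id": f"{agent.id}[{value}]",
                "endpoint": _substitute(agent.endpoint, mapping),
                "query": _substitute(agent.query, mapping),
                "items": _substitute(agent.items, mapping),
                "selectors": [
                    Selector(key=s.key, value=_substitute(s.value, mapping))
                    for s in agent.selectors
                ],
                "seed_refs": [],
            }
        )
        # concrete agents share the parent's cache scope
        object.__setattr__(child, "parent_scope", agent.id)
        concrete.append(child)
    log_step(log, agent.id, "detector", f"seed expanded into {len(concrete)} agents")
    return concrete


def cache_scope(agent: AgentConfig) -> str:
    """The cache scope an agent's fingerprints live in (parent id for
    seed-expanded agents, own id otherwise)."""
    return getattr(agent, "parent_scope", agent.id)
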