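# Methods

## The integration model

feedwire implements reactive, event-driven extract–transform–load. The
unit of work is a *monitoring pass* over one agent:

1. **Poll** — fetch the origin resource's current content (file read, HTTP
   GET, or SQL query). Polling never mutates the source.
2. **Extract** — split the content into ordered records (CSV data rows,
   XML item nodes, JSON array elements, SQL result rows) and apply each
   selector within the record's scope. All values are normalized to
   whitespace-stripped strings.
3. **Detect** — compute each record's fingerprint and atomically
   check-and-insert it in the agent's cache scope. Records whose
   fingerprints were already present are dropped; the rest become events.
4. **Route and deliver** — each event is fanned out to every template of
   every enabled integration containing the agent, one delivery per
   (integration, template) pair, sequentially.

The pass is idempotent by construction: an unchanged resource produces
zero events on every run after the first, and appending k novel records
produces exactly k events. This is the property the whole design serves —
it converts "poll repeatedly" into "deliver exactly once".

### Fingerprints

Two modes, chosen per agent:

* **Identifier mode** (`cache_key`): the value of one designated selector
  is the fingerprint, verbatim. Appropriate when records carry a stable
  unique id (variant accessions, database keys). A record edited in place
  but keeping its id will *not* re-fire.
* **Content mode** (default): the lowercase MD5 hex digest of the
  canonical serialization — `key=value` lines with keys sorted
  lexicographically, joined by `\n`, UTF-8. Any change to any field
  changes the fingerprint. MD5 is used as a fast content identifier, not
  for security; collision resistance at cryptographic strength is not
  required for change detection.

Duplicate fingerprints within one polled batch count once (first
occurrence wins). The cache is append-only and never evicted: it is the
system's memory of everything ever integrated. Check-and-insert is a
single atomic operation (a lock in the in-memory backend; one IMMEDIATE
transaction in the sqlite backend), so concurrent runs of the same agent
cannot double-fire. A later delivery failure deliberately does not roll
the cache back — delivery verification would require destination
acknowledgement metadata, which is out of scope; the log records the
failure instead.

### Cache scoping and seeds

Scopes are per agent definition. A seed-expanded agent (one abstract
definition fanned out over harvested values, e.g. a gene list) shares the
*parent's* scope: the same variant reached through two seed values is
still one event. Seeds are re-harvested on every pass, so growing the gene
list grows the agent set on the next run.

## Assumptions and deviations from the simplest reading

* Column selectors are 1-based (spreadsheet convention). CSV/TSV headers
  are skipped by default (`has_header=True`).
* XML `items`/selector expressions are XPath 1.0, evaluated with optional
  per-agent namespace bindings; a selector matching multiple nodes within
  one item is string-joined with `;`.
* JSON `items` must address an array via a dot-separated key path.
* A pushed event (passive pipeline) *does* populate the detection cache;
  otherwise a later poll of the same source would duplicate deliveries.
* One seed placeholder per agent. Multiple placeholders would need a
  cross-product policy with no obvious right answer; the gene-list
  scenario needs exactly one.

## Template engine

Single-pass, left-to-right, non-nesting scan over the template text:
`%{var}` substitutes payload values, `${fn}` calls a registered built-in
(`datetime` → ISO-8601 UTC delivery time), `${code(...)}` evaluates an
embedded script. Rendering is pure: the context and template are never
mutated, and any unknown variable or function aborts the delivery with an
error naming it.

Embedded scripts run in a sandboxed Python expression evaluator rather
than a full host interpreter: the AST is whitelisted (expressions, simple
statements, comprehensions; no imports, no dunder access), builtins are
restricted to a safe arithmetic/string/collection set, payload variables
are bound as string *values* — never textually spliced into the script —
and execution is bounded at 5 s wall-clock. The script's last statement
must be an expression; its value, stringified, is the substitution. This
covers the intended use cases (mapping tables, conditionals, arithmetic,
string manipulation) while keeping template execution safe to expose to
configuration authors.

Plain textual substitution into SQL statements is injection-prone by
nature; an opt-in `escape_sql` flag doubles single quotes in substituted
values. It is off by default to keep substitution byte-transparent.

## Delivery semantics

One attempt per delivery, one 15 s network timeout, zero retries. A
failing template never affects sibling deliveries of the same event.
Per type:

* **sql** — the rendered text executes as a single statement batch on the
  destination connection (sqlite; other dialects would need their own
  driver behind the same executor interface).
* **file** — paths resolve inside a per-deployment workspace root;
  rendered paths escaping the root fail the delivery (variables flow into
  paths, so traversal must be assumed hostile). `create` overwrites,
  `append` appends, `delete` of a missing file is tolerated (delivered
  with a warning detail).
* **url** — GET renders variables into the address with percent-escaping
  of substituted values; POST sends the rendered body with a Content-Type
  matching the declared payload format (text/json/xml).
* **email** — the transport is pluggable: SMTP in deployments, an
  in-process capture sink in tests.

## Scheduling and the queue

Schedules are named intervals from a settings list, not hard-coded; the
stock list is every_5_minutes, every_15_minutes, hourly, daily, weekly.
Five minutes is the floor below which polling cost outweighs freshness
for typical sources; arbitrary intervals can be configured. Due agents
are enqueued (at most one pending job per agent) on a single homogeneous
FIFO queue with no priorities. The worker pool admits at most
`worker_limit` concurrent jobs; starts are serialized through a gate so
arrival order is exactly start order. Job failures are recorded in the
trace and the log and never block the queue. All timing in tests runs on
injected clocks; queue tests use real threads with ~tens-of-milliseconds
service times, long enough to observe true concurrency, short enough to
keep the suite in seconds.

## Service API and tokens

Access tokens are 32-character strings over `[a-z0-9]` from a
cryptographically strong source (`secrets`), revocable, and scoped to
their owner: a token can only reach its owner's agents (403 otherwise).
The API is a plain WSGI app — callable in-process for tests, servable by
any WSGI server; transport security is a deployment concern. Remote
agents hash locally and exchange only fingerprints and novel payloads
with the server, which keeps the server-side scope identical to local
monitoring of the same agent id — the basis of the local/remote
equivalence guarantee.

## Synthetic resources: what they emulate and what they do not

The fixtures module fabricates the study conditions: an Atom-style
variant feed (2 genes × 3 variants by default, matching the flagship
two-gene scenario exercised end to end over three mutation cycles), a
one-column gene list for seeding, and one logically identical 4-row
variant table in CSV, JSON, XML and sqlite for format-parity checks.
Variant descriptions are HGVS-*like* random strings; entry timestamps are
fixed so generation is byte-deterministic under a seed. The feed emulates
structure (entries, ids, per-gene association, monotone growth), not real
LOVD payload schemas, authentication, pagination, or server-side failure
modes; passing tests therefore demonstrate the detection/delivery logic,
not robustness against every real-world feed dialect. Mutation only adds
entries — record *edits* are covered by unit tests of content-mode
fingerprints, not by the feed scenario.

Problem sizes throughout (4-row tables, 6-entry feeds, 1000-token
uniqueness samples, 4-job queue traces) are chosen so every property is
decidable exactly and the full suite runs in seconds; the properties
checked (idempotence, exactly-once, parity, FIFO/bounded concurrency) are
size-independent.

## Known limitations

* SQL connectivity is sqlite-only; MySQL/PostgreSQL would slot behind the
  same connection-string interface but are not implemented.
* No delivery verification or retry protocol: at-most-once delivery per
  event per template, with the log as the audit trail.
* No streaming parsers: sources are read whole, so very large documents
  are better split at the source or queried incrementally (SQL agents).
* Compressed or encrypted source payloads are not handled.
* Cache entries are kept forever; a long-lived deployment watching a
  high-churn source will grow its cache without bound.
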