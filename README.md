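# feedwire

Event-driven data integration for dynamic life-sciences resources.

Keeping a warehouse synchronized with sources that change on their own
schedule — a locus-specific variant database publishing new mutations, an
institutional CSV export, a collaborator's REST service — usually means
either re-running a batch ETL pipeline from scratch or writing one-off glue
code per source. feedwire replaces both with a small reactive framework:

* **Agents** watch origin resources in CSV/TSV, XML, JSON or SQL form and
  extract flat records through *selectors* (column numbers, XPath
  expressions, dotted key paths, result-column names).
* **Change detection** is atomic and content-based: every record gets a
  *fingerprint* — a user-designated identifier field, or otherwise the MD5
  digest of its canonical `key=value` serialization — checked-and-inserted
  atomically in a per-agent cache. A record becomes an **event** exactly
  once, no matter how often the source is polled.
* **Templates** render event payloads into typed deliveries — SQL
  statements, emails, files, HTTP GET/POST — using `%{variable}`
  substitution, built-in functions such as `${datetime}`, and sandboxed
  `${code(...)}` blocks for mappings and conditionals.
* **Integrations** bind many agents to many templates; a scheduler and a
  FIFO queue with bounded concurrency drive recurring runs (default
  schedule floor: every 5 minutes).
* Remote deployments run agents next to private resources and talk to the
  server over a token-authenticated JSON API (`/api/agents/<id>/check`,
  `/api/agents/<id>/events`); sources can also *push* events directly,
  skipping detection entirely.

It is aimed at bioinformatics groups who maintain aggregated databases
(the flagship scenario is harvesting variant feeds per gene from LOVD-style
locus-specific databases), but nothing in the core is domain-specific.

## Worked example

Monitor a synthetic two-gene variant feed and warehouse every new variant
into a SQL table:

```python
import sqlite3, pathlib
import feedwire as fw
from feedwire.fixtures import FeedSpec, make_variant_feed, mutate_feed

work = pathlib.Path("demo"); work.mkdir(exist_ok=True)
feed = make_variant_feed(
    FeedSpec(genes=("BRCA2", "TP53"), variants_per_gene=3, seed=1),
    work / "feed.xml")

dest = work / "warehouse.db"
con = sqlite3.connect(dest)
con.execute("CREATE TABLE v (id TEXT, gene TEXT, variant TEXT)")
con.commit(); con.close()

ns = {"a": "http://www.w3.org/2005/Atom", "v": "urn:feedwire:variant"}
agent = fw.AgentConfig(
    id="lovd", format="xml", endpoint=str(feed),
    items="//a:entry", namespaces=ns, cache_key="id",
    selectors=[fw.Selector(key="id", value="./v:variant_id/text()"),
               fw.Selector(key="gene", value="./v:gene/text()"),
               fw.Selector(key="variant", value="./v:hgvs/text()")])

template = fw.Template(
    id="sql-variant", type="sql", connection=f"sqlite:///{dest}",
    statement="INSERT INTO v VALUES ('%{id}','%{gene}','%{variant}')")

hub = fw.Hub(workspace=work)
hub.register_agent(agent)
hub.register_template(template)
hub.register_integration(fw.Integration(
    id="variome", agent_ids={"lovd"}, template_ids={"sql-variant"}))

print(f"first run:  {len(hub.run_agent('lovd'))} deliveries")
print(f"second run: {len(hub.run_agent('lovd'))} deliveries")
mutate_feed(feed, 2)
print(f"after 2 new variants: {len(hub.run_agent('lovd'))} deliveries")
```

Output:

```
first run:  6 deliveries
second run: 0 deliveries
after 2 new variants: 2 deliveries
```

The first run delivers all six variants (2 genes × 3). The second run
delivers nothing — every fingerprint is already cached. After two new
variants are published to the feed, exactly those two are detected and
delivered; the warehouse ends with 8 distinct rows.

The same pipelines are available from the shell:

```bash
feedwire fixtures make --out demo --seed 1     # synthetic resources
feedwire agent run --config client.json        # run configured agents once
feedwire integration run variome --config server.json
feedwire serve --config server.json            # token-authenticated API
```

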