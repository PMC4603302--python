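"""Agent configuration, polling, extraction and seed expansion."""

from __future__ import annotations

import json
import threading
from http.server import BaseHTTPRequestHandler, HTTPServer

import pytest
import pydantic

import feedwire as fw
from feedwire.agents import SqlResult, harvest_seed
from feedwire.fixtures import make_gene_list
from feedwire.logging import LogStore

from conftest import make_agent


class TestConfigInvariants:
    def test_duplicate_selector_keys_rejected(self):
        with pytest.raises(pydantic.ValidationError):
            fw.AgentConfig(id="a", format="csv", endpoint="x.csv",
                           selectors=[fw.Selector(key="g", value="1"),
                                      fw.Selector(key="g", value="2")])

    def test_cache_key_must_be_declared(self):
        with pytest.raises(pydantic.ValidationError):
            fw.AgentConfig(id="a", format="csv", endpoint="x.csv",
                           selectors=[fw.Selector(key="g", value="1")],
                           cache_key="nope")

    @pytest.mark.parametrize("key", ["1bad", "with space", "", "a-b"])
    def test_selector_key_must_be_identifier(self, key):
        with pytest.raises(pydantic.ValidationError):
            fw.Selector(key=key, value="1")

    def test_query_iff_sql(self):
        with pytest.raises(pydantic.ValidationError):
            fw.AgentConfig(id="a", format="csv", endpoint="x.csv", query="SELECT 1",
                           selectors=[fw.Selector(key="g", value="1")])
        with pytest.raises(pydantic.ValidationError):
            fw.AgentConfig(id="a", format="sql", endpoint="x.db",
                           selectors=[fw.Selector(key="g", value="g")])

    def test_items_iff_structured_format(self):
        with pytest.raises(pydantic.ValidationError):
            fw.AgentConfig(id="a", format="json", endpoint="x.json",
                           selectors=[fw.Selector(key="g", value="g")])

    def test_roundtrips_through_json(self, tabular):
        agent = make_agent("xml", str(tabular["xml"]))
        again = fw.AgentConfig.model_validate_json(agent.model_dump_json())
        assert again == agent


class TestPoll:
    def test_file_read_identity(self, tmp_path):
        src = tmp_path / "v.csv"
        src.write_text("gene,variant\nBRCA2,c.1A>G\nTP53,c.2C>T\n")
        agent = fw.AgentConfig(id="a", format="csv", endpoint=str(src),
                               selectors=[fw.Selector(key="gene", value="1")])
        assert fw.poll(agent) == src.read_text()

    def test_sql_query_identity(self, tabular):
        agent = make_agent("sql", str(tabular["sql"]),
                           query="SELECT gene, variant FROM variants LIMIT 2")
        result = fw.poll(agent)
        assert isinstance(result, SqlResult)
        assert len(result.rows) == 2
        assert result.columns == ["gene", "variant"]

    def test_missing_file_is_retriable_poll_error(self, tmp_path):
        agent = fw.AgentConfig(id="a", format="csv",
                               endpoint=str(tmp_path / "gone.csv"),
                               selectors=[fw.Selector(key="g", value="1")])
        with pytest.raises(fw.PollError):
            fw.poll(agent)

    def test_http_500_raises_poll_error_and_logs(self):
        class Handler(BaseHTTPRequestHandler):
            def do_GET(self):
                self.send_error(500)

            def log_message(self, *a):
                pass

        server = HTTPServer(("127.0.0.1", 0), Handler)
        thread = threading.Thread(target=server.serve_forever, daemon=True)
        thread.start()
        try:
            agent = fw.AgentConfig(
                id="a", format="csv",
                endpoint=f"http://127.0.0.1:{server.server_port}/x.csv",
                selectors=[fw.Selector(key="g", value="1")])
            log = LogStore()
            with pytest.raises(fw.PollError):
                fw.poll(agent, log)
            assert log.by_status("error")
        finally:
            server.shutdown()
            server.server_close()

    def test_foreign_scheme_is_config_error(self):
        agent = fw.AgentConfig(id="a", format="sql",
                               endpoint="postgres://host/db", query="SELECT 1",
                               selectors=[fw.Selector(key="g", value="g")])
        with pytest.raises(fw.ConfigError):
            fw.poll(agent)


class TestExtract:
    def test_csv_rows_to_records(self):
        agent = fw.AgentConfig(id="a", format="csv", endpoint="mem",
                               selectors=[fw.Selector(key="gene", value="1"),
                                          fw.Selector(key="variant", value="2")])
        records = fw.extract("gene,variant\nBRCA2,c.100A>T\nTP53,c.215C>G", agent)
        assert len(records) == 2
        assert records[0].values == {"gene": "BRCA2", "variant": "c.100A>T"}
        assert [r.ordinal for r in records] == [0, 1]

    def test_tsv_uses_tab_delimiter(self):
        agent = fw.AgentConfig(id="a", format="tsv", endpoint="mem",
                               has_header=False,
                               selectors=[fw.Selector(key="gene", value="1")])
        records = fw.extract("BRCA2\tc.1A>G\nTP53\tc.2C>T", agent)
        assert [r.values["gene"] for r in records] == ["BRCA2", "TP53"]

    def test_xml_items_split_into_records(self, feed_path):
        agent = fw.AgentConfig(
            id="a", format="xml", endpoint=str(feed_path),
            items="//*[local-name()='entry']",
            selectors=[fw.Selector(key="title",
                                   value="./*[local-name()='title']/text()")])
        records = fw.extract(feed_path.read_text(), agent)
        assert len(records) == 6  # 2 genes x 3 variants

    def test_json_record_count_matches_independent_parse(self, tabular):
        content = tabular["json"].read_text()
        agent = make_agent("json", str(tabular["json"]))
        records = fw.extract(content, agent)
        # independent parse of the same document
        assert len(records) == len(json.loads(content)["variants"])

    def test_missing_selector_yields_empty_string_and_warning(self):
        agent = fw.AgentConfig(id="a", format="csv", endpoint="mem",
                               selectors=[fw.Selector(key="gene", value="1"),
                                          fw.Selector(key="extra", value="9")])
        log = LogStore()
        records = fw.extract("gene\nBRCA2", agent, log)
        assert records[0].values["extra"] == ""
        assert log.by_status("warning")

    def test_values_are_whitespace_stripped(self):
        agent = fw.AgentConfig(id="a", format="csv", endpoint="mem",
                               has_header=False,
                               selectors=[fw.Selector(key="g", value="1")])
        records = fw.extract("  BRCA2  ", agent)
        assert records[0].values["g"] == "BRCA2"

    def test_unparseable_content_raises_extract_error(self, tabular):
        xml_agent = make_agent("xml", "mem")
        with pytest.raises(fw.ExtractError):
            fw.extract("not <xml", xml_agent)
        json_agent = make_agent("json", "mem")
        with pytest.raises(fw.ExtractError):
            fw.extract("{broken", json_agent)

    def test_invalid_xpath_raises_config_error(self):
        agent = fw.AgentConfig(id="a", format="xml", endpoint="mem",
                               items="///[",
                               selectors=[fw.Selector(key="g", value=".")])
        with pytest.raises(fw.ConfigError):
            fw.extract("<r><v>1</v></r>", agent)

    def test_multiple_xpath_matches_join_with_semicolon(self):
        agent = fw.AgentConfig(
            id="a", format="xml", endpoint="mem", items="//rec",
            selectors=[fw.Selector(key="alias", value="./alias/text()")])
        content = "<r><rec><alias>p53</alias><alias>LFS1</alias></rec></r>"
        records = fw.extract(content, agent)
        assert records[0].values["alias"] == "p53;LFS1"

    def test_format_parity_across_fixtures(self, tabular):
        """A logically identical dataset yields payload-identical records
        whether presented as CSV, JSON, XML or SQL."""
        payloads = {}
        for fmt in ("csv", "json", "xml", "sql"):
            agent = make_agent(fmt, str(tabular[fmt]))
            records = fw.extract(fw.poll(agent), agent)
            payloads[fmt] = [r.values for r in records]
        assert payloads["csv"] == payloads["json"] == payloads["xml"] \
            == payloads["sql"]


class TestSeeds:
    def gene_seed(self, tmp_path, genes=("BRCA2", "TP53")):
        path = make_gene_list(tmp_path / "genes.csv", genes)
        return fw.SeedConfig(id="s1", placeholder="gene", format="csv",
                             endpoint=str(path),
                             selectors=[fw.Selector(key="gene", value="1")])

    def test_harvest_reads_placeholder_values(self, tmp_path):
        seed = self.gene_seed(tmp_path)
        assert harvest_seed(seed) == ["BRCA2", "TP53"]

    def test_expansion_substitutes_endpoint(self, tmp_path):
        seed = self.gene_seed(tmp_path)
        agent = fw.AgentConfig(
            id="lovd", format="xml",
            endpoint="https://lsdb.example/api/rest/variants/%{seed.gene}",
            items="//entry",
            selectors=[fw.Selector(key="id", value="./id/text()")])
        concrete = fw.expand_seeds(agent, [seed])
        assert [a.endpoint for a in concrete] == [
            "https://lsdb.example/api/rest/variants/BRCA2",
            "https://lsdb.example/api/rest/variants/TP53",
        ]

    def test_agent_without_placeholders_is_identity(self, tabular):
        agent = make_agent("csv", str(tabular["csv"]))
        assert fw.expand_seeds(agent, []) == [agent]

    def test_placeholder_used_twice_substitutes_both(self, tmp_path):
        seed = self.gene_seed(tmp_path, genes=("BRCA2", "TP53", "MLH1"))
        agent = fw.AgentConfig(
            id="g", format="json",
            endpoint="https://x/%{seed.gene}", items="genes.%{seed.gene}",
            selectors=[fw.Selector(key="id", value="id")])
        concrete = fw.expand_seeds(agent, [seed])
        assert len(concrete) == 3
        for child, gene in zip(concrete, ("BRCA2", "TP53", "MLH1")):
            assert child.endpoint == f"https://x/{gene}"
            assert child.items == f"genes.{gene}"

    def test_unresolvable_placeholder_is_config_error(self):
        agent = fw.AgentConfig(
            id="g", format="csv", endpoint="https://x/%{seed.nope}",
            selectors=[fw.Selector(key="id", value="1")])
        with pytest.raises(fw.ConfigError):
            fw.expand_seeds(agent, [])

    def test_empty_harvest_yields_empty_list(self, tmp_path):
        seed = self.gene_seed(tmp_path, genes=())
        agent = fw.AgentConfig(
            id="g", format="csv", endpoint="https://x/%{seed.gene}",
            selectors=[fw.Selector(key="id", value="1")])
        assert fw.expand_seeds(agent, [seed]) == []

    def test_concrete_agents_share_parent_cache_scope(self, tmp_path):
        from feedwire.agents import cache_scope

        seed = self.gene_seed(tmp_path)
        agent = fw.AgentConfig(
            id="g", format="csv", endpoint="https://x/%{seed.gene}",
            selectors=[fw.Selector(key="id", value="1")])
        for child in fw.expand_seeds(agent, [seed]):
            assert cache_scope(child) == "g"


class TestMonitor:
    def test_first_run_emits_all_then_none(self, tabular):
        agent = make_agent("csv", str(tabular["csv"]))
        cache = fw.MemoryCache()
        first = fw.monitor(agent, cache)
        second = fw.monitor(agent, cache)
        assert (len(first), len(second)) == (4, 0)

    def test_appended_records_fire_exactly_k_events(self, tabular):
        agent = make_agent("csv", str(tabular["csv"]))
        cache = fw.MemoryCache()
        fw.monitor(agent, cache)
        with open(tabular["csv"], "a") as fh:
            fh.write("VAR900001,GENEX,c.1A>G\nVAR900002,GENEY,c.2C>T\n")
        events = fw.monitor(agent, cache)
        assert len(events) == 2
        assert [e.payload["id"] for e in events] == ["VAR900001", "VAR900002"]

    def test_event_order_preserves_source_order(self, tabular):
        agent = make_agent("json", str(tabular["json"]))
        events = fw.monitor(agent, fw.MemoryCache())
        ids = [e.payload["id"] for e in events]
        assert ids == sorted(ids)  # fixture writes ids in ascending order

    def test_failed_poll_leaves_cache_empty(self, tmp_path):
        agent = fw.AgentConfig(id="a", format="csv",
                               endpoint=str(tmp_path / "gone.csv"),
                               selectors=[fw.Selector(key="g", value="1")])
        cache = fw.MemoryCache()
        with pytest.raises(fw.PollError):
            fw.monitor(agent, cache)
        assert cache.size("a") == 0
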