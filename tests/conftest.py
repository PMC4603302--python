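"""Shared fixtures: synthetic resources, a wired hub, capture transports."""

from __future__ import annotations

import sqlite3
from pathlib import Path

import pytest

import feedwire as fw
from feedwire.fixtures import FeedSpec, make_tabular_resources, make_variant_feed

VARIANT_SELECTORS = {
    "csv": [("id", "1"), ("gene", "2"), ("variant", "3")],
    "json": [("id", "id"), ("gene", "gene"), ("variant", "variant")],
    "xml": [("id", "./id/text()"), ("gene", "./gene/text()"),
            ("variant", "./variant/text()")],
    "sql": [("id", "id"), ("gene", "gene"), ("variant", "variant")],
}


def make_agent(fmt: str, endpoint: str, agent_id: str = "a1",
               **kwargs) -> fw.AgentConfig:
    """A variant-table agent for any of the four fixture formats."""
    defaults = {
        "csv": {},
        "json": {"items": "variants"},
        "xml": {"items": "//record"},
        "sql": {"query": "SELECT id, gene, variant FROM variants"},
    }[fmt]
    defaults.update(kwargs)
    return fw.AgentConfig(
        id=agent_id,
        format=fmt,
        endpoint=endpoint,
        selectors=[fw.Selector(key=k, value=v) for k, v in VARIANT_SELECTORS[fmt]],
        **defaults,
    )


@pytest.fixture
def tabular(tmp_path: Path) -> dict[str, Path]:
    """CSV/JSON/XML/sqlite variant tables with identical logical content."""
    return make_tabular_resources(tmp_path / "tabular", seed=0)


@pytest.fixture
def feed_path(tmp_path: Path) -> Path:
    """A 2-gene x 3-variant synthetic Atom feed."""
    return make_variant_feed(FeedSpec(genes=("BRCA2", "TP53"),
                                      variants_per_gene=3, seed=7),
                             tmp_path / "feed.xml")


@pytest.fixture
def dest_db(tmp_path: Path) -> Path:
    """An empty destination database with a ``v(id, gene, variant)`` table."""
    path = tmp_path / "dest.db"
    con = sqlite3.connect(path)
    con.execute("CREATE TABLE v (id TEXT, gene TEXT, variant TEXT)")
    con.commit()
    con.close()
    return path


def count_rows(db: Path, table: str = "v") -> int:
    con = sqlite3.connect(db)
    try:
        (n,) = con.execute(f"SELECT COUNT(*) FROM {table}").fetchone()
        return n
    finally:
        con.close()


def fetch_rows(db: Path, table: str = "v") -> list[tuple]:
    con = sqlite3.connect(db)
    try:
        return con.execute(f"SELECT * FROM {table} ORDER BY id").fetchall()
    finally:
        con.close()


def sql_insert_template(db: Path, template_id: str = "t-sql") -> fw.Template:
    return fw.Template(
        id=template_id,
        type="sql",
        connection=f"sqlite:///{db}",
        statement="INSERT INTO v VALUES ('%{id}','%{gene}','%{variant}')",
    )


@pytest.fixture
def hub(tmp_path: Path) -> fw.Hub:
    return fw.Hub(workspace=tmp_path)
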