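"""Synthetic origin resources for end-to-end testing.

Real deployments watch live resources — locus-specific variant databases
exposing Atom feeds, institutional CSV exports, relational stores.  This
module fabricates small stand-ins for all of them so every pipeline is
exercisable offline: an LOVD-style Atom feed of gene variants (with a
``mutate_feed`` helper that publishes fresh variants, the raw material for
change-detection tests), and a logically identical variant table in CSV,
JSON, XML and an embedded sqlite database for format-parity tests.

Variant descriptions are syntactically HGVS-like random strings; no
biological validity is claimed.  Generation is deterministic under a seed,
byte-for-byte.
"""

from __future__ import annotations

import csv
import json
import random
import sqlite3
from dataclasses import dataclass
from pathlib import Path

from lxml import etree

from .errors import ExtractError

ATOM_NS = "http://www.w3.org/2005/Atom"
VAR_NS = "urn:feedwire:variant"
_BASES = "ACGT"
_EPOCH = "2015-10-13T00:00:00Z"  # fixed stamp: feeds must be byte-stable


@dataclass(frozen=True)
class FeedSpec:
    """Shape of a synthetic variant feed."""

    genes: tuple[str, ...] = ("BRCA2", "TP53")
    variants_per_gene: int = 3
    seed: int = 0


def _hgvs_like(rng: random.Random) -> str:
    pos = rng.randrange(1, 5000)
    ref, alt = rng.sample(_BASES, 2)
    return f"c.{pos}{ref}>{alt}"


def _entry(parent: etree._Element, vid: str, gene: str, hgvs: str) -> None:
    entry = etree.SubElement(parent, f"{{{ATOM_NS}}}entry")
    etree.SubElement(entry, f"{{{ATOM_NS}}}id").text = vid
    etree.SubElement(entry, f"{{{ATOM_NS}}}title").text = f"{gene}:{hgvs}"
    etree.SubElement(entry, f"{{{ATOM_NS}}}updated").text = _EPOCH
    etree.SubElement(entry, f"{{{VAR_NS}}}gene").text = gene
    etree.SubElement(entry, f"{{{VAR_NS}}}variant_id").text = vid
    etree.SubElement(entry, f"{{{VAR_NS}}}hgvs").text = hgvs


def _write_feed(root: etree._Element, path: str | Path) -> None:
    Path(path).write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                       pretty_print=True)
    )


def make_variant_feed(spec: FeedSpec, path: str | Path) -> Path:
    """Write an Atom-like feed with one entry per variant.

    Entries carry a unique variant id, the gene symbol and an HGVS-like
    description; the same spec always produces identical bytes.
    """
    rng = random.Random(spec.seed)
    root = etree.Element(f"{{{ATOM_NS}}}feed",
                         nsmap={None: ATOM_NS, "v": VAR_NS})
    etree.SubElement(root, f"{{{ATOM_NS}}}title").text = "synthetic variant feed"
    etree.SubElement(root, f"{{{ATOM_NS}}}updated").text = _EPOCH
    n = 0
    for gene in spec.genes:
        for _ in range(spec.variants_per_gene):
            n += 1
            _entry(root, f"VAR{n:06d}", gene, _hgvs_like(rng))
    _write_feed(root, path)
    return Path(path)


def feed_entry_count(path: str | Path) -> int:
    root = etree.parse(str(path)).getroot()
    return len(root.findall(f"{{{ATOM_NS}}}entry"))


def mutate_feed(path: str | Path, k: int, seed: int = 0) -> Path:
    """Append *k* novel variant entries with fresh unique ids.

    Emulates curators publishing new variants between monitoring runs.
    """
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise ExtractError(f"malformed feed {path}: {exc}") from exc
    root = tree.getroot()
    entries = root.findall(f"{{{ATOM_NS}}}entry")
    genes = sorted({
        e.findtext(f"{{{VAR_NS}}}gene", default="GENE") for e in entries
    }) or ["GENE"]
    start = len(entries)
    rng = random.Random(seed * 100003 + start)
    for i in range(k):
        vid = f"VAR{start + i + 1:06d}"
        _entry(root, vid, genes[(start + i) % len(genes)], _hgvs_like(rng))
    _write_feed(root, path)
    return Path(path)


#: rows shared by the tabular fixtures (deterministic under seed)
def _variant_rows(seed: int, n: int = 4) -> list[dict[str, str]]:
    rng = random.Random(seed)
    genes = ["BRCA2", "TP53", "MLH1", "CFTR", "FBN1"]
    rows = []
    for i in range(n):
        rows.append({
            "id": f"VAR{i + 1:06d}",
            "gene": genes[i % len(genes)],
            "variant": _hgvs_like(rng),
        })
    return rows


def make_tabular_resources(directory: str | Path, seed: int = 0,
                           n: int = 4) -> dict[str, Path]:
    """Write one logically identical variant table in four formats.

    Returns ``{"csv": ..., "json": ..., "xml": ..., "sql": ...}`` paths;
    the sql path is an embedded sqlite database with a ``variants`` table.
    CSV and JSON regeneration under the same seed is byte-stable.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = _variant_rows(seed, n)

    csv_path = directory / "variants.csv"
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id", "gene", "variant"])
        for row in rows:
            writer.writerow([row["id"], row["gene"], row["variant"]])

    json_path = directory / "variants.json"
    json_path.write_text(
        json.dumps({"variants": rows}, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )

    xml_path = directory / "variants.xml"
    root = etree.Element("variants")
    for row in rows:
        node = etree.SubElement(root, "record")
        for key in ("id", "gene", "variant"):
            etree.SubElement(node, key).text = row[key]
    _write_feed(root, xml_path)

    sql_path = directory / "variants.db"
    if sql_path.exists():
        sql_path.unlink()
    con = sqlite3.connect(sql_path)
    try:
        con.execute("CREATE TABLE variants (id TEXT, gene TEXT, variant TEXT)")
        con.executemany(
            "INSERT INTO variants VALUES (?,?,?)",
            [(r["id"], r["gene"], r["variant"]) for r in rows],
        )
        con.commit()
    finally:
        con.close()

    return {"csv": csv_path, "json": json_path, "xml": xml_path,
            "sql": sql_path}


def make_gene_list(path: str | Path, genes: tuple[str, ...] = ("BRCA2", "TP53")) -> Path:
    """A one-column CSV gene list, the classic seed source."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["gene"])
        for gene in genes:
            writer.writerow([gene])
    return path
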