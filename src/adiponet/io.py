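"""Readers and writers: assertion CSV, GEXF / GraphML export, report files.

The assertion CSV dialect has the exact header
``source,source_category,target,target_category,sign,provenance``
(UTF-8, comma-separated, quoted fields allowed; categories and signs as
lowercase snake-case tokens).  GEXF 1.3 is written directly (node
attributes category/degree/betweenness, edge attribute sign, node size
proportional to degree, as a Gephi-ready export); GraphML export goes
through networkx as the alternate format.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd
from lxml import etree

from .classification import ClassificationResult
from .construction import AssertionRecord
from .robustness import StabilityReport
from .schema import EdgeSign, NodeCategory, TypedNetwork

__all__ = [
    "ASSERTION_HEADER",
    "AssertionParseError",
    "read_assertions",
    "write_assertions",
    "to_networkx",
    "write_gexf",
    "write_graphml",
    "write_centrality_tsv",
    "write_classification_json",
    "write_stability_tsv",
]

ASSERTION_HEADER = [
    "source",
    "source_category",
    "target",
    "target_category",
    "sign",
    "provenance",
]

GEXF_NS = "http://gexf.net/1.3"
VIZ_NS = "http://gexf.net/1.3/viz"


class AssertionParseError(ValueError):
    """Malformed assertion CSV; carries the 1-based line number and field."""

    def __init__(self, line: int, field: str, message: str):
        self.line = line
        self.field = field
        super().__init__(f"line {line}, field {field!r}: {message}")


def read_assertions(path: str | Path) -> list[AssertionRecord]:
    """Parse an assertion CSV, validating categories and signs row by row."""
    records: list[AssertionRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise AssertionParseError(1, "header", "empty file") from None
        if [h.strip() for h in header] != ASSERTION_HEADER:
            raise AssertionParseError(
                1, "header", f"expected {','.join(ASSERTION_HEADER)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(ASSERTION_HEADER):
                raise AssertionParseError(
                    lineno, "row", f"expected {len(ASSERTION_HEADER)} fields, got {len(row)}"
                )
            vals = {k: v.strip() for k, v in zip(ASSERTION_HEADER, row)}
            for field in ("source", "target"):
                if not vals[field]:
                    raise AssertionParseError(lineno, field, "empty entity name")
            cats = {}
            for field in ("source_category", "target_category"):
                try:
                    cats[field] = NodeCategory(vals[field])
                except ValueError:
                    raise AssertionParseError(
                        lineno,
                        field,
                        f"unknown category {vals[field]!r}; expected one of "
                        + ", ".join(c.value for c in NodeCategory),
                    ) from None
            try:
                sign = EdgeSign(vals["sign"])
            except ValueError:
                raise AssertionParseError(
                    lineno,
                    "sign",
                    f"unknown sign {vals['sign']!r}; expected one of "
                    + ", ".join(s.value for s in EdgeSign),
                ) from None
            try:
                records.append(
                    AssertionRecord(
                        source=vals["source"],
                        source_category=cats["source_category"],
                        target=vals["target"],
                        target_category=cats["target_category"],
                        sign=sign,
                        provenance=vals["provenance"],
                    )
                )
            except ValueError as exc:
                raise AssertionParseError(lineno, "target", str(exc)) from None
    return records


def write_assertions(records: Iterable[AssertionRecord], path: str | Path) -> None:
    """Write records in the assertion CSV dialect (inverse of read_assertions)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ASSERTION_HEADER)
        for rec in records:
            writer.writerow(
                [
                    rec.source,
                    NodeCategory(rec.source_category).value,
                    rec.target,
                    NodeCategory(rec.target_category).value,
                    EdgeSign(rec.sign).value,
                    rec.provenance,
                ]
            )


def to_networkx(network: TypedNetwork, table: pd.DataFrame | None = None) -> nx.DiGraph:
    """Convert to a networkx DiGraph with category/sign (and centrality) attrs."""
    g = nx.DiGraph()
    for name in sorted(network.nodes):
        attrs = {"category": network.nodes[name].value}
        if table is not None:
            attrs["degree"] = int(table.at[name, "degree"])
            attrs["betweenness"] = float(table.at[name, "betweenness"])
        g.add_node(name, **attrs)
    for (u, v), sign in sorted(network.edges.items()):
        g.add_edge(u, v, sign=EdgeSign(sign).value)
    return g


def write_gexf(
    network: TypedNetwork, path: str | Path, table: pd.DataFrame | None = None
) -> None:
    """Write a GEXF 1.3 file with a node-size visual attribute equal to degree.

    Node attributes: category, degree, betweenness; edge attribute: sign;
    ``viz:size`` carries the degree so nodes render proportionally to
    their connectivity in Gephi.
    """
    if table is not None and set(table.index) != set(network.nodes):
        raise ValueError("centrality table and network cover different node sets")
    nsmap = {None: GEXF_NS, "viz": VIZ_NS}
    root = etree.Element(f"{{{GEXF_NS}}}gexf", nsmap=nsmap, version="1.3")
    graph = etree.SubElement(root, f"{{{GEXF_NS}}}graph", defaultedgetype="directed")

    node_attrs = etree.SubElement(graph, f"{{{GEXF_NS}}}attributes", attrib={"class": "node"})
    for aid, (title, atype) in enumerate(
        [("category", "string"), ("degree", "integer"), ("betweenness", "double")]
    ):
        etree.SubElement(
            node_attrs, f"{{{GEXF_NS}}}attribute", id=str(aid), title=title, type=atype
        )
    edge_attrs = etree.SubElement(graph, f"{{{GEXF_NS}}}attributes", attrib={"class": "edge"})
    etree.SubElement(
        edge_attrs, f"{{{GEXF_NS}}}attribute", id="sign", title="sign", type="string"
    )

    weights = network.node_weights
    nodes_el = etree.SubElement(graph, f"{{{GEXF_NS}}}nodes")
    for name in sorted(network.nodes):
        node_el = etree.SubElement(nodes_el, f"{{{GEXF_NS}}}node", id=name, label=name)
        values = etree.SubElement(node_el, f"{{{GEXF_NS}}}attvalues")
        etree.SubElement(
            values, f"{{{GEXF_NS}}}attvalue", attrib={"for": "0", "value": network.nodes[name].value}
        )
        degree = int(table.at[name, "degree"]) if table is not None else weights[name]
        etree.SubElement(
            values, f"{{{GEXF_NS}}}attvalue", attrib={"for": "1", "value": str(degree)}
        )
        if table is not None:
            etree.SubElement(
                values,
                f"{{{GEXF_NS}}}attvalue",
                attrib={"for": "2", "value": f"{float(table.at[name, 'betweenness']):.9g}"},
            )
        etree.SubElement(node_el, f"{{{VIZ_NS}}}size", value=str(max(degree, 1)))

    edges_el = etree.SubElement(graph, f"{{{GEXF_NS}}}edges")
    for eid, ((u, v), sign) in enumerate(sorted(network.edges.items())):
        edge_el = etree.SubElement(
            edges_el, f"{{{GEXF_NS}}}edge", id=str(eid), source=u, target=v
        )
        values = etree.SubElement(edge_el, f"{{{GEXF_NS}}}attvalues")
        etree.SubElement(
            values, f"{{{GEXF_NS}}}attvalue", attrib={"for": "sign", "value": EdgeSign(sign).value}
        )
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def write_graphml(
    network: TypedNetwork, path: str | Path, table: pd.DataFrame | None = None
) -> None:
    """Alternate export: GraphML via networkx."""
    nx.write_graphml(to_networkx(network, table), str(path))


def write_centrality_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="node", float_format="%.9g")


def write_classification_json(result: ClassificationResult, path: str | Path) -> None:
    payload = {
        "hubs": sorted(result.hubs),
        "bottlenecks": sorted(result.bottlenecks),
        "nonhub_bottlenecks": sorted(result.nonhub_bottlenecks),
        "thresholds": {
            k: {"value": float(v), "rule": rule} for k, (v, rule) in result.thresholds.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_stability_tsv(report: StabilityReport, path: str | Path) -> None:
    """Long-format TSV (node, class, frequency) plus a JSON parameter block."""
    long = report.frequencies.reset_index(names="node").melt(
        id_vars="node", var_name="class", value_name="frequency"
    )
    long.to_csv(path, sep="\t", index=False, float_format="%.9g")
    Path(str(path) + ".params.json").write_text(
        json.dumps(report.parameters, indent=2) + "\n", encoding="utf-8"
    )
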