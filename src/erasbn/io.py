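"""Dataset/schema I/O and graph export.

Datasets travel as UTF-8 CSV (comma) or TSV (tab, auto-detected from the
``.tsv`` extension) with a header row.  Empty cells and the literal ``NA``
map to missing.  Schemas are JSON documents listing each categorical
variable's name, ordered grade labels and role, plus the names of the
numeric outcome columns.  Graphs export as DOT, tab-separated edge lists, or
JSON.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import BayesianNetwork, DagStructure, DiscreteDataset, VariableSpec

__all__ = [
    "read_schema",
    "write_schema",
    "read_dataset",
    "write_dataset",
    "graph_to_dot",
    "graph_to_edge_list",
    "graph_to_json",
    "parse_dot",
    "write_graph",
    "network_to_json",
    "network_from_json",
]

_MISSING_TOKENS = {"", "NA"}


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


def read_schema(path: str | Path) -> tuple[list[VariableSpec], list[str]]:
    """Load a JSON schema: (categorical variable specs, numeric outcome names)."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    specs = [
        VariableSpec(v["name"], tuple(v["states"]), v.get("role", "indicator"))
        for v in doc["variables"]
    ]
    return specs, list(doc.get("outcomes", []))


def write_schema(
    path: str | Path, variables: Sequence[VariableSpec], outcomes: Sequence[str] = ()
) -> None:
    doc = {
        "variables": [
            {"name": v.name, "states": list(v.states), "role": v.role}
            for v in variables
        ],
        "outcomes": list(outcomes),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_dataset(
    path: str | Path, schema: Sequence[VariableSpec]
) -> tuple[DiscreteDataset, pd.DataFrame]:
    """Parse a CSV/TSV into a validated dataset plus any non-schema columns.

    Schema columns are validated against their grade sets (an
    out-of-vocabulary cell raises, naming the row and column); remaining
    columns (typically numeric outcomes) are returned as a separate frame.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str,
                        keep_default_na=False)
    names = [v.name for v in schema]
    missing = set(names) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing schema columns {sorted(missing)}")
    cat = frame[names].map(lambda x: None if x in _MISSING_TOKENS else x)
    data = DiscreteDataset(list(schema), cat)
    rest = frame[[c for c in frame.columns if c not in names]].apply(
        pd.to_numeric, errors="coerce"
    )
    return data, rest


def write_dataset(
    path: str | Path,
    data: DiscreteDataset,
    extra: pd.DataFrame | None = None,
) -> None:
    """Write a dataset (plus optional numeric columns) as CSV/TSV."""
    path = Path(path)
    frame = data.frame.copy()
    if extra is not None:
        frame = pd.concat([frame, extra.reset_index(drop=True)], axis=1)
    frame = frame.where(pd.notna(frame), other="")
    frame.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------

def _dot_id(name: str) -> str:
    if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", name):
        return name
    return '"' + name.replace('"', '\\"') + '"'


def graph_to_dot(dag: DagStructure, name: str = "G") -> str:
    lines = [f"digraph {name} {{"]
    for n in dag.nodes:
        lines.append(f"  {_dot_id(n)};")
    for u in dag.nodes:
        for v in dag.children(u):
            lines.append(f"  {_dot_id(u)} -> {_dot_id(v)};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def graph_to_edge_list(dag: DagStructure) -> str:
    lines = []
    for u in dag.nodes:
        for v in dag.children(u):
            lines.append(f"{u}\t{v}")
    return "\n".join(lines) + ("\n" if lines else "")


def graph_to_json(dag: DagStructure) -> str:
    doc = {
        "nodes": list(dag.nodes),
        "edges": sorted(dag.edges, key=lambda e: (dag.nodes.index(e[0]),
                                                  dag.nodes.index(e[1]))),
    }
    return json.dumps(doc, indent=2) + "\n"


_DOT_EDGE = re.compile(r'\s*("(?:[^"\\]|\\.)*"|[\w]+)\s*->\s*("(?:[^"\\]|\\.)*"|[\w]+)\s*;')
_DOT_NODE = re.compile(r'\s*("(?:[^"\\]|\\.)*"|[\w]+)\s*;')


def _unquote(tok: str) -> str:
    if tok.startswith('"'):
        return tok[1:-1].replace('\\"', '"')
    return tok


def parse_dot(text: str) -> DagStructure:
    """Parse the DOT dialect produced by :func:`graph_to_dot`."""
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("digraph", "}")):
            continue
        m = _DOT_EDGE.fullmatch(line)
        if m:
            u, v = _unquote(m.group(1)), _unquote(m.group(2))
            for n in (u, v):
                if n not in nodes:
                    nodes.append(n)
            edges.append((u, v))
            continue
        m = _DOT_NODE.fullmatch(line)
        if m:
            n = _unquote(m.group(1))
            if n not in nodes:
                nodes.append(n)
    return DagStructure(nodes, edges)


def write_graph(dag: DagStructure, path: str | Path, format: str = "dot") -> None:
    """Serialize a DAG to ``dot``, ``edge_list`` or ``json``."""
    renderers = {
        "dot": graph_to_dot,
        "edge_list": graph_to_edge_list,
        "json": graph_to_json,
    }
    if format not in renderers:
        raise ValueError(f"unsupported graph format {format!r}")
    Path(path).write_text(renderers[format](dag), encoding="utf-8")


# ---------------------------------------------------------------------------
# Network (structure + CPTs) serialization
# ---------------------------------------------------------------------------

def network_to_json(bn: BayesianNetwork) -> str:
    doc = {
        "nodes": [
            {
                "name": n,
                "states": list(bn.states(n)),
                "parents": list(bn.cpts[n].parents),
                "cpt": {
                    "|".join(cfg): [float(p) for p in vec]
                    for cfg, vec in sorted(bn.cpts[n].table.items())
                },
            }
            for n in bn.dag.nodes
        ],
        "edges": sorted(bn.dag.edges),
    }
    return json.dumps(doc, indent=2) + "\n"


def network_from_json(text: str) -> BayesianNetwork:
    from .core import Cpt

    doc = json.loads(text)
    names = [n["name"] for n in doc["nodes"]]
    dag = DagStructure(names, [tuple(e) for e in doc["edges"]])
    states = {n["name"]: tuple(n["states"]) for n in doc["nodes"]}
    cpts = {}
    for n in doc["nodes"]:
        parents = tuple(n["parents"])
        table = {}
        for key, vec in n["cpt"].items():
            cfg = tuple(key.split("|")) if key else ()
            table[cfg] = vec
        cpts[n["name"]] = Cpt(
            n["name"], states[n["name"]], parents,
            tuple(states[p] for p in parents), table,
        )
    return BayesianNetwork(dag, cpts)
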