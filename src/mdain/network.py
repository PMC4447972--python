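"""Coarse-grained subsegment networks of significant interaction changes.

Significant residue-pair differences between an investigated condition and a
reference are gathered onto pairs of subsegments (e.g. TM6m-TM10m).  An edge
connects two subsegments if any member residue pair differs significantly;
its sign is ``increased`` when every member pair is more frequent in the
investigated condition, ``decreased`` when every member is less frequent,
and ``mixed`` otherwise.  Intersecting the networks of two different
perturbations exposes the shared allosteric pathway.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .interactions import DifferentialEdge
from .model import SubsegmentScheme

_REGION_Y = {"e": 2.0, "m": 1.0, "i": 0.0, "loop": 3.0, "terminus": -1.0}


@dataclass
class GraphEdge:
    u: str
    v: str
    sign: str  # increased | decreased | mixed
    member_pairs: list[DifferentialEdge] = field(default_factory=list)
    sources: list[str] = field(default_factory=list)
    self_edge: bool = False


@dataclass
class SubsegmentGraph:
    """Signed 2-D network over subsegments; vertices carry region and layout."""

    scheme: SubsegmentScheme
    investigated: str
    reference: str
    edges: dict[tuple[str, str], GraphEdge] = field(default_factory=dict)

    @property
    def vertices(self) -> list[str]:
        return [e.name for e in self.scheme.entries]

    def layout(self) -> dict[str, tuple[float, float]]:
        """Presentational positions: three horizontal bands (e / m / i), loops
        above, terminus below; x follows sequence order."""
        pos = {}
        for x, entry in enumerate(self.scheme.entries):
            y = _REGION_Y[entry.region]
            if entry.region == "loop" and entry.name.startswith("IL"):
                y = -1.0
            pos[entry.name] = (float(x), y)
        return pos

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        layout = self.layout()
        for entry in self.scheme.entries:
            g.add_node(entry.name, region=entry.region,
                       x=layout[entry.name][0], y=layout[entry.name][1])
        for (u, v), e in self.edges.items():
            g.add_edge(u, v, sign=e.sign, n_members=len(e.member_pairs),
                       self_edge=e.self_edge)
        return g


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def coarse_grain(
    edges: list[DifferentialEdge],
    scheme: SubsegmentScheme,
    investigated: str,
    reference: str,
) -> SubsegmentGraph:
    """Map differential residue pairs onto subsegment pairs with a sign.

    ``freq_a`` of each input edge is read as the investigated condition and
    ``freq_b`` as the reference.  Pairs falling inside one subsegment form a
    flagged self-edge.  Residues not covered by the scheme raise KeyError.
    """
    graph = SubsegmentGraph(scheme=scheme, investigated=investigated, reference=reference)
    for de in edges:
        sa = scheme.lookup(de.pair[0])
        sb = scheme.lookup(de.pair[1])
        key = _edge_key(sa, sb)
        ge = graph.edges.get(key)
        if ge is None:
            ge = GraphEdge(u=key[0], v=key[1], sign="", self_edge=(sa == sb))
            graph.edges[key] = ge
        ge.member_pairs.append(de)
        ge.sources.append(investigated)
    for ge in graph.edges.values():
        deltas = [m.delta for m in ge.member_pairs]
        if all(d > 0 for d in deltas):
            ge.sign = "increased"
        elif all(d < 0 for d in deltas):
            ge.sign = "decreased"
        else:
            ge.sign = "mixed"
    return graph


def graph_intersection(g1: SubsegmentGraph, g2: SubsegmentGraph) -> SubsegmentGraph:
    """Edges present in both networks regardless of sign (shared pathway).

    Member pairs are concatenated and tagged by their source condition.
    """
    if [e.name for e in g1.scheme.entries] != [e.name for e in g2.scheme.entries]:
        raise ValueError("schemes differ between graphs")
    out = SubsegmentGraph(
        scheme=g1.scheme,
        investigated=f"{g1.investigated}&{g2.investigated}",
        reference=g1.reference,
    )
    for key in sorted(g1.edge_set() & g2.edge_set()):
        e1, e2 = g1.edges[key], g2.edges[key]
        sign = e1.sign if e1.sign == e2.sign else "mixed"
        out.edges[key] = GraphEdge(
            u=key[0], v=key[1], sign=sign,
            member_pairs=e1.member_pairs + e2.member_pairs,
            sources=(e1.sources or [g1.investigated] * len(e1.member_pairs))
            + (e2.sources or [g2.investigated] * len(e2.member_pairs)),
            self_edge=e1.self_edge,
        )
    return out


def _graph_to_dict(graph: SubsegmentGraph) -> dict:
    return {
        "investigated": graph.investigated,
        "reference": graph.reference,
        "scheme": [
            {"name": e.name, "first": e.first_residue, "last": e.last_residue,
             "region": e.region}
            for e in graph.scheme.entries
        ],
        "edges": [
            {
                "u": e.u, "v": e.v, "sign": e.sign, "self_edge": e.self_edge,
                "sources": e.sources,
                "member_pairs": [
                    {"res_a": m.pair[0], "res_b": m.pair[1],
                     "freq_a": m.freq_a, "freq_b": m.freq_b,
                     "p": m.p_value, "q": m.q_value}
                    for m in e.member_pairs
                ],
            }
            for _, e in sorted(graph.edges.items())
        ],
    }


def export_graph(graph: SubsegmentGraph, path: str | Path, format: str = "json") -> None:
    """Write the network as JSON (lossless), GraphML, or DOT."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_graph_to_dict(graph), indent=1))
    elif format == "graphml":
        nx.write_graphml(graph.to_networkx(), str(path))
    elif format == "dot":
        with open(path, "w") as fh:
            fh.write(f'graph "{graph.investigated} vs {graph.reference}" {{\n')
            for name, (x, y) in graph.layout().items():
                region = graph.scheme.region_of(name)
                fh.write(f'  "{name}" [region="{region}", pos="{x},{y}!"];\n')
            color = {"increased": "orange", "decreased": "green", "mixed": "black"}
            for (u, v), e in sorted(graph.edges.items()):
                fh.write(f'  "{u}" -- "{v}" [sign="{e.sign}", color="{color[e.sign]}"];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def import_graph(path: str | Path) -> SubsegmentGraph:
    """Re-load a JSON export (inverse of export_graph(..., format='json'))."""
    from .model import SubsegmentEntry, SubsegmentScheme

    doc = json.loads(Path(path).read_text())
    scheme = SubsegmentScheme(entries=tuple(
        SubsegmentEntry(e["name"], e["first"], e["last"], e["region"])
        for e in doc["scheme"]
    ))
    graph = SubsegmentGraph(scheme=scheme, investigated=doc["investigated"],
                            reference=doc["reference"])
    for e in doc["edges"]:
        members = [
            DifferentialEdge(pair=(m["res_a"], m["res_b"]), freq_a=m["freq_a"],
                             freq_b=m["freq_b"], p_value=m["p"], q_value=m["q"])
            for m in e["member_pairs"]
        ]
        graph.edges[(e["u"], e["v"])] = GraphEdge(
            u=e["u"], v=e["v"], sign=e["sign"], member_pairs=members,
            sources=e["sources"], self_edge=e["self_edge"],
        )
    return graph


def pathway_extract(graph: SubsegmentGraph, source: str, target: str) -> list[list[str]]:
    """All shortest subsegment paths (unweighted), lexicographically ordered.

    Returns an empty list when source and target are disconnected.
    """
    g = graph.to_networkx()
    if source not in g or target not in g:
        raise KeyError("source or target not in graph")
    if source == target:
        return [[source]]
    try:
        paths = [list(p) for p in nx.all_shortest_paths(g, source, target)]
    except nx.NetworkXNoPath:
        return []
    return sorted(paths)
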