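"""Network export: GraphML (round-trippable), SIF and flat TSV."""

from __future__ import annotations

import networkx as nx

from ..errors import FormatError


def write_network(network: nx.MultiGraph, path: str, format: str = "GraphML") -> None:
    """Write a coregulation multigraph.

    GraphML preserves parallel edges with their ``go_term`` attribute and
    round-trips through :func:`read_network`. SIF uses the GO term id as
    the interaction type. TSV writes ``reg_a<TAB>reg_b<TAB>go_term``.
    """
    fmt = format.upper()
    if fmt == "GRAPHML":
        nx.write_graphml(network, path)
    elif fmt == "SIF":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for u, v, data in sorted(
                network.edges(data=True), key=lambda e: (e[0], e[1], e[2].get("go_term", ""))
            ):
                fh.write(f"{u}\t{data.get('go_term', 'linked')}\t{v}\n")
            for node in sorted(n for n in network.nodes if network.degree(n) == 0):
                fh.write(f"{node}\n")
    elif fmt == "TSV":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("reg_a\treg_b\tgo_term\n")
            for u, v, data in sorted(
                network.edges(data=True), key=lambda e: (e[0], e[1], e[2].get("go_term", ""))
            ):
                fh.write(f"{u}\t{v}\t{data.get('go_term', '')}\n")
    else:
        raise FormatError(f"unknown network format {format!r}")


def read_network(path: str) -> nx.MultiGraph:
    """Read a GraphML file written by :func:`write_network`."""
    g = nx.read_graphml(path, force_multigraph=True)
    return nx.MultiGraph(g)
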