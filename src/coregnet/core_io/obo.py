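"""Minimal OBO 1.2 parser producing a biological_process DAG.

Only the fields the pipeline needs are read: ``id``, ``name``,
``namespace``, ``is_a``, ``relationship: part_of`` and ``is_obsolete``.
The returned graph is a :class:`networkx.MultiDiGraph` with child->parent
edges keyed by relation (``"is_a"`` or ``"part_of"``) so the two relation
types stay separable downstream.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Tuple

import networkx as nx

from ..errors import IntegrityError

log = logging.getLogger(__name__)

BP_NAMESPACE = "biological_process"
BP_ROOT = "GO:0008150"


def _strip_comment(value: str) -> str:
    # trailing "! human readable name" comments are not part of the value
    return value.split("!", 1)[0].strip()


def parse_obo(path: str, namespace: str = BP_NAMESPACE) -> nx.MultiDiGraph:
    """Parse an OBO 1.2 file into a DAG restricted to one namespace.

    Obsolete terms are dropped (count logged). Raises
    :class:`IntegrityError` if the is_a relation contains a cycle.
    """
    terms: Dict[str, dict] = {}
    current: dict | None = None
    in_term = False
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("["):
                if current is not None and current.get("id"):
                    terms[current["id"]] = current
                in_term = line.strip() == "[Term]"
                current = {"is_a": [], "part_of": []} if in_term else None
                continue
            if not in_term or current is None or not line.strip():
                continue
            if ":" not in line:
                continue
            key, _, value = line.partition(":")
            key = key.strip()
            value = value.strip()
            if key == "id":
                current["id"] = _strip_comment(value)
            elif key == "name":
                current["name"] = value
            elif key == "namespace":
                current["namespace"] = value
            elif key == "is_a":
                current["is_a"].append(_strip_comment(value))
            elif key == "relationship":
                parts = _strip_comment(value).split()
                if len(parts) >= 2 and parts[0] == "part_of":
                    current["part_of"].append(parts[1])
            elif key == "is_obsolete":
                current["obsolete"] = value.lower().startswith("true")
    if current is not None and current.get("id"):
        terms[current["id"]] = current

    n_obsolete = sum(1 for t in terms.values() if t.get("obsolete"))
    if n_obsolete:
        log.warning("dropping %d obsolete terms", n_obsolete)

    keep = {
        tid: t
        for tid, t in terms.items()
        if not t.get("obsolete") and t.get("namespace", namespace) == namespace
    }

    dag = nx.MultiDiGraph()
    for tid, t in keep.items():
        dag.add_node(tid, name=t.get("name", tid))
    for tid, t in keep.items():
        for parent in t["is_a"]:
            if parent in keep:
                dag.add_edge(tid, parent, key="is_a")
        for parent in t["part_of"]:
            if parent in keep:
                dag.add_edge(tid, parent, key="part_of")

    isa = nx.DiGraph(
        (u, v) for u, v, k in dag.edges(keys=True) if k == "is_a"
    )
    if not nx.is_directed_acyclic_graph(isa):
        raise IntegrityError("is_a relation contains a cycle")
    return dag


def find_bp_root(dag: nx.MultiDiGraph) -> str:
    """Locate the namespace root: GO:0008150 if present, else the unique
    term with no outgoing is_a edge."""
    if BP_ROOT in dag:
        return BP_ROOT
    roots = [
        n
        for n in dag.nodes
        if not any(k == "is_a" for _, _, k in dag.out_edges(n, keys=True))
    ]
    if len(roots) != 1:
        raise IntegrityError(
            f"cannot identify a unique biological_process root (candidates: {sorted(roots)})"
        )
    return roots[0]


def ancestors(
    dag: nx.MultiDiGraph, term: str, use_part_of: bool = True
) -> frozenset:
    """Transitive closure of parents of ``term`` (term itself included).

    is_a edges are always traversed; part_of edges only when
    ``use_part_of`` is true.
    """
    seen = {term}
    stack: List[str] = [term]
    while stack:
        node = stack.pop()
        for _, parent, key in dag.out_edges(node, keys=True):
            if key == "part_of" and not use_part_of:
                continue
            if parent not in seen:
                seen.add(parent)
                stack.append(parent)
    return frozenset(seen)
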