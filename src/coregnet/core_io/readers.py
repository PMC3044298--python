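"""Typed readers for the tab-separated inputs and the ontology bundle.

All TSV readers skip blank lines and lines starting with ``#``, and treat
identifiers as opaque case-sensitive strings. Every reader logs the record
counts it loaded so runs are auditable against raw line counts.
"""

from __future__ import annotations

import csv
import logging
from typing import Dict, Iterator, List, Set, Tuple

import networkx as nx
import pandas as pd

from ..errors import FormatError, IntegrityError
from . import obo as obo_mod
from .types import ExpressionDataset, Regulator, RegulatorKind, RegulatorTargetNetwork

log = logging.getLogger(__name__)

_KIND_TOKENS = {
    "TF": RegulatorKind.TF,
    "MIRNA_FAMILY": RegulatorKind.MIRNA_FAMILY,
}


def _tsv_rows(path: str) -> Iterator[Tuple[int, List[str]]]:
    """Yield (1-based line number, fields) for data lines of a TSV file."""
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n").rstrip("\r")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            yield lineno, stripped.split("\t")


def _header_index(fields: List[str], required: Tuple[str, ...], path: str) -> Dict[str, int]:
    idx = {name: i for i, name in enumerate(fields)}
    for col in required:
        if col not in idx:
            raise FormatError(f"{path}: missing required column {col!r}")
    return idx


def read_regulator_targets(path: str, kind_column: str = "regulator_kind") -> RegulatorTargetNetwork:
    """Read a regulator->target edge list.

    Expects header columns ``regulator_id``, ``regulator_kind`` (or the
    name given in *kind_column*) and ``target_gene``. Duplicate edges are
    collapsed silently; the collapse count is logged.
    """
    rows = _tsv_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header line")
    idx = _header_index(header, ("regulator_id", kind_column, "target_gene"), path)

    regulators: Dict[str, Regulator] = {}
    edges: Set[Tuple[str, str]] = set()
    n_rows = 0
    for lineno, fields in rows:
        if len(fields) <= max(idx.values()):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
        rid = fields[idx["regulator_id"]]
        kind_token = fields[idx[kind_column]]
        target = fields[idx["target_gene"]]
        kind = _KIND_TOKENS.get(kind_token.upper())
        if kind is None:
            raise FormatError(
                f"{path}:{lineno}: unknown regulator kind {kind_token!r} "
                f"(expected one of {sorted(_KIND_TOKENS)})"
            )
        prev = regulators.get(rid)
        if prev is not None and prev.kind is not kind:
            raise IntegrityError(f"{path}:{lineno}: regulator {rid!r} has conflicting kinds")
        if prev is None:
            regulators[rid] = Regulator(id=rid, kind=kind, members=frozenset({rid}))
        edges.add((rid, target))
        n_rows += 1

    net = RegulatorTargetNetwork(regulators.values(), edges)
    log.info(
        "read %s: %d regulators, %d edges (%d duplicate rows collapsed), %d target genes",
        path, net.n_regulators, net.n_edges, n_rows - net.n_edges, len(net.universe),
    )
    return net


def read_two_column_map(path: str, key_column: str, value_column: str) -> Dict[str, str]:
    """Read a headered two-column TSV mapping (e.g. mature->family, precursor->host)."""
    rows = _tsv_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header line")
    idx = _header_index(header, (key_column, value_column), path)
    mapping: Dict[str, str] = {}
    for lineno, fields in rows:
        key, value = fields[idx[key_column]], fields[idx[value_column]]
        if key in mapping and mapping[key] != value:
            raise IntegrityError(f"{path}:{lineno}: conflicting mapping for {key!r}")
        mapping[key] = value
    log.info("read %s: %d mappings", path, len(mapping))
    return mapping


def read_edge_list(path: str, source_column: str = "source", dest_column: str = "dest") -> Set[Tuple[str, str]]:
    """Read a headered directed edge list (deduplicated)."""
    rows = _tsv_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header line")
    idx = _header_index(header, (source_column, dest_column), path)
    edges = {(f[idx[source_column]], f[idx[dest_column]]) for _, f in rows}
    log.info("read %s: %d edges", path, len(edges))
    return edges


def _read_annotations_tsv2(path: str, known_terms: Set[str]) -> Tuple[Dict[str, Set[str]], int]:
    mapping: Dict[str, Set[str]] = {}
    skipped = 0
    for lineno, fields in _tsv_rows(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected gene<TAB>term")
        gene, term = fields[0], fields[1]
        if gene == "gene" and term == "term" and lineno == 1:
            continue  # optional header
        if term not in known_terms:
            skipped += 1
            continue
        mapping.setdefault(gene, set()).add(term)
    return mapping, skipped


def _read_annotations_gaf(
    path: str, known_terms: Set[str], exclude_evidence: Tuple[str, ...]
) -> Tuple[Dict[str, Set[str]], int]:
    # GAF 2.x columns: 3=symbol, 4=qualifier, 5=GO id, 7=evidence (1-based)
    mapping: Dict[str, Set[str]] = {}
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise FormatError(f"{path}:{lineno}: too few GAF columns")
            symbol, qualifier, term, evidence = fields[2], fields[3], fields[4], fields[6]
            if "NOT" in qualifier.split("|"):
                skipped += 1
                continue
            if evidence in exclude_evidence:
                skipped += 1
                continue
            if term not in known_terms:
                skipped += 1
                continue
            mapping.setdefault(symbol, set()).add(term)
    return mapping, skipped


def read_ontology(
    obo_path: str,
    annot_path: str,
    annot_format: str = "TSV2",
    exclude_evidence: Tuple[str, ...] = (),
) -> Tuple[nx.MultiDiGraph, Dict[str, Set[str]]]:
    """Load the biological_process DAG and the raw gene->term mapping.

    ``annot_format`` is ``"GAF"`` or ``"TSV2"`` (gene<TAB>term). Rows with a
    NOT qualifier, an excluded evidence code or an unknown/obsolete term
    are skipped (counts logged).
    """
    dag = obo_mod.parse_obo(obo_path)
    known = set(dag.nodes)
    fmt = annot_format.upper()
    if fmt == "TSV2":
        mapping, skipped = _read_annotations_tsv2(annot_path, known)
    elif fmt == "GAF":
        mapping, skipped = _read_annotations_gaf(annot_path, known, exclude_evidence)
    else:
        raise FormatError(f"unknown annotation format {annot_format!r}")
    log.info(
        "read ontology %s (+%s): %d BP terms, %d annotated genes, %d rows skipped",
        obo_path, annot_path, dag.number_of_nodes(), len(mapping), skipped,
    )
    return dag, mapping


def read_expression(
    matrix_path: str,
    meta_path: str,
    entity_kind_path: str | None = None,
    na_token: str = "NA",
) -> ExpressionDataset:
    """Read an entity x sample matrix and its sample metadata.

    Samples present in the matrix but absent from the metadata raise an
    :class:`IntegrityError` naming them; metadata rows without a matrix
    column are dropped.
    """
    values = pd.read_csv(
        matrix_path, sep="\t", index_col=0, comment="#",
        na_values=[na_token], keep_default_na=False,
    )
    for col in values.columns:
        if values[col].dtype == object:
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna() & values[col].notna()]
            if len(bad):
                raise FormatError(
                    f"{matrix_path}: non-numeric value {bad.iloc[0]!r} in column {col!r}"
                )
            values[col] = pd.to_numeric(values[col], errors="coerce")
    values = values.astype(float)

    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "tissue", "condition"):
        if col not in meta.columns:
            raise FormatError(f"{meta_path}: missing required column {col!r}")
    meta = meta.set_index("sample_id")

    kinds = None
    if entity_kind_path is not None:
        kinds = read_two_column_map(entity_kind_path, "entity_id", "kind")

    ds = ExpressionDataset(values, meta, kinds)
    log.info(
        "read expression %s: %d entities x %d samples, %d missing cells",
        matrix_path, ds.n_entities, ds.n_samples, ds.n_missing,
    )
    return ds
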