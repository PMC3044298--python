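"""End-to-end orchestration: bundle loading, staged execution, run manifest.

The CLI subcommands are thin wrappers around this module so that a
stepwise run and a full ``run_pipeline`` produce identical outputs for
identical inputs and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    read_edge_list,
    read_expression,
    read_ontology,
    read_regulator_targets,
    read_two_column_map,
    write_network,
)
from .core_io.types import Condition, RegulatorKind
from .errors import CoregnetError
from .expression_correlation import correlation_distributions
from .linkage_network import (
    build_coregulation_network,
    build_linkages,
    network_stats,
)
from .motif_analysis import (
    DEFAULT_CATALOG,
    build_upstream_network,
    count_motifs,
    motif_significance,
)
from .ontology_profiles import map_to_level2
from .pair_enrichment import (
    CoregulationPair,
    PairKind,
    collapse_families,
    enumerate_pairs,
    find_enriched_pairs,
    propagate_host_regulation,
    results_to_frame,
)
from .synthetic_fixtures import bundle_paths

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    bundle_dir: str
    out_dir: str
    permutations: int = 10000
    resamples: int = 10000
    fdr: float = 0.05
    motif_alpha: float = 0.001
    min_shared: int = 3
    motif_pool_min_shared: int = 1
    expression_pool_min_shared: int = 0
    seed: int = 0
    fdr_method: str = "BH"
    linkage_fdr_method: str = "BL"
    use_part_of: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seed(seed: int, stage: str) -> int:
    """Independent per-stage seed so skipping a stage does not shift
    downstream randomness."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class BundleData:
    """All inputs of one bundle, loaded and cross-linked."""

    def __init__(self, bundle_dir: str, use_part_of: bool = True) -> None:
        paths = bundle_paths(bundle_dir)
        self.paths = paths
        self.tf_net = read_regulator_targets(paths["tf_targets"])
        self.family_map = read_two_column_map(paths["family_map"], "mature_mirna", "family")
        mir_edges = read_edge_list(paths["mirna_targets"], "mature_mirna", "target_gene")
        self.mir_net = collapse_families(sorted(mir_edges), self.family_map)
        self.host_map = read_two_column_map(paths["host_map"], "precursor", "host_gene")
        self.tf_mir_edges = read_edge_list(paths["tf_mir_edges"], "source", "dest")
        dag, raw = read_ontology(paths["obo"], paths["annotations"], "TSV2")
        universe = set(raw) | self.tf_net.universe | self.mir_net.universe
        self.ann = map_to_level2(raw, dag, universe=universe, use_part_of=use_part_of)
        self.dag = dag
        self.expression = None
        if os.path.exists(paths["expression"]):
            self.expression = read_expression(
                paths["expression"], paths["sample_meta"], paths["entity_kinds"]
            )

    @property
    def regulators(self) -> dict:
        return {**self.tf_net.regulators, **self.mir_net.regulators}


def _write_tsv_frame(frame: pd.DataFrame, path: str) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.8g")


def pairs_frame(pairs: Sequence[CoregulationPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "reg_a": [p.reg_a for p in pairs],
            "reg_b": [p.reg_b for p in pairs],
            "pair_kind": [p.pair_kind.value for p in pairs],
            "n_shared": [len(p.shared_targets) for p in pairs],
            "shared_targets": ["|".join(sorted(p.shared_targets)) for p in pairs],
        }
    )


def run_pipeline(config: PipelineConfig, stages: Optional[Sequence[str]] = None) -> Dict[str, object]:
    """Execute pairs -> enrichment -> linkages -> network -> motifs ->
    expression, writing result TSVs and a deterministic manifest.

    Returns a dict of in-memory stage results. Wall-clock timings go to a
    separate ``timings.json`` so the manifest is reproducible
    byte-for-byte across runs with identical inputs and seed.
    """
    all_stages = ("pairs", "enrich", "linkages", "network", "motifs", "expression")
    selected = tuple(stages) if stages else all_stages
    os.makedirs(config.out_dir, exist_ok=True)

    # out_dir is excluded so identical runs into different directories
    # produce byte-identical manifests
    config_snapshot = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    manifest: Dict[str, object] = {
        "tool": "coregnet",
        "version": __version__,
        "config": config_snapshot,
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in ("enrich", "motifs")},
        "inputs": {},
        "counts": {},
        "stages_run": list(selected),
        "failed_stage": None,
    }
    timings: Dict[str, float] = {}
    results: Dict[str, object] = {}

    try:
        t0 = time.perf_counter()
        data = BundleData(config.bundle_dir, use_part_of=config.use_part_of)
        timings["load"] = time.perf_counter() - t0
        manifest["inputs"] = {
            key: _sha256(path)
            for key, path in sorted(data.paths.items())
            if os.path.exists(path) and key not in ("config",)
        }
        results["data"] = data

        pairs: List[CoregulationPair] = []
        if "pairs" in selected:
            t0 = time.perf_counter()
            pairs = enumerate_pairs(data.tf_net, data.mir_net, min_shared=config.min_shared)
            _write_tsv_frame(pairs_frame(pairs), os.path.join(config.out_dir, "pairs.tsv"))
            timings["pairs"] = time.perf_counter() - t0
            manifest["counts"]["pairs"] = len(pairs)
            results["pairs"] = pairs

        enrichment = []
        if "enrich" in selected:
            t0 = time.perf_counter()
            enrichment = find_enriched_pairs(
                pairs,
                data.ann,
                n_perm=config.permutations,
                alpha=config.fdr,
                rng_seed=_stage_seed(config.seed, "enrich"),
                fdr_method=config.fdr_method,
            )
            _write_tsv_frame(
                results_to_frame(enrichment), os.path.join(config.out_dir, "enrichment.tsv")
            )
            timings["enrich"] = time.perf_counter() - t0
            manifest["counts"]["enriched_pairs"] = sum(r.enriched for r in enrichment)
            results["enrichment"] = enrichment

        linkages = []
        if "linkages" in selected:
            t0 = time.perf_counter()
            linkages = build_linkages(
                enrichment, data.ann, alpha=config.fdr, method=config.linkage_fdr_method
            )
            names = {t: data.dag.nodes[t].get("name", t) for t in data.ann.terms}
            frame = pd.DataFrame(
                {
                    "reg_a": [l.pair.reg_a for l in linkages],
                    "reg_b": [l.pair.reg_b for l in linkages],
                    "pair_kind": [l.pair.pair_kind.value for l in linkages],
                    "term": [l.term for l in linkages],
                    "term_name": [names.get(l.term, l.term) for l in linkages],
                    "p_fisher": [l.p_fisher for l in linkages],
                    "q": [l.q for l in linkages],
                    "passed": [l.passed for l in linkages],
                }
            )
            _write_tsv_frame(frame, os.path.join(config.out_dir, "linkages.tsv"))
            timings["linkages"] = time.perf_counter() - t0
            manifest["counts"]["linkages_passed"] = sum(l.passed for l in linkages)
            results["linkages"] = linkages

        if "network" in selected:
            t0 = time.perf_counter()
            stats = {}
            net_all = build_coregulation_network(linkages)
            write_network(net_all, os.path.join(config.out_dir, "network.graphml"), "GraphML")
            write_network(net_all, os.path.join(config.out_dir, "network.sif"), "SIF")
            stats["all"] = network_stats(net_all)
            for kind in PairKind:
                stats[kind.value] = network_stats(
                    build_coregulation_network(linkages, kind_filter=kind)
                )
            with open(os.path.join(config.out_dir, "network_stats.json"), "w",
                      encoding="utf-8", newline="\n") as fh:
                json.dump(stats, fh, indent=2, sort_keys=True, allow_nan=True)
                fh.write("\n")
            timings["network"] = time.perf_counter() - t0
            manifest["counts"]["network_nodes"] = stats["all"]["n_nodes"]
            manifest["counts"]["network_edges"] = stats["all"]["n_edges"]
            results["network"] = net_all
            results["network_stats"] = stats

        if "motifs" in selected:
            t0 = time.perf_counter()
            host_edges = propagate_host_regulation(data.tf_net, data.host_map, data.family_map)
            upstream = build_upstream_network(
                data.tf_net, sorted(data.tf_mir_edges), sorted(host_edges), data.mir_net
            )
            pool = enumerate_pairs(
                data.tf_net, data.mir_net, min_shared=config.motif_pool_min_shared
            )
            enriched = [r.pair for r in enrichment if r.enriched]
            rows = []
            for kind in PairKind:
                fg = [p for p in enriched if p.pair_kind is kind]
                bg = [p for p in pool if p.pair_kind is kind]
                if not fg or len(bg) < len(fg):
                    continue
                for res in motif_significance(
                    fg, bg, upstream,
                    n_resample=config.resamples,
                    rng_seed=_stage_seed(config.seed, "motifs"),
                    alpha_motif=config.motif_alpha,
                    pair_kind=kind,
                ):
                    rows.append(
                        {
                            "motif_id": res.motif_id,
                            "pair_kind": kind.value,
                            "observed": res.observed,
                            "fraction": res.observed_fraction,
                            "null_mean": res.null_mean,
                            "null_sd": res.null_sd,
                            "p_emp": res.p_emp,
                            "significant": res.significant,
                        }
                    )
            frame = pd.DataFrame(
                rows,
                columns=[
                    "motif_id", "pair_kind", "observed", "fraction",
                    "null_mean", "null_sd", "p_emp", "significant",
                ],
            )
            _write_tsv_frame(frame, os.path.join(config.out_dir, "motifs.tsv"))
            timings["motifs"] = time.perf_counter() - t0
            manifest["counts"]["motif_tests"] = len(rows)
            results["motifs"] = rows
            results["upstream"] = upstream

        if "expression" in selected and data.expression is not None:
            t0 = time.perf_counter()
            # background follows the all-possible-pairs reading: every
            # same-kind regulator combination not flagged enriched
            pool = enumerate_pairs(
                data.tf_net, data.mir_net, min_shared=config.expression_pool_min_shared
            )
            enriched = [r.pair for r in enrichment if r.enriched]
            values_rows = []
            summary_rows = []
            summaries = {}
            for condition in (Condition.NORMAL, Condition.TUMOR):
                try:
                    dists = correlation_distributions(
                        enriched, pool, data.regulators, data.expression, condition
                    )
                except CoregnetError as exc:
                    log.warning("expression stage skipped for %s: %s", condition.value, exc)
                    continue
                summaries[condition] = dists
                for kind, summ in sorted(dists.items(), key=lambda kv: kv[0].value):
                    for group, rs in (("foreground", summ.foreground_r), ("background", summ.background_r)):
                        values_rows.extend(
                            {"pair_kind": kind.value, "condition": condition.value,
                             "group": group, "r": r}
                            for r in rs
                        )
                    summary_rows.append(
                        {
                            "pair_kind": kind.value,
                            "condition": condition.value,
                            "n_foreground": len(summ.foreground_r),
                            "n_background": len(summ.background_r),
                            "ks_stat": summ.ks_stat,
                            "ks_p": summ.ks_p,
                            "n_pairs_used": summ.n_pairs_used,
                            "n_pairs_skipped": summ.n_pairs_skipped,
                        }
                    )
            _write_tsv_frame(
                pd.DataFrame(values_rows, columns=["pair_kind", "condition", "group", "r"]),
                os.path.join(config.out_dir, "correlation_values.tsv"),
            )
            _write_tsv_frame(
                pd.DataFrame(
                    summary_rows,
                    columns=["pair_kind", "condition", "n_foreground", "n_background",
                             "ks_stat", "ks_p", "n_pairs_used", "n_pairs_skipped"],
                ),
                os.path.join(config.out_dir, "correlation_summary.tsv"),
            )
            timings["expression"] = time.perf_counter() - t0
            manifest["counts"]["correlation_summaries"] = len(summary_rows)
            results["correlations"] = summaries
    except Exception as exc:
        manifest["failed_stage"] = _current_stage(timings, selected)
        _write_manifest(config.out_dir, manifest, timings)
        raise

    _write_manifest(config.out_dir, manifest, timings)
    return results


def _current_stage(timings: Dict[str, float], selected: Sequence[str]) -> str:
    done = set(timings)
    for stage in ("load",) + tuple(selected):
        if stage not in done:
            return stage
    return "unknown"


def _write_manifest(out_dir: str, manifest: Dict[str, object], timings: Dict[str, float]) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(out_dir, "timings.json"), "w", encoding="utf-8", newline="\n") as fh:
        json.dump({k: round(v, 3) for k, v in timings.items()}, fh, indent=2, sort_keys=True)
        fh.write("\n")
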