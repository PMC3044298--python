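"""Self-contained synthetic input bundles with known ground truth.

The generator writes every file the pipeline reads — a toy ontology,
annotations, regulator-target layers, family/host maps, an upstream edge
list and paired normal/tumour expression — and a truth record naming the
planted coregulation pairs, motifs and correlations. Planted pairs share
targets drawn coherently from a single level-2 term's gene pool (the
exact signal the enrichment stage claims to detect); background edges are
independent coin flips.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import yaml

from .errors import ConfigError, IntegrityError

log = logging.getLogger(__name__)

TISSUES = ("colon", "pancreas", "kidney", "bladder", "prostate", "uterus", "lung", "breast")


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    n_tfs: int = 20
    n_families: int = 20
    n_level2_terms: int = 15
    genes_per_term: float = 120.0
    n_planted_pairs: int = 10
    planted_overlap: int = 8
    background_edge_prob: float = 0.01
    planted_rho_normal: float = 0.7
    planted_rho_tumor: float = 0.0
    n_samples_per_condition: int = 16
    matures_per_family: int = 2
    n_host_precursors: int = 5
    plant_motifs: bool = True
    n_random_upstream_edges: int = 0
    leaf_annotation_prob: float = 0.3
    member_noise_sd: float = 0.05
    n_na_cells: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_tfs": self.n_tfs,
            "n_families": self.n_families, "n_level2_terms": self.n_level2_terms,
            "n_planted_pairs": self.n_planted_pairs, "planted_overlap": self.planted_overlap,
            "n_samples_per_condition": self.n_samples_per_condition,
            "matures_per_family": self.matures_per_family,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive (got {value})")
        if not 0.0 <= self.background_edge_prob <= 1.0:
            raise ConfigError("background_edge_prob must lie in [0, 1]")
        for name in ("planted_rho_normal", "planted_rho_tumor"):
            if abs(getattr(self, name)) > 1.0:
                raise ConfigError(f"{name} must lie in [-1, 1]")
        if self.n_planted_pairs > min(self.n_tfs, self.n_families):
            raise ConfigError(
                "n_planted_pairs cannot exceed min(n_tfs, n_families): "
                "each planted pair uses a distinct TF and family"
            )
        if self.n_samples_per_condition < 3:
            raise ConfigError("n_samples_per_condition must be >= 3")

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticTruth:
    planted_pairs: List[Tuple[str, str, str]]  # (tf, family, planted term)
    planted_motifs: List[Tuple[Tuple[str, str], str]]
    planted_correlations: Dict[Tuple[str, str], Tuple[float, float]]
    tf_ids: List[str] = field(default_factory=list)
    family_members: Dict[str, List[str]] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "planted_pairs": [list(t) for t in self.planted_pairs],
            "planted_motifs": [[list(pair), motif] for pair, motif in self.planted_motifs],
            "planted_correlations": {
                f"{a}|{b}": list(rhos) for (a, b), rhos in self.planted_correlations.items()
            },
            "tf_ids": self.tf_ids,
            "family_members": self.family_members,
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            planted_pairs=[tuple(t) for t in payload["planted_pairs"]],
            planted_motifs=[(tuple(p), m) for p, m in payload["planted_motifs"]],
            planted_correlations={
                tuple(k.split("|")): tuple(v)
                for k, v in payload["planted_correlations"].items()
            },
            tf_ids=payload.get("tf_ids", []),
            family_members=payload.get("family_members", {}),
        )


def _term_id(i: int) -> str:
    return f"GO:{1000001 + i:07d}"


def _leaf_id(i: int) -> str:
    return f"GO:{2000001 + i:07d}"


def _write_tsv(path: str, header: Sequence[str], rows: Sequence[Sequence[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


BUNDLE_FILES = {
    "obo": "ontology.obo",
    "annotations": "annotations.tsv",
    "tf_targets": "tf_targets.tsv",
    "mirna_targets": "mirna_targets.tsv",
    "family_map": "family_map.tsv",
    "host_map": "host_map.tsv",
    "tf_mir_edges": "tf_mir_edges.tsv",
    "truth": "truth.json",
    "config": "config.yaml",
    "expression": "expression_matrix.tsv",
    "sample_meta": "sample_meta.tsv",
    "entity_kinds": "entity_kinds.tsv",
}


def bundle_paths(out_dir: str) -> Dict[str, str]:
    return {key: os.path.join(out_dir, name) for key, name in BUNDLE_FILES.items()}


def simulate_regulatory_system(
    config: SyntheticConfig, out_dir: str
) -> Tuple[Dict[str, str], SyntheticTruth]:
    """Generate the regulatory half of a bundle; returns (paths, truth).

    Infeasible configurations (a planted term too small for the requested
    overlap) raise :class:`ConfigError` before any file is written.
    Deterministic: same config (incl. seed) -> byte-identical files.
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)

    genes = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]
    terms = [_term_id(i) for i in range(cfg.n_level2_terms)]
    leaves = [_leaf_id(i) for i in range(cfg.n_level2_terms)]
    tf_ids = [f"TF{i + 1:03d}" for i in range(cfg.n_tfs)]
    fam_ids = [f"miR-fam{i + 1:03d}" for i in range(cfg.n_families)]
    family_members = {
        fam: [f"miR-{i + 1:03d}{chr(ord('a') + j)}" for j in range(cfg.matures_per_family)]
        for i, fam in enumerate(fam_ids)
    }

    # --- annotations: each gene carries 0-3 level-2 terms -------------------
    mean_terms = cfg.n_level2_terms * cfg.genes_per_term / cfg.n_genes
    p_term = min(1.0, max(0.0, mean_terms / 3.0))
    gene_l2: Dict[str, List[int]] = {}
    for g in genes:
        k = int(rng.binomial(3, p_term))
        gene_l2[g] = sorted(rng.choice(cfg.n_level2_terms, size=k, replace=False)) if k else []
    term_pool: Dict[int, List[str]] = {i: [] for i in range(cfg.n_level2_terms)}
    for g in genes:
        for i in gene_l2[g]:
            term_pool[i].append(g)

    # raw annotation rows point either at the level-2 term or its leaf child
    annot_rows: List[Tuple[str, str]] = []
    for g in genes:
        for i in gene_l2[g]:
            use_leaf = rng.random() < cfg.leaf_annotation_prob
            annot_rows.append((g, leaves[i] if use_leaf else terms[i]))

    # --- planted pairs (feasibility checked before writing) -----------------
    tf_order = list(rng.permutation(tf_ids))
    fam_order = list(rng.permutation(fam_ids))
    eligible = [i for i in range(cfg.n_level2_terms) if len(term_pool[i]) >= cfg.planted_overlap]
    if len(eligible) == 0 and cfg.n_planted_pairs > 0:
        raise ConfigError(
            f"no level-2 term has >= {cfg.planted_overlap} annotated genes; "
            "increase genes_per_term or lower planted_overlap"
        )
    planted: List[Tuple[str, str, str]] = []
    planted_edges_tf: Set[Tuple[str, str]] = set()
    planted_edges_fam: Set[Tuple[str, str]] = set()
    for j in range(cfg.n_planted_pairs):
        tf, fam = tf_order[j], fam_order[j]
        ti = eligible[int(rng.integers(len(eligible)))]
        shared = list(rng.choice(term_pool[ti], size=cfg.planted_overlap, replace=False))
        planted.append((tf, fam, terms[ti]))
        for g in shared:
            planted_edges_tf.add((tf, g))
            planted_edges_fam.add((fam, g))

    # --- background edges ----------------------------------------------------
    tf_edges: Set[Tuple[str, str]] = set(planted_edges_tf)
    for tf in tf_ids:
        mask = rng.random(cfg.n_genes) < cfg.background_edge_prob
        tf_edges.update((tf, genes[i]) for i in np.nonzero(mask)[0])
    fam_edges: Set[Tuple[str, str]] = set(planted_edges_fam)
    for fam in fam_ids:
        mask = rng.random(cfg.n_genes) < cfg.background_edge_prob
        fam_edges.update((fam, genes[i]) for i in np.nonzero(mask)[0])

    # family edges are written at mature level; member chosen at random
    mature_rows: List[Tuple[str, str]] = []
    for fam, g in sorted(fam_edges):
        members = family_members[fam]
        mature_rows.append((members[int(rng.integers(len(members)))], g))

    # --- upstream network ----------------------------------------------------
    planted_motifs: List[Tuple[Tuple[str, str], str]] = []
    upstream_tf_rows: Set[Tuple[str, str]] = set()  # extra TF->TF-gene target rows
    tf_mir_rows: Set[Tuple[str, str]] = set()
    if cfg.plant_motifs:
        for tf, fam, _term in planted:
            candidates = [x for x in tf_ids if x != tf]
            x = candidates[int(rng.integers(len(candidates)))]
            upstream_tf_rows.add((x, tf))   # X targets the TF's gene -> X->TF
            tf_mir_rows.add((x, fam))       # predicted X->family edge
            key = (tf, fam) if tf < fam else (fam, tf)
            planted_motifs.append((key, "COMMON_UP_TF"))
    for _ in range(cfg.n_random_upstream_edges):
        x = tf_ids[int(rng.integers(cfg.n_tfs))]
        fam = fam_ids[int(rng.integers(cfg.n_families))]
        tf_mir_rows.add((x, fam))

    # --- host genes ----------------------------------------------------------
    host_rows: List[Tuple[str, str]] = []
    precursor_family: List[Tuple[str, str]] = []
    n_pre = min(cfg.n_host_precursors, cfg.n_families)
    for i in range(n_pre):
        fam = fam_ids[i]
        precursor = f"{fam}-pre"
        host = genes[int(rng.integers(cfg.n_genes))]
        host_rows.append((precursor, host))
        precursor_family.append((precursor, fam))

    # --- expression correlations (consumed by simulate_expression) ----------
    planted_corr = {
        ((tf, fam) if tf < fam else (fam, tf)): (cfg.planted_rho_normal, cfg.planted_rho_tumor)
        for tf, fam, _ in planted
    }

    truth = SyntheticTruth(
        planted_pairs=planted,
        planted_motifs=planted_motifs,
        planted_correlations=planted_corr,
        tf_ids=list(tf_ids),
        family_members={f: list(m) for f, m in family_members.items()},
    )

    # --- write files ---------------------------------------------------------
    os.makedirs(out_dir, exist_ok=True)
    paths = bundle_paths(out_dir)

    with open(paths["obo"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("format-version: 1.2\nontology: toy-bp\n")
        fh.write("\n[Term]\nid: GO:0008150\nname: biological_process\nnamespace: biological_process\n")
        for i, t in enumerate(terms):
            fh.write(f"\n[Term]\nid: {t}\nname: process_{i + 1}\n")
            fh.write("namespace: biological_process\nis_a: GO:0008150 ! biological_process\n")
        for i, leaf in enumerate(leaves):
            fh.write(f"\n[Term]\nid: {leaf}\nname: process_{i + 1}_child\n")
            fh.write(f"namespace: biological_process\nis_a: {terms[i]} ! process_{i + 1}\n")

    _write_tsv(paths["annotations"], ("gene", "term"), sorted(annot_rows))
    _write_tsv(
        paths["tf_targets"],
        ("regulator_id", "regulator_kind", "target_gene"),
        [(tf, "TF", g) for tf, g in sorted(tf_edges | upstream_tf_rows)],
    )
    _write_tsv(paths["mirna_targets"], ("mature_mirna", "target_gene"), sorted(mature_rows))
    fam_map_rows = [
        (m, fam) for fam, members in sorted(family_members.items()) for m in members
    ] + sorted(precursor_family)
    _write_tsv(paths["family_map"], ("mature_mirna", "family"), sorted(fam_map_rows))
    _write_tsv(paths["host_map"], ("precursor", "host_gene"), sorted(host_rows))
    _write_tsv(paths["tf_mir_edges"], ("source", "dest"), sorted(tf_mir_rows))
    truth.to_json(paths["truth"])
    with open(paths["config"], "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

    _verify_regulatory_bundle(paths, truth, cfg)
    log.info(
        "simulate_regulatory_system: %d TF edges, %d mature-miRNA edges, %d planted pairs -> %s",
        len(tf_edges), len(mature_rows), len(planted), out_dir,
    )
    return paths, truth


def _verify_regulatory_bundle(paths: Dict[str, str], truth: SyntheticTruth, cfg: SyntheticConfig) -> None:
    """Post-write check: file-level shared-target counts honour the plant."""
    from .core_io.readers import read_edge_list, read_regulator_targets, read_two_column_map
    from .pair_enrichment import collapse_families

    tf_net = read_regulator_targets(paths["tf_targets"])
    fam_map = read_two_column_map(paths["family_map"], "mature_mirna", "family")
    mir_edges = read_edge_list(paths["mirna_targets"], "mature_mirna", "target_gene")
    mir_net = collapse_families(sorted(mir_edges), fam_map)
    for tf, fam, _term in truth.planted_pairs:
        shared = tf_net.targets(tf) & mir_net.targets(fam)
        if len(shared) < cfg.planted_overlap:
            raise IntegrityError(
                f"planted pair ({tf}, {fam}) shares only {len(shared)} targets on file"
            )


def simulate_expression(
    truth: SyntheticTruth, config: SyntheticConfig, out_dir: str
) -> Dict[str, str]:
    """Generate paired normal/tumour expression for the bundle's regulators.

    Planted pairs get bivariate-normal expression with the configured
    correlation per condition (family members share the family signal plus
    small independent noise); everything else is independent N(0, 1).
    """
    cfg = config
    if cfg.n_samples_per_condition < 3:
        raise ConfigError("n_samples_per_condition must be >= 3")
    rng = np.random.default_rng([cfg.rng_seed, 7919])

    n = cfg.n_samples_per_condition
    sample_ids = [f"N{i + 1:03d}" for i in range(n)] + [f"T{i + 1:03d}" for i in range(n)]
    conditions = ["normal"] * n + ["tumor"] * n
    tissues = [TISSUES[i % len(TISSUES)] for i in range(n)] * 2

    tf_ids = sorted(truth.tf_ids)
    matures = sorted(m for members in truth.family_members.values() for m in members)
    fam_of_pairkey: Dict[str, Tuple[str, float, float]] = {}

    rows: Dict[str, np.ndarray] = {}
    for tf in tf_ids:
        rows[tf] = rng.standard_normal(2 * n)
    fam_signal: Dict[str, np.ndarray] = {}
    for fam in sorted(truth.family_members):
        fam_signal[fam] = rng.standard_normal(2 * n)

    # overwrite planted pairs with correlated draws, per condition
    for (a, b), (rho_n, rho_t) in sorted(truth.planted_correlations.items()):
        tf, fam = (a, b) if a in rows else (b, a)
        if tf not in rows or fam not in fam_signal:
            continue
        t_vec = np.empty(2 * n)
        f_vec = np.empty(2 * n)
        for sl, rho in ((slice(0, n), rho_n), (slice(n, 2 * n), rho_t)):
            # explicit Cholesky construction; well-defined at |rho| = 1
            z1 = rng.standard_normal(n)
            z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)
            t_vec[sl] = z1
            f_vec[sl] = z2
        rows[tf] = t_vec
        fam_signal[fam] = f_vec

    for fam, members in sorted(truth.family_members.items()):
        for m in members:
            rows[m] = fam_signal[fam] + cfg.member_noise_sd * rng.standard_normal(2 * n)

    entity_ids = tf_ids + matures
    matrix = np.vstack([rows[e] for e in entity_ids])

    if cfg.n_na_cells:
        flat = rng.choice(matrix.size, size=cfg.n_na_cells, replace=False)
        matrix.ravel()[flat] = np.nan

    paths = bundle_paths(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    with open(paths["expression"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("entity_id\t" + "\t".join(sample_ids) + "\n")
        for eid, row in zip(entity_ids, matrix):
            cells = ["NA" if np.isnan(v) else f"{v:.6f}" for v in row]
            fh.write(eid + "\t" + "\t".join(cells) + "\n")
    _write_tsv(
        paths["sample_meta"],
        ("sample_id", "tissue", "condition"),
        list(zip(sample_ids, tissues, conditions)),
    )
    _write_tsv(
        paths["entity_kinds"],
        ("entity_id", "kind"),
        [(tf, "mRNA") for tf in tf_ids] + [(m, "mature_miRNA") for m in matures],
    )
    log.info(
        "simulate_expression: %d entities x %d samples -> %s",
        len(entity_ids), 2 * n, out_dir,
    )
    return paths


def simulate_bundle(config: SyntheticConfig, out_dir: str) -> Tuple[Dict[str, str], SyntheticTruth]:
    """Regulatory system plus matched expression in one call."""
    paths, truth = simulate_regulatory_system(config, out_dir)
    simulate_expression(truth, config, out_dir)
    return paths, truth
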