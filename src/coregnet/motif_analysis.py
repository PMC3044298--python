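"""Upstream network-motif counting and resampling-based enrichment.

Each motif is a pure predicate over (coregulation pair, upstream
network). Because a pair shares downstream targets by construction, any
direct edge between its members completes a feed-forward loop through
every shared target; the catalog therefore tests the upstream edge
patterns directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .core_io.types import RegulatorKind, RegulatorTargetNetwork, UpstreamNetwork
from .errors import ConfigError, DomainError
from .pair_enrichment import CoregulationPair, PairKind

log = logging.getLogger(__name__)


class UpstreamIndex:
    """Adjacency/kind lookups for fast motif predicates."""

    def __init__(self, upstream: UpstreamNetwork) -> None:
        self.out: Dict[str, Set[str]] = {}
        self.inc: Dict[str, Set[str]] = {}
        for s, d in upstream.edges:
            self.out.setdefault(s, set()).add(d)
            self.inc.setdefault(d, set()).add(s)
        self.kinds = dict(upstream.kinds)

    def succ(self, node: str) -> Set[str]:
        return self.out.get(node, set())

    def pred(self, node: str) -> Set[str]:
        return self.inc.get(node, set())

    def has_edge(self, s: str, d: str) -> bool:
        return d in self.out.get(s, ())

    def preds_of_kind(self, node: str, kind: RegulatorKind) -> Set[str]:
        return {p for p in self.pred(node) if self.kinds.get(p) is kind}


Predicate = Callable[[CoregulationPair, UpstreamIndex], bool]


@dataclass(frozen=True)
class MotifCatalogEntry:
    motif_id: str
    predicate: Predicate
    description: str


def _ffl_bidir(pair: CoregulationPair, idx: UpstreamIndex) -> bool:
    return idx.has_edge(pair.reg_a, pair.reg_b) and idx.has_edge(pair.reg_b, pair.reg_a)


def _ffl_unidir(pair: CoregulationPair, idx: UpstreamIndex) -> bool:
    return idx.has_edge(pair.reg_a, pair.reg_b) != idx.has_edge(pair.reg_b, pair.reg_a)


def _common_up_tf(pair: CoregulationPair, idx: UpstreamIndex) -> bool:
    common = idx.preds_of_kind(pair.reg_a, RegulatorKind.TF) & idx.preds_of_kind(
        pair.reg_b, RegulatorKind.TF
    )
    return bool(common - {pair.reg_a, pair.reg_b})


def _common_up_tf_and_mir(pair: CoregulationPair, idx: UpstreamIndex) -> bool:
    if not _common_up_tf(pair, idx):
        return False
    common = idx.preds_of_kind(pair.reg_a, RegulatorKind.MIRNA_FAMILY) & idx.preds_of_kind(
        pair.reg_b, RegulatorKind.MIRNA_FAMILY
    )
    return bool(common - {pair.reg_a, pair.reg_b})


def _upstream_crosstalk(pair: CoregulationPair, idx: UpstreamIndex) -> bool:
    exclude = {pair.reg_a, pair.reg_b}
    preds_a = idx.pred(pair.reg_a) - exclude
    preds_b = idx.pred(pair.reg_b) - exclude
    if not preds_a or not preds_b:
        return False
    if preds_a & preds_b:
        return True
    for x in preds_a:
        if idx.succ(x) & preds_b:
            return True
    for y in preds_b:
        if idx.succ(y) & preds_a:
            return True
    return False


DEFAULT_CATALOG: Tuple[MotifCatalogEntry, ...] = (
    MotifCatalogEntry("FFL_BIDIR", _ffl_bidir, "pair members regulate each other (A<->B)"),
    MotifCatalogEntry("FFL_UNIDIR", _ffl_unidir, "exactly one of A->B, B->A"),
    MotifCatalogEntry("COMMON_UP_TF", _common_up_tf, "a third-party TF regulates both members"),
    MotifCatalogEntry(
        "COMMON_UP_TF_AND_MIR", _common_up_tf_and_mir,
        "a third-party TF and a third-party miRNA family each regulate both members",
    ),
    MotifCatalogEntry(
        "UPSTREAM_CROSSTALK", _upstream_crosstalk,
        "upstream regulators of the two members coincide or regulate one another",
    ),
)


def catalog_by_id(catalog: Sequence[MotifCatalogEntry] = DEFAULT_CATALOG) -> Dict[str, MotifCatalogEntry]:
    ids = [e.motif_id for e in catalog]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate motif ids in catalog")
    return {e.motif_id: e for e in catalog}


def build_upstream_network(
    tf_net: RegulatorTargetNetwork,
    tf_mir_edges: Iterable[Tuple[str, str]],
    host_edges: Iterable[Tuple[str, str]],
    mir_net: RegulatorTargetNetwork,
) -> UpstreamNetwork:
    """Directed regulator->regulator network from four evidence sources.

    TF->TF when a TF's gene is in another TF's target set; TF->family from
    predicted targeting plus host-gene propagation; family->TF when a
    family targets a TF's gene. The union is deduplicated.
    """
    up = UpstreamNetwork()
    up.kinds.update({rid: RegulatorKind.TF for rid in tf_net.regulators})
    up.kinds.update({rid: RegulatorKind.MIRNA_FAMILY for rid in mir_net.regulators})

    tf_genes: Dict[str, str] = {}
    for rid, reg in tf_net.regulators.items():
        for gene in reg.members:
            tf_genes[gene] = rid

    for tf_id in tf_net.regulators:
        for gene in tf_net.targets(tf_id):
            other = tf_genes.get(gene)
            if other is not None and other != tf_id:
                up.add_edge(tf_id, other)
    for tf_id, fam_id in tf_mir_edges:
        if tf_id != fam_id:
            up.add_edge(tf_id, fam_id)
            up.kinds.setdefault(tf_id, RegulatorKind.TF)
            up.kinds.setdefault(fam_id, RegulatorKind.MIRNA_FAMILY)
    for tf_id, fam_id in host_edges:
        if tf_id != fam_id:
            up.add_edge(tf_id, fam_id)
            up.kinds.setdefault(tf_id, RegulatorKind.TF)
            up.kinds.setdefault(fam_id, RegulatorKind.MIRNA_FAMILY)
    for fam_id in mir_net.regulators:
        for gene in mir_net.targets(fam_id):
            tf_id = tf_genes.get(gene)
            if tf_id is not None and tf_id != fam_id:
                up.add_edge(fam_id, tf_id)
    log.info("build_upstream_network: %d directed edges", up.n_edges)
    return up


def count_motifs(
    pairs: Sequence[CoregulationPair],
    upstream: UpstreamNetwork,
    catalog: Sequence[MotifCatalogEntry] = DEFAULT_CATALOG,
) -> Dict[str, int]:
    """Number of pairs satisfying each motif predicate."""
    idx = UpstreamIndex(upstream)
    return {
        entry.motif_id: sum(1 for p in pairs if entry.predicate(p, idx))
        for entry in catalog
    }


@dataclass(frozen=True)
class MotifResult:
    motif_id: str
    pair_kind: Optional[PairKind]
    observed: int
    observed_fraction: float
    null_mean: float
    null_sd: float
    null_max: int
    p_emp: float
    significant: bool


def motif_significance(
    enriched_pairs: Sequence[CoregulationPair],
    all_pairs: Sequence[CoregulationPair],
    upstream: UpstreamNetwork,
    catalog: Sequence[MotifCatalogEntry] = DEFAULT_CATALOG,
    n_resample: int = 10000,
    rng_seed: int = 0,
    alpha_motif: float = 0.001,
    pair_kind: Optional[PairKind] = None,
) -> List[MotifResult]:
    """Compare observed motif counts to same-size pair sets resampled from
    the background pool.

    p_emp = (1 + #{null >= observed}) / (1 + n_resample); over-representation
    only. ``pair_kind`` restricts both foreground and pool to one kind.
    """
    if pair_kind is not None:
        enriched_pairs = [p for p in enriched_pairs if p.pair_kind is pair_kind]
        all_pairs = [p for p in all_pairs if p.pair_kind is pair_kind]
    if not enriched_pairs:
        raise DomainError("enriched pair set is empty")
    if len(all_pairs) < len(enriched_pairs):
        raise DomainError("background pool smaller than the enriched set")

    idx = UpstreamIndex(upstream)
    pool = sorted(all_pairs, key=lambda p: p.key)
    flags = np.array(
        [[entry.predicate(p, idx) for entry in catalog] for p in pool], dtype=bool
    )
    observed = np.array(
        [sum(1 for p in enriched_pairs if entry.predicate(p, idx)) for entry in catalog]
    )

    k = len(enriched_pairs)
    rng = np.random.default_rng(rng_seed)
    null_counts = np.empty((n_resample, len(catalog)), dtype=np.int64)
    n_pool = len(pool)
    for i in range(n_resample):
        take = rng.choice(n_pool, size=k, replace=False)
        null_counts[i] = flags[take].sum(axis=0)

    results = []
    for j, entry in enumerate(catalog):
        exceed = int((null_counts[:, j] >= observed[j]).sum())
        p_emp = (1 + exceed) / (1 + n_resample)
        results.append(
            MotifResult(
                motif_id=entry.motif_id,
                pair_kind=pair_kind,
                observed=int(observed[j]),
                observed_fraction=float(observed[j] / k),
                null_mean=float(null_counts[:, j].mean()),
                null_sd=float(null_counts[:, j].std(ddof=1)) if n_resample > 1 else 0.0,
                null_max=int(null_counts[:, j].max()),
                p_emp=float(p_emp),
                significant=bool(p_emp < alpha_motif),
            )
        )
    return results
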