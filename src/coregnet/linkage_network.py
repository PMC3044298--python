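"""Per-term functional linkages (Fisher's exact test) and coregulation networks.

A pair that passed profile enrichment is linked through every level-2
term significantly over-represented in its shared targets; the linkages
form a regulator multigraph whose parallel edges are GO terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import DomainError
from .ontology_profiles import Level2Annotation, functional_profile
from .pair_enrichment import CoregulationPair, EnrichmentResult, PairKind, fdr_adjust

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FunctionalLinkage:
    pair: CoregulationPair
    term: str
    p_fisher: float
    q: float
    passed: bool


def _ln_choose(m: float, c: float) -> float:
    return gammaln(m + 1.0) - gammaln(c + 1.0) - gammaln(m - c + 1.0)


def fisher_term_enrichment(shared: Iterable[str], term: str, ann: Level2Annotation) -> float:
    """One-sided enrichment p for a term in a gene set: hypergeometric
    tail P(X >= x), summed directly in log space."""
    if term not in ann.population_counts:
        raise DomainError(f"{term!r} is not a level-2 term")
    genes = {g for g in shared if g in ann.gene_terms}
    n = len(genes)
    x = sum(1 for g in genes if term in ann.gene_terms[g])
    big_n = ann.universe_size
    big_k = ann.population_counts[term]
    if x == 0:
        return 1.0
    hi = min(n, big_k)
    ln_terms = [
        _ln_choose(big_k, i) + _ln_choose(big_n - big_k, n - i)
        for i in range(x, hi + 1)
        if n - i <= big_n - big_k
    ]
    p = math.exp(logsumexp(ln_terms) - _ln_choose(big_n, n))
    return min(p, 1.0)


def build_linkages(
    enriched_pairs: Sequence[EnrichmentResult],
    ann: Level2Annotation,
    alpha: float = 0.05,
    method: str = "BL",
) -> List[FunctionalLinkage]:
    """Test every nonzero-count level-2 term of each enriched pair's
    shared targets; correction is pooled over all (pair, term) tests.

    Zero-count terms are skipped — they cannot be over-represented, so
    the rejections are identical to testing them.
    """
    tests: List[Tuple[CoregulationPair, str, float]] = []
    for res in enriched_pairs:
        if not res.enriched:
            continue
        prof = functional_profile(res.pair.shared_targets, ann)
        for term in ann.terms:
            if prof.counts[term] >= 1:
                tests.append(
                    (res.pair, term, fisher_term_enrichment(res.pair.shared_targets, term, ann))
                )
    if not tests:
        return []
    qs, reject = fdr_adjust([t[2] for t in tests], method=method, alpha=alpha)
    linkages = [
        FunctionalLinkage(pair=pair, term=term, p_fisher=p, q=float(q), passed=bool(rej))
        for (pair, term, p), q, rej in zip(tests, qs, reject)
    ]
    log.info(
        "build_linkages: %d/%d (pair, term) tests passed FDR-%s at %.3g",
        sum(l.passed for l in linkages), len(linkages), method.upper(), alpha,
    )
    return linkages


def build_coregulation_network(
    linkages: Sequence[FunctionalLinkage],
    kind_filter: Optional[PairKind] = None,
) -> nx.MultiGraph:
    """Multigraph of regulators linked by their passing GO terms.

    Nodes carry a ``kind`` attribute; each passing (pair, term) becomes
    one edge with a ``go_term`` attribute.
    """
    net = nx.MultiGraph()
    for link in linkages:
        if not link.passed:
            continue
        if kind_filter is not None and link.pair.pair_kind is not kind_filter:
            continue
        pair = link.pair
        net.add_node(pair.reg_a, kind=pair.kind_a.value)
        net.add_node(pair.reg_b, kind=pair.kind_b.value)
        net.add_edge(pair.reg_a, pair.reg_b, go_term=link.term)
    return net


def network_stats(net: nx.MultiGraph) -> Dict[str, float]:
    """Density and diversity summaries of a coregulation multigraph.

    ``links_per_pair`` = edges / distinct connected regulator pairs;
    ``edge_types_per_regulator`` = mean number of distinct GO terms on a
    node's incident edges; ``largest_component`` = node count. Empty
    networks report NaN markers rather than raising.
    """
    if net.number_of_nodes() == 0:
        return {
            "n_nodes": 0, "n_edges": 0,
            "links_per_pair": float("nan"),
            "edge_types_per_regulator": float("nan"),
            "largest_component": 0,
        }
    distinct_pairs: Set[Tuple[str, str]] = set()
    node_terms: Dict[str, Set[str]] = {n: set() for n in net.nodes}
    for u, v, data in net.edges(data=True):
        distinct_pairs.add((u, v) if u <= v else (v, u))
        term = data.get("go_term", "")
        node_terms[u].add(term)
        node_terms[v].add(term)
    n_edges = net.number_of_edges()
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": n_edges,
        "links_per_pair": n_edges / len(distinct_pairs) if distinct_pairs else float("nan"),
        "edge_types_per_regulator": float(np.mean([len(ts) for ts in node_terms.values()])),
        "largest_component": max(len(c) for c in nx.connected_components(net)),
    }
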