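"""Level-2 biological-process annotation and functional profiles.

The category space for all downstream enrichment is the set of direct
is_a children of the biological_process root ("level-2" terms). A gene
carries a level-2 term when any of its raw annotations is that term or
has it among its ancestors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import networkx as nx
import numpy as np

from .core_io.obo import ancestors, find_bp_root
from .errors import IntegrityError

log = logging.getLogger(__name__)


def level2_terms(dag: nx.MultiDiGraph) -> List[str]:
    """Direct is_a children of the biological_process root, sorted."""
    root = find_bp_root(dag)  # raises IntegrityError when absent
    children = {
        u for u, v, k in dag.in_edges(root, keys=True) if k == "is_a"
    }
    return sorted(children)


class Level2Annotation:
    """Gene -> level-2 term sets plus population counts over a universe.

    ``population_counts[k]`` (M_k) is the number of universe genes
    carrying term k; ``unannotated_count`` is the number of universe genes
    carrying no level-2 term.
    """

    def __init__(self, terms: Iterable[str], gene_terms: Mapping[str, FrozenSet[str]]):
        self.terms: Tuple[str, ...] = tuple(terms)
        term_set = set(self.terms)
        for gene, ts in gene_terms.items():
            if not set(ts) <= term_set:
                raise IntegrityError(
                    f"gene {gene!r} annotated to terms outside the level-2 set"
                )
        self.gene_terms: Dict[str, FrozenSet[str]] = {
            g: frozenset(ts) for g, ts in gene_terms.items()
        }
        self.universe: Tuple[str, ...] = tuple(sorted(self.gene_terms))
        self.population_counts: Dict[str, int] = {t: 0 for t in self.terms}
        self.unannotated_count = 0
        for ts in self.gene_terms.values():
            if ts:
                for t in ts:
                    self.population_counts[t] += 1
            else:
                self.unannotated_count += 1
        self._matrix: Optional[np.ndarray] = None
        self._gene_index: Optional[Dict[str, int]] = None

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def universe_size(self) -> int:
        return len(self.universe)

    def indicator_matrix(self) -> Tuple[np.ndarray, Dict[str, int]]:
        """(genes x (K+1)) 0/1 matrix; last column flags unannotated genes."""
        if self._matrix is None:
            tidx = {t: j for j, t in enumerate(self.terms)}
            mat = np.zeros((len(self.universe), len(self.terms) + 1), dtype=np.int8)
            for i, gene in enumerate(self.universe):
                ts = self.gene_terms[gene]
                if ts:
                    for t in ts:
                        mat[i, tidx[t]] = 1
                else:
                    mat[i, -1] = 1
            self._matrix = mat
            self._gene_index = {g: i for i, g in enumerate(self.universe)}
        return self._matrix, self._gene_index  # type: ignore[return-value]


def map_to_level2(
    raw_annotations: Mapping[str, Set[str]],
    dag: nx.MultiDiGraph,
    universe: Optional[Iterable[str]] = None,
    use_part_of: bool = True,
) -> Level2Annotation:
    """Project raw GO annotations onto the level-2 term space.

    is_a edges are always traversed upward; part_of edges only when
    ``use_part_of`` is on. The universe defaults to the genes of
    ``raw_annotations``; passing a larger universe keeps genes without any
    annotation in the background as unannotated.
    """
    l2 = level2_terms(dag)
    l2set = set(l2)
    closure_cache: Dict[str, FrozenSet[str]] = {}

    def l2_of(term: str) -> FrozenSet[str]:
        hit = closure_cache.get(term)
        if hit is None:
            hit = frozenset(ancestors(dag, term, use_part_of=use_part_of) & l2set)
            closure_cache[term] = hit
        return hit

    genes = sorted(universe) if universe is not None else sorted(raw_annotations)
    gene_terms: Dict[str, FrozenSet[str]] = {}
    for gene in genes:
        acc: Set[str] = set()
        for term in raw_annotations.get(gene, ()):
            acc |= l2_of(term)
        gene_terms[gene] = frozenset(acc)
    ann = Level2Annotation(l2, gene_terms)
    log.info(
        "level-2 mapping: %d terms, %d genes (%d unannotated)",
        ann.n_terms, ann.universe_size, ann.unannotated_count,
    )
    return ann


@dataclass(frozen=True)
class FunctionalProfile:
    """Per-level-2-term annotation counts for a gene set (its fingerprint)."""

    counts: Mapping[str, int]
    set_size: int
    unannotated: int
    n_dropped: int = 0

    @property
    def total_instances(self) -> int:
        return sum(self.counts.values()) + self.unannotated


def functional_profile(genes: Iterable[str], ann: Level2Annotation) -> FunctionalProfile:
    """Tally the level-2 fingerprint of a gene set against ``ann``.

    Genes outside the annotation universe are dropped (count reported on
    the profile and logged). The empty set yields an all-zero profile.
    """
    counts = {t: 0 for t in ann.terms}
    unannotated = 0
    kept = 0
    dropped = 0
    for gene in set(genes):
        ts = ann.gene_terms.get(gene)
        if ts is None:
            dropped += 1
            continue
        kept += 1
        if ts:
            for t in ts:
                counts[t] += 1
        else:
            unannotated += 1
    if dropped:
        log.debug("functional_profile: dropped %d genes outside universe", dropped)
    return FunctionalProfile(counts=counts, set_size=kept, unannotated=unannotated, n_dropped=dropped)
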