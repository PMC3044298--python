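"""Coregulation-pair enumeration and permutation-based profile enrichment.

Two regulators form a coregulation pair when they share enough targets.
Each pair's shared-target functional fingerprint is scored with a
log-likelihood under the multivariate hypergeometric form over level-2
annotation-instance counts (plus an unannotated pseudo-category), and
significance comes entirely from an empirical null of same-size gene sets
drawn uniformly from the background universe. Low likelihood = atypical,
function-coherent profile.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core_io.types import Regulator, RegulatorKind, RegulatorTargetNetwork
from .errors import DomainError
from .ontology_profiles import FunctionalProfile, Level2Annotation, functional_profile

log = logging.getLogger(__name__)


class PairKind(enum.Enum):
    TF_TF = "TF_TF"
    TF_MIR = "TF_MIR"
    MIR_MIR = "MIR_MIR"


_KIND_TABLE = {
    frozenset({RegulatorKind.TF}): PairKind.TF_TF,
    frozenset({RegulatorKind.TF, RegulatorKind.MIRNA_FAMILY}): PairKind.TF_MIR,
    frozenset({RegulatorKind.MIRNA_FAMILY}): PairKind.MIR_MIR,
}


@dataclass(frozen=True)
class CoregulationPair:
    """An unordered regulator pair with its shared-target set.

    ``reg_a < reg_b`` lexicographically (canonical form).
    """

    reg_a: str
    reg_b: str
    kind_a: RegulatorKind
    kind_b: RegulatorKind
    pair_kind: PairKind
    shared_targets: FrozenSet[str]

    @staticmethod
    def make(
        a: str, kind_a: RegulatorKind, b: str, kind_b: RegulatorKind,
        shared: Iterable[str],
    ) -> "CoregulationPair":
        if a == b:
            raise DomainError("a coregulation pair needs two distinct regulators")
        if b < a:
            a, b = b, a
            kind_a, kind_b = kind_b, kind_a
        return CoregulationPair(
            reg_a=a, reg_b=b, kind_a=kind_a, kind_b=kind_b,
            pair_kind=_KIND_TABLE[frozenset({kind_a, kind_b})],
            shared_targets=frozenset(shared),
        )

    @property
    def key(self) -> Tuple[str, str]:
        return (self.reg_a, self.reg_b)


# ---------------------------------------------------------------------------
# network assembly

def collapse_families(
    mirna_edges: Iterable[Tuple[str, str]],
    family_map: Mapping[str, str],
) -> RegulatorTargetNetwork:
    """Collapse mature-miRNA edges into miRNA-family regulators.

    A family's target set is the union over its members. Mature miRNAs
    absent from ``family_map`` become singleton families under their own
    name (logged) rather than being dropped.
    """
    members: Dict[str, set] = {}
    for mature, family in family_map.items():
        members.setdefault(family, set()).add(mature)
    edges = set()
    unmapped = set()
    for mature, target in mirna_edges:
        family = family_map.get(mature)
        if family is None:
            family = mature
            unmapped.add(mature)
            members.setdefault(family, set()).add(mature)
        edges.add((family, target))
    if unmapped:
        log.warning("collapse_families: %d mature miRNAs without a family kept as singletons", len(unmapped))
    used = {f for f, _ in edges}
    regulators = [
        Regulator(id=f, kind=RegulatorKind.MIRNA_FAMILY, members=frozenset(m))
        for f, m in members.items()
        if f in used
    ]
    net = RegulatorTargetNetwork(regulators, edges)
    log.info("collapse_families: %d families, %d edges", net.n_regulators, net.n_edges)
    return net


def propagate_host_regulation(
    tf_net: RegulatorTargetNetwork,
    host_map: Mapping[str, str],
    family_map: Mapping[str, str],
) -> set:
    """TF->family edges implied by miRNA precursors embedded in host genes.

    A TF targeting a host gene is taken to regulate every miRNA family
    whose precursor sits in that host (shared transcription unit).
    Precursors with no family mapping are skipped (logged).
    """
    host_families: Dict[str, set] = {}
    skipped = 0
    for precursor, host in host_map.items():
        family = family_map.get(precursor)
        if family is None:
            skipped += 1
            continue
        host_families.setdefault(host, set()).add(family)
    edges = set()
    for tf_id, target in tf_net.edges:
        for family in host_families.get(target, ()):
            edges.add((tf_id, family))
    if skipped:
        log.warning("propagate_host_regulation: %d precursors without family mapping skipped", skipped)
    log.info("propagate_host_regulation: %d TF->family edges", len(edges))
    return edges


def enumerate_pairs(
    tf_net: RegulatorTargetNetwork,
    mir_net: RegulatorTargetNetwork,
    min_shared: int = 3,
) -> List[CoregulationPair]:
    """All same-kind and cross-kind pairs with >= ``min_shared`` shared targets.

    Returned in canonical (reg_a, reg_b) order; enumeration is invariant
    to input ordering.
    """
    tf_ids = sorted(tf_net.regulators)
    mir_ids = sorted(mir_net.regulators)
    pairs: List[CoregulationPair] = []

    def _scan(ids_a, net_a, ids_b, net_b, cross):
        for i, a in enumerate(ids_a):
            ta = net_a.targets(a)
            bs = ids_b if cross else ids_a[i + 1:]
            for b in bs:
                if not cross and b == a:
                    continue
                shared = ta & net_b.targets(b)
                if len(shared) >= min_shared:
                    pairs.append(
                        CoregulationPair.make(
                            a, net_a.regulators[a].kind, b, net_b.regulators[b].kind, shared
                        )
                    )

    _scan(tf_ids, tf_net, tf_ids, tf_net, cross=False)
    _scan(mir_ids, mir_net, mir_ids, mir_net, cross=False)
    _scan(tf_ids, tf_net, mir_ids, mir_net, cross=True)
    pairs.sort(key=lambda p: p.key)
    log.info("enumerate_pairs: %d pairs with >= %d shared targets", len(pairs), min_shared)
    return pairs


# ---------------------------------------------------------------------------
# scoring

def _ln_choose(m: np.ndarray, c: np.ndarray) -> np.ndarray:
    return gammaln(m + 1.0) - gammaln(c + 1.0) - gammaln(m - c + 1.0)


def _profile_vectors(profile: FunctionalProfile, ann: Level2Annotation) -> Tuple[np.ndarray, np.ndarray]:
    m = np.array(
        [ann.population_counts[t] for t in ann.terms] + [ann.unannotated_count],
        dtype=np.float64,
    )
    c = np.array(
        [profile.counts[t] for t in ann.terms] + [profile.unannotated],
        dtype=np.float64,
    )
    return m, c


def mvh_loglik(profile: FunctionalProfile, ann: Level2Annotation) -> float:
    """Log-likelihood of a fingerprint under the multivariate hypergeometric form.

    L = sum_k ln C(M_k, c_k) - ln C(M_tot, n_inst) over the level-2
    categories plus the unannotated pseudo-category. L <= 0; lower values
    mean the instance counts concentrate in few categories relative to the
    population. Computed with log-gamma, so safe for M_tot up to 1e7.
    """
    m, c = _profile_vectors(profile, ann)
    over = c > m
    if over.any():
        labels = list(ann.terms) + ["<unannotated>"]
        bad = [labels[i] for i in np.nonzero(over)[0]]
        raise DomainError(f"profile count exceeds population count for: {bad}")
    return float(_ln_choose(m, c).sum() - _ln_choose(m.sum(), c.sum()))


def empirical_p(observed: float, null_scores: Sequence[float]) -> float:
    """Lower-tail empirical p with the add-one pseudocount: never 0."""
    null = np.asarray(null_scores, dtype=float)
    return float((1 + int((null <= observed).sum())) / (1 + null.size))


class PermutationNull:
    """Cached null score distributions, one per gene-set size.

    The null for size n depends only on n, so it is computed once per run
    and shared across pairs; the RNG for size n is seeded as
    ``(seed, n)`` so results do not depend on pair processing order.
    """

    def __init__(self, ann: Level2Annotation, n_perm: int, seed: int) -> None:
        self.ann = ann
        self.n_perm = int(n_perm)
        if self.n_perm < 1:
            raise DomainError("n_perm must be >= 1")
        self.seed = int(seed)
        self._cache: Dict[int, np.ndarray] = {}

    def scores(self, n: int) -> np.ndarray:
        n = int(n)
        if n < 1:
            raise DomainError("gene-set size must be >= 1")
        mat, _ = self.ann.indicator_matrix()
        n_genes = mat.shape[0]
        if n > n_genes:
            raise DomainError(f"gene-set size {n} exceeds universe size {n_genes}")
        hit = self._cache.get(n)
        if hit is not None:
            return hit
        rng = np.random.default_rng([self.seed, n])
        counts = np.empty((self.n_perm, mat.shape[1]), dtype=np.float64)
        for i in range(self.n_perm):
            idx = rng.choice(n_genes, size=n, replace=False)
            counts[i] = mat[idx].sum(axis=0)
        m = np.array(
            [self.ann.population_counts[t] for t in self.ann.terms]
            + [self.ann.unannotated_count],
            dtype=np.float64,
        )
        lls = _ln_choose(m[None, :], counts).sum(axis=1) - _ln_choose(
            m.sum(), counts.sum(axis=1)
        )
        self._cache[n] = lls
        return lls


def permutation_test(
    profile: FunctionalProfile,
    ann: Level2Annotation,
    n_perm: int = 10000,
    rng_seed: int = 0,
    null: Optional[PermutationNull] = None,
) -> Tuple[float, float]:
    """Score a fingerprint and return (L_obs, empirical p vs same-size null sets)."""
    if profile.set_size < 1:
        raise DomainError("cannot test an empty gene set")
    if null is None:
        null = PermutationNull(ann, n_perm, rng_seed)
    l_obs = mvh_loglik(profile, ann)
    return l_obs, empirical_p(l_obs, null.scores(profile.set_size))


# ---------------------------------------------------------------------------
# multiple-testing correction

def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _bl_adjust(p: np.ndarray) -> np.ndarray:
    # step-down procedure with adjusted value
    # (m-i+1)/m * (1 - (1-p_(i))^(m-i+1)), running max for monotonicity
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    i = np.arange(1, m + 1)
    k = m - i + 1
    raw = (k / m) * (1.0 - np.power(1.0 - ps, k))
    adj = np.minimum(np.maximum.accumulate(raw), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def fdr_adjust(
    pvalues: Sequence[float], method: str = "BH", alpha: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """FDR correction: Benjamini-Hochberg step-up or Benjamini-Liu step-down.

    Returns (adjusted values, rejection flags at ``alpha``); flags are
    consistent with the adjusted values (reject iff adjusted <= alpha).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    meth = method.upper()
    if meth == "BH":
        adj = _bh_adjust(p)
    elif meth == "BL":
        adj = _bl_adjust(p)
    else:
        raise DomainError(f"unknown FDR method {method!r}")
    return adj, adj <= alpha


# ---------------------------------------------------------------------------
# driver

@dataclass(frozen=True)
class EnrichmentResult:
    pair: CoregulationPair
    n_shared: int
    loglik: float
    p_perm: float
    q: float
    enriched: bool


def find_enriched_pairs(
    pairs: Sequence[CoregulationPair],
    ann: Level2Annotation,
    n_perm: int = 10000,
    alpha: float = 0.05,
    rng_seed: int = 0,
    fdr_method: str = "BH",
) -> List[EnrichmentResult]:
    """Score every pair's shared-target fingerprint against the permutation
    null and flag pairs passing pooled FDR at ``alpha``. Deterministic
    given the seed."""
    if not pairs:
        raise DomainError("no coregulation pairs to test")
    null = PermutationNull(ann, n_perm, rng_seed)
    rows: List[Tuple[CoregulationPair, FunctionalProfile, float, float]] = []
    for pair in sorted(pairs, key=lambda p: p.key):
        prof = functional_profile(pair.shared_targets, ann)
        l_obs, p = permutation_test(prof, ann, null=null)
        rows.append((pair, prof, l_obs, p))
    qs, reject = fdr_adjust([r[3] for r in rows], method=fdr_method, alpha=alpha)
    results = [
        EnrichmentResult(
            pair=pair, n_shared=len(pair.shared_targets),
            loglik=l_obs, p_perm=p, q=float(q), enriched=bool(rej),
        )
        for (pair, _, l_obs, p), q, rej in zip(rows, qs, reject)
    ]
    log.info(
        "find_enriched_pairs: %d/%d pairs enriched at FDR %.3g (%s, %d permutations)",
        sum(r.enriched for r in results), len(results), alpha, fdr_method, n_perm,
    )
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "reg_a": [r.pair.reg_a for r in results],
            "reg_b": [r.pair.reg_b for r in results],
            "pair_kind": [r.pair.pair_kind.value for r in results],
            "n_shared": [r.n_shared for r in results],
            "loglik": [r.loglik for r in results],
            "p_perm": [r.p_perm for r in results],
            "q": [r.q for r in results],
            "enriched": [r.enriched for r in results],
        }
    )
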