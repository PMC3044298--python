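import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coregnet.core_io.types import Regulator, RegulatorKind, RegulatorTargetNetwork
from coregnet.errors import DomainError
from coregnet.ontology_profiles import FunctionalProfile, Level2Annotation, functional_profile
from coregnet.pair_enrichment import (
    CoregulationPair,
    PairKind,
    PermutationNull,
    collapse_families,
    empirical_p,
    enumerate_pairs,
    fdr_adjust,
    find_enriched_pairs,
    mvh_loglik,
    permutation_test,
    propagate_host_regulation,
    results_to_frame,
)

from .oracles import bh_stepup, compositions, exact_mvh_probability


def _tf_net(targets_by_tf):
    regs = [
        Regulator(id=tf, kind=RegulatorKind.TF, members=frozenset({tf}))
        for tf in targets_by_tf
    ]
    edges = [(tf, g) for tf, gs in targets_by_tf.items() for g in gs]
    return RegulatorTargetNetwork(regs, edges)


def _mir_net(targets_by_fam):
    regs = [
        Regulator(id=f, kind=RegulatorKind.MIRNA_FAMILY, members=frozenset({f}))
        for f in targets_by_fam
    ]
    edges = [(f, g) for f, gs in targets_by_fam.items() for g in gs]
    return RegulatorTargetNetwork(regs, edges)


def _ann_from_counts(m, n_unannotated=0):
    """Annotation whose population counts are exactly ``m`` using
    single-term genes (enough for score arithmetic tests)."""
    terms = [f"GO:{k:07d}" for k in range(1, len(m) + 1)]
    gene_terms = {}
    gid = 0
    for term, mk in zip(terms, m):
        for _ in range(mk):
            gene_terms[f"g{gid:05d}"] = frozenset({term})
            gid += 1
    for _ in range(n_unannotated):
        gene_terms[f"g{gid:05d}"] = frozenset()
        gid += 1
    return Level2Annotation(terms, gene_terms)


def _profile(ann, c, unannotated=0):
    return FunctionalProfile(
        counts=dict(zip(ann.terms, c)), set_size=sum(c) + unannotated, unannotated=unannotated
    )


class TestCollapseFamilies:
    def test_union_of_member_targets(self):
        net = collapse_families(
            [("miR-a", "g1"), ("miR-b", "g2")], {"miR-a": "F", "miR-b": "F"}
        )
        assert net.targets("F") == {"g1", "g2"}
        assert net.regulators["F"].members == {"miR-a", "miR-b"}

    def test_shared_target_deduplicated(self):
        net = collapse_families(
            [("miR-a", "g1"), ("miR-b", "g1")], {"miR-a": "F", "miR-b": "F"}
        )
        assert net.n_edges == 1

    def test_unmapped_mature_becomes_singleton(self):
        net = collapse_families([("miR-x", "g1")], {})
        assert net.targets("miR-x") == {"g1"}
        assert net.regulators["miR-x"].kind is RegulatorKind.MIRNA_FAMILY


class TestHostPropagation:
    def test_basic_propagation(self):
        tf_net = _tf_net({"X": {"H"}})
        edges = propagate_host_regulation(tf_net, {"pre-m": "H"}, {"pre-m": "F"})
        assert edges == {("X", "F")}

    def test_untargeted_host_produces_nothing(self):
        tf_net = _tf_net({"X": {"g1"}})
        assert propagate_host_regulation(tf_net, {"pre-m": "H"}, {"pre-m": "F"}) == set()

    def test_two_tfs_one_host_two_precursors(self):
        tf_net = _tf_net({"X": {"H"}, "Y": {"H"}})
        host_map = {"pre-1": "H", "pre-2": "H"}
        fam_map = {"pre-1": "F1", "pre-2": "F2"}
        edges = propagate_host_regulation(tf_net, host_map, fam_map)
        # hand enumeration: 2 TFs x 2 embedded families
        assert edges == {("X", "F1"), ("X", "F2"), ("Y", "F1"), ("Y", "F2")}

    def test_unknown_family_skipped(self):
        tf_net = _tf_net({"X": {"H"}})
        assert propagate_host_regulation(tf_net, {"pre-m": "H"}, {}) == set()


class TestEnumeratePairs:
    def test_cross_pair_intersection(self):
        pairs = enumerate_pairs(
            _tf_net({"TF1": {"g1", "g2", "g3"}}),
            _mir_net({"F1": {"g2", "g3", "g4"}}),
            min_shared=2,
        )
        assert len(pairs) == 1
        (p,) = pairs
        assert p.pair_kind is PairKind.TF_MIR
        assert p.shared_targets == {"g2", "g3"}

    def test_disjoint_targets_no_pair(self):
        pairs = enumerate_pairs(
            _tf_net({"TF1": {"g1"}}), _mir_net({"F1": {"g9"}}), min_shared=1
        )
        assert pairs == []

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(40)]
        tf_targets = {
            f"TF{i}": set(rng.choice(genes, size=12, replace=False)) for i in range(5)
        }
        fam_targets = {
            f"F{i}": set(rng.choice(genes, size=12, replace=False)) for i in range(5)
        }
        tf_net, mir_net = _tf_net(tf_targets), _mir_net(fam_targets)
        pairs = enumerate_pairs(tf_net, mir_net, min_shared=3)
        # brute force over every unordered regulator pair
        everything = {**tf_targets, **fam_targets}
        expected = set()
        ids = sorted(everything)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if a.startswith("TF") != b.startswith("TF") or True:
                    shared = everything[a] & everything[b]
                    if len(shared) >= 3:
                        expected.add((a, b, frozenset(shared)))
        got = {(p.reg_a, p.reg_b, p.shared_targets) for p in pairs}
        assert got == expected

    def test_symmetry_and_canonical_order(self):
        pairs = enumerate_pairs(
            _tf_net({"TFb": {"g1", "g2"}, "TFa": {"g1", "g2"}}),
            _mir_net({"F1": set()}),
            min_shared=2,
        )
        (p,) = pairs
        assert (p.reg_a, p.reg_b) == ("TFa", "TFb")

    def test_self_pair_rejected(self):
        with pytest.raises(DomainError):
            CoregulationPair.make("A", RegulatorKind.TF, "A", RegulatorKind.TF, [])


class TestMvhLoglik:
    def test_single_category_is_zero(self):
        ann = _ann_from_counts([7])
        assert mvh_loglik(_profile(ann, [4]), ann) == pytest.approx(0.0, abs=1e-12)

    def test_two_category_example(self):
        # L = ln( C(3,2) * C(2,1) / C(5,3) ) = ln 0.6
        ann = _ann_from_counts([3, 2])
        got = mvh_loglik(_profile(ann, [2, 1]), ann)
        assert got == pytest.approx(math.log(0.6), abs=1e-12)

    def test_count_above_population_names_term(self):
        ann = _ann_from_counts([3, 2])
        with pytest.raises(DomainError, match="GO:0000002"):
            mvh_loglik(_profile(ann, [1, 3]), ann)

    def test_exhaustive_small_instances_vs_exact_oracle(self):
        m_by_k = {1: [9], 2: [5, 7], 3: [5, 7, 9], 4: [5, 7, 9, 11]}
        for k, m in m_by_k.items():
            ann = _ann_from_counts(m)
            for n in range(0, 7):
                for c in compositions(n, k):
                    if any(ck > mk for ck, mk in zip(c, m)):
                        continue
                    want = float(Fraction(exact_mvh_probability(m, c)))
                    got = mvh_loglik(_profile(ann, list(c)), ann)
                    assert got == pytest.approx(math.log(want), abs=1e-12)

    def test_unannotated_pseudo_category_enters_score(self):
        ann = _ann_from_counts([3], n_unannotated=2)
        got = mvh_loglik(_profile(ann, [2], unannotated=1), ann)
        want = math.log(float(exact_mvh_probability([3, 2], [2, 1])))
        assert got == pytest.approx(want, abs=1e-12)

    def test_score_never_positive(self):
        rng = np.random.default_rng(0)
        ann = _ann_from_counts([4, 6, 8, 10])
        for _ in range(50):
            c = [int(rng.integers(0, m + 1)) for m in (4, 6, 8, 10)]
            assert mvh_loglik(_profile(ann, c), ann) <= 1e-12


class TestPermutationTest:
    def test_count_rule(self):
        assert empirical_p(-5.0, [-6.0, -4.0, -2.0]) == pytest.approx(0.5)

    def test_extreme_tail_with_pseudocount(self):
        assert empirical_p(-99.0, [-6.0, -4.0, -2.0]) == pytest.approx(1 / 4)

    def test_p_bounds(self):
        null = [-3.0, -2.0, -1.0]
        assert empirical_p(0.0, null) == 1.0
        assert empirical_p(-10.0, null) == pytest.approx(1 / 4)

    def test_set_larger_than_universe_rejected(self):
        ann = _ann_from_counts([3, 2])
        prof = FunctionalProfile(
            counts={t: 3 for t in ann.terms}, set_size=99, unannotated=0
        )
        with pytest.raises(DomainError):
            permutation_test(prof, ann, n_perm=10, rng_seed=0)

    def test_null_cache_reused_and_seed_stable(self):
        ann = _ann_from_counts([10, 12], n_unannotated=4)
        null = PermutationNull(ann, n_perm=50, seed=3)
        a = null.scores(5)
        b = null.scores(5)
        assert a is b
        c = PermutationNull(ann, n_perm=50, seed=3).scores(5)
        np.testing.assert_array_equal(a, c)

    def test_calibration_on_random_annotations(self):
        # scaled-down version of the acceptance calibration check
        rng = np.random.default_rng(42)
        terms = [f"GO:{k:07d}" for k in range(8)]
        gene_terms = {
            f"g{i:04d}": frozenset(rng.choice(terms, size=rng.integers(0, 3), replace=False))
            for i in range(400)
        }
        ann = Level2Annotation(terms, gene_terms)
        null = PermutationNull(ann, n_perm=200, seed=7)
        ps = []
        for _ in range(100):
            genes = rng.choice(ann.universe, size=15, replace=False)
            _, p = permutation_test(functional_profile(genes, ann), ann, null=null)
            ps.append(p)
        frac = np.mean(np.asarray(ps) <= 0.05)
        assert 0.0 <= frac <= 0.15  # loose band at this scale


class TestFdrAdjust:
    def test_bh_hand_worked_example(self):
        adj, reject = fdr_adjust([0.01, 0.02, 0.03, 0.04], "BH", alpha=0.05)
        assert reject.all()
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        adj, reject = fdr_adjust([1.0, 1.0, 1.0], "BH")
        assert not reject.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_bh_matches_reference_stepup(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            _, reject = fdr_adjust(p, "BH", alpha=0.05)
            assert list(reject) == bh_stepup(list(p), 0.05)

    def test_bh_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(23)
        for _ in range(50):
            p = rng.uniform(size=20)
            adj, reject = fdr_adjust(p, "BH", alpha=0.05)
            ref_rej, ref_adj, _, _ = sm.multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(adj, ref_adj, atol=1e-12)
            np.testing.assert_array_equal(reject, ref_rej)

    def test_bl_monotone_and_at_least_bonferroni(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            p = rng.uniform(size=25) ** 2
            adj, reject = fdr_adjust(p, "BL", alpha=0.05)
            order = np.argsort(p, kind="stable")
            assert (np.diff(adj[order]) >= -1e-12).all()
            bonf = p <= 0.05 / p.size
            assert reject[bonf].all()

    def test_bad_pvalue_rejected(self):
        with pytest.raises(DomainError):
            fdr_adjust([0.5, 1.2], "BH")

    def test_unknown_method(self):
        with pytest.raises(DomainError):
            fdr_adjust([0.5], "BY")


class TestFindEnrichedPairs:
    def _coherent_scenario(self):
        # universe of 60 genes over 3 terms; the pair's 6 shared targets
        # all carry term GO:0000001
        rng = np.random.default_rng(2)
        terms = ["GO:0000001", "GO:0000002", "GO:0000003"]
        gene_terms = {
            f"g{i:03d}": frozenset({terms[i % 3]}) for i in range(60)
        }
        ann = Level2Annotation(terms, gene_terms)
        shared = [f"g{i:03d}" for i in range(0, 18, 3)]  # 6 genes, all term 1
        pair = CoregulationPair.make(
            "TF1", RegulatorKind.TF, "famA", RegulatorKind.MIRNA_FAMILY, shared
        )
        return pair, ann

    def test_planted_signal_detected(self):
        pair, ann = self._coherent_scenario()
        (res,) = find_enriched_pairs([pair], ann, n_perm=1000, alpha=0.05, rng_seed=4)
        assert res.enriched
        assert res.p_perm <= 0.05
        assert res.q >= res.p_perm - 1e-15

    def test_deterministic_given_seed(self):
        pair, ann = self._coherent_scenario()
        t1 = results_to_frame(find_enriched_pairs([pair], ann, n_perm=300, rng_seed=9))
        t2 = results_to_frame(find_enriched_pairs([pair], ann, n_perm=300, rng_seed=9))
        assert t1.equals(t2)

    def test_empty_pair_list_rejected(self):
        _, ann = self._coherent_scenario()
        with pytest.raises(DomainError):
            find_enriched_pairs([], ann)
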