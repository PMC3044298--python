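import itertools

import numpy as np
import pytest

from coregnet.core_io.types import Regulator, RegulatorKind, RegulatorTargetNetwork, UpstreamNetwork
from coregnet.errors import ConfigError, DomainError
from coregnet.motif_analysis import (
    DEFAULT_CATALOG,
    UpstreamIndex,
    build_upstream_network,
    catalog_by_id,
    count_motifs,
    motif_significance,
)
from coregnet.pair_enrichment import CoregulationPair, PairKind

TF = RegulatorKind.TF
MIR = RegulatorKind.MIRNA_FAMILY


def _pair(a, b, kind_a=TF, kind_b=MIR):
    return CoregulationPair.make(a, kind_a, b, kind_b, [])


def _upstream(edges, kinds):
    up = UpstreamNetwork()
    for s, d in edges:
        up.add_edge(s, d)
    up.kinds.update(kinds)
    return up


def brute_force_counts(pairs, upstream, regulator_ids):
    """Independent motif counter: explicit loops over candidate regulators,
    written directly from the motif definitions."""
    edges = upstream.edges
    kinds = upstream.kinds
    counts = {m.motif_id: 0 for m in DEFAULT_CATALOG}
    for p in pairs:
        a, b = p.reg_a, p.reg_b
        ab = (a, b) in edges
        ba = (b, a) in edges
        if ab and ba:
            counts["FFL_BIDIR"] += 1
        if ab != ba:
            counts["FFL_UNIDIR"] += 1
        common_tf = any(
            kinds.get(x) is TF and (x, a) in edges and (x, b) in edges
            for x in regulator_ids if x not in (a, b)
        )
        common_mir = any(
            kinds.get(x) is MIR and (x, a) in edges and (x, b) in edges
            for x in regulator_ids if x not in (a, b)
        )
        if common_tf:
            counts["COMMON_UP_TF"] += 1
        if common_tf and common_mir:
            counts["COMMON_UP_TF_AND_MIR"] += 1
        crosstalk = False
        for x, y in itertools.product(regulator_ids, regulator_ids):
            if x in (a, b) or y in (a, b):
                continue
            if (x, a) in edges and (y, b) in edges:
                if x == y or (x, y) in edges or (y, x) in edges:
                    crosstalk = True
                    break
        if crosstalk:
            counts["UPSTREAM_CROSSTALK"] += 1
    return counts


class TestCountMotifs:
    def test_empty_upstream_all_zero(self):
        counts = count_motifs([_pair("A", "B")], _upstream([], {}))
        assert all(v == 0 for v in counts.values())

    def test_common_up_tf_only(self):
        up = _upstream([("X", "A"), ("X", "B")], {"X": TF, "A": TF, "B": MIR})
        counts = count_motifs([_pair("A", "B")], up)
        assert counts["COMMON_UP_TF"] == 1
        assert counts["FFL_BIDIR"] == 0 and counts["FFL_UNIDIR"] == 0
        assert counts["UPSTREAM_CROSSTALK"] == 1  # same upstream regulator

    def test_bidirectional_ffl(self):
        up = _upstream([("A", "B"), ("B", "A")], {"A": TF, "B": MIR})
        counts = count_motifs([_pair("A", "B")], up)
        assert counts["FFL_BIDIR"] == 1 and counts["FFL_UNIDIR"] == 0

    def test_unidirectional_ffl(self):
        up = _upstream([("A", "B")], {"A": TF, "B": MIR})
        counts = count_motifs([_pair("A", "B")], up)
        assert counts["FFL_UNIDIR"] == 1 and counts["FFL_BIDIR"] == 0

    def test_pair_members_not_their_own_common_regulator(self):
        # A regulates both itself?-no: A->B plus A->A would be a self-loop;
        # a pair member regulating both is excluded by the third-party rule
        up = _upstream([("A", "B")], {"A": TF, "B": MIR})
        counts = count_motifs([_pair("A", "B")], up)
        assert counts["COMMON_UP_TF"] == 0

    def test_crosstalk_via_linked_upstream(self):
        up = _upstream(
            [("X", "A"), ("Y", "B"), ("X", "Y")],
            {"X": TF, "Y": TF, "A": TF, "B": MIR},
        )
        counts = count_motifs([_pair("A", "B")], up)
        assert counts["UPSTREAM_CROSSTALK"] == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        ids = [f"R{i}" for i in range(n)]
        kinds = {r: (TF if rng.random() < 0.5 else MIR) for r in ids}
        edges = set()
        for s, d in itertools.permutations(ids, 2):
            if rng.random() < 0.08:
                edges.add((s, d))
        up = _upstream(edges, kinds)
        pairs = []
        for a, b in itertools.combinations(ids, 2):
            if rng.random() < 0.25:
                pairs.append(_pair(a, b, kinds[a], kinds[b]))
        assert count_motifs(pairs, up) == brute_force_counts(pairs, up, ids)

    def test_invariant_to_pair_and_edge_order(self):
        rng = np.random.default_rng(3)
        ids = [f"R{i}" for i in range(10)]
        kinds = {r: (TF if i % 2 else MIR) for i, r in enumerate(ids)}
        edges = [(a, b) for a, b in itertools.permutations(ids, 2) if rng.random() < 0.2]
        pairs = [_pair(a, b, kinds[a], kinds[b]) for a, b in itertools.combinations(ids, 2)]
        fwd = count_motifs(pairs, _upstream(edges, kinds))
        rev = count_motifs(pairs[::-1], _upstream(edges[::-1], kinds))
        assert fwd == rev

    def test_catalog_ids_unique(self):
        assert set(catalog_by_id()) == {
            "FFL_BIDIR", "FFL_UNIDIR", "COMMON_UP_TF",
            "COMMON_UP_TF_AND_MIR", "UPSTREAM_CROSSTALK",
        }
        with pytest.raises(ConfigError):
            catalog_by_id(list(DEFAULT_CATALOG) + [DEFAULT_CATALOG[0]])


class TestBuildUpstreamNetwork:
    def _nets(self):
        tfs = [
            Regulator(id=t, kind=TF, members=frozenset({t})) for t in ("X", "Y", "Z")
        ]
        tf_net = RegulatorTargetNetwork(tfs, [("X", "Y"), ("X", "g1"), ("Z", "g2")])
        fams = [Regulator(id="F", kind=MIR, members=frozenset({"m1"}))]
        mir_net = RegulatorTargetNetwork(fams, [("F", "Z"), ("F", "g3")])
        return tf_net, mir_net

    def test_tf_tf_edge_from_targeting(self):
        tf_net, mir_net = self._nets()
        up = build_upstream_network(tf_net, [], [], mir_net)
        assert ("X", "Y") in up.edges

    def test_family_to_tf_edge(self):
        tf_net, mir_net = self._nets()
        up = build_upstream_network(tf_net, [], [], mir_net)
        assert ("F", "Z") in up.edges

    def test_union_deduplicated_against_independent_set_union(self):
        tf_net, mir_net = self._nets()
        tf_mir = [("X", "F"), ("Y", "F")]
        host = [("X", "F")]  # duplicate of a predicted edge
        up = build_upstream_network(tf_net, tf_mir, host, mir_net)
        expected = {("X", "Y"), ("F", "Z")} | set(tf_mir) | set(host)
        assert up.edges == expected
        assert up.n_edges == len(expected)


class TestMotifSignificance:
    def _scenario(self, n_pool=60, n_fg=8, plant=True, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"T{i}" for i in range(20)] + [f"F{i}" for i in range(20)]
        kinds = {r: (TF if r.startswith("T") else MIR) for r in ids}
        kinds["XX"] = TF
        pool = []
        for a, b in itertools.combinations(ids, 2):
            pool.append(_pair(a, b, kinds[a], kinds[b]))
            if len(pool) == n_pool:
                break
        fg = pool[:n_fg]
        edges = set()
        if plant:
            for p in fg:
                edges.add(("XX", p.reg_a))
                edges.add(("XX", p.reg_b))
        return fg, pool, _upstream(edges, kinds)

    def test_observed_zero_gives_p_one(self):
        fg, pool, up = self._scenario(plant=False)
        results = motif_significance(fg, pool, up, n_resample=100, rng_seed=1)
        assert all(r.p_emp == 1.0 and r.observed == 0 for r in results)

    def test_planted_common_up_tf_floor_p(self):
        fg, pool, up = self._scenario(plant=True)
        results = {r.motif_id: r for r in motif_significance(fg, pool, up, n_resample=999, rng_seed=1)}
        # observed beats every resample: p hits the floor 1/(n_resample+1),
        # which equals alpha exactly, so the strict < rule does not flag it
        assert results["COMMON_UP_TF"].p_emp == pytest.approx(1 / 1000)
        assert not results["COMMON_UP_TF"].significant
        results = {r.motif_id: r for r in motif_significance(fg, pool, up, n_resample=1999, rng_seed=1)}
        assert results["COMMON_UP_TF"].p_emp == pytest.approx(1 / 2000)
        assert results["COMMON_UP_TF"].significant

    def test_full_background_as_foreground_p_one(self):
        fg, pool, up = self._scenario(plant=True)
        results = motif_significance(pool, pool, up, n_resample=50, rng_seed=1)
        assert all(r.p_emp == pytest.approx(1.0) for r in results)

    def test_empty_foreground_rejected(self):
        _, pool, up = self._scenario()
        with pytest.raises(DomainError):
            motif_significance([], pool, up, n_resample=10)

    def test_pool_smaller_than_foreground_rejected(self):
        fg, pool, up = self._scenario()
        with pytest.raises(DomainError):
            motif_significance(pool, fg, up, n_resample=10)

    def test_kind_restriction(self):
        fg, pool, up = self._scenario()
        results = motif_significance(
            fg, pool, up, n_resample=20, rng_seed=0, pair_kind=PairKind.TF_TF
        )
        assert all(r.pair_kind is PairKind.TF_TF for r in results)
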