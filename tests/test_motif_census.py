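"""Canonical labels, exact census vs brute force, rewiring nulls, enrichment."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from regnet import (CASCADE_LABEL, FFL_LABEL, canonical_label, census,
                    composite_ppi_motifs, motif_enrichment, rewire_null)
from regnet.motif_census import _graph_view
from regnet.network_builder import IntegratedNetwork

from conftest import random_typed_network


def census_oracle(network, size=3, signed=False):
    """Independent all-triples enumerator (O(n^k) over node combinations)."""
    typ, dir_sign, _ = _graph_view(network, signed)
    counts = {}
    for nodes in combinations(sorted(typ), size):
        edges = []
        for i, u in enumerate(nodes):
            for j, v in enumerate(nodes):
                if i != j and (u, v) in dir_sign:
                    edges.append((i, j, dir_sign[(u, v)]))
        if not edges:
            continue
        try:
            label = canonical_label([typ[n] for n in nodes], edges, signed=signed)
        except ValueError:  # disconnected
            continue
        counts[label] = counts.get(label, 0) + 1
    return counts


def _mini_net(edge_triples, types):
    nodes = dict(types)
    edges = pd.DataFrame(edge_triples, columns=["source", "target", "etype", "sign"])
    return IntegratedNetwork(nodes=nodes, edges=edges).validate()


class TestCanonicalLabel:
    def test_relabeled_subgraphs_share_a_label(self):
        a = canonical_label(["TF", "TF", "gene"], [(0, 1, 0), (1, 2, 0)])
        b = canonical_label(["TF", "gene", "TF"], [(2, 0, 0), (0, 1, 0)])
        assert a == b

    def test_ffl_and_cascade_differ(self):
        assert FFL_LABEL != CASCADE_LABEL

    def test_signed_labels_distinguish_sign_patterns(self):
        coherent = canonical_label(["TF", "TF", "gene"],
                                   [(0, 1, 1), (0, 2, 1), (1, 2, 1)], signed=True)
        other = canonical_label(["TF", "TF", "gene"],
                                [(0, 1, 1), (0, 2, 1), (1, 2, -1)], signed=True)
        assert coherent != other

    def test_unsigned_mode_ignores_signs(self):
        a = canonical_label(["TF", "gene"], [(0, 1, 1)], signed=False)
        b = canonical_label(["TF", "gene"], [(0, 1, -1)], signed=False)
        assert a == b

    def test_disconnected_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            canonical_label(["TF", "TF", "gene"], [(0, 1, 0)])


class TestCensus:
    def test_single_ffl_counts_once(self):
        net = _mini_net([("t1", "t2", "TF>TF", 0), ("t1", "g1", "TF>gene", 0),
                         ("t2", "g1", "TF>gene", 0)],
                        {"t1": "TF", "t2": "TF", "g1": "gene"})
        c = census(net)
        assert c == {FFL_LABEL: 1}

    def test_planted_disjoint_motifs_counted(self):
        rows, types = [], {}
        for i in range(4):  # 4 node-disjoint FFLs
            a, b, g = f"ta{i}", f"tb{i}", f"gf{i}"
            types.update({a: "TF", b: "TF", g: "gene"})
            rows += [(a, b, "TF>TF", 0), (a, g, "TF>gene", 0), (b, g, "TF>gene", 0)]
        for i in range(3):  # 3 node-disjoint cascades
            a, b, g = f"ca{i}", f"cb{i}", f"gc{i}"
            types.update({a: "TF", b: "TF", g: "gene"})
            rows += [(a, b, "TF>TF", 0), (b, g, "TF>gene", 0)]
        c = census(_mini_net(rows, types))
        assert c[FFL_LABEL] == 4
        assert c[CASCADE_LABEL] == 3

    def test_self_loops_not_in_triple_census(self):
        net = _mini_net([("t1", "t1", "TF>TF", 0), ("t1", "g1", "TF>gene", 0),
                         ("t2", "g1", "TF>gene", 0)],
                        {"t1": "TF", "t2": "TF", "g1": "gene"})
        c = census(net)
        assert sum(c.values()) == 1  # only the two-regulator fan-in triple

    @pytest.mark.parametrize("signed", [False, True])
    def test_matches_bruteforce_oracle(self, signed, rng):
        for _ in range(12):
            n = int(rng.integers(10, 50))
            net = random_typed_network(rng, n_nodes=n, p=0.08, signed=signed)
            assert census(net, signed=signed) == census_oracle(net, signed=signed)

    def test_triple_count_conservation(self, rng):
        """Sum over labels equals the number of connected node triples."""
        net = random_typed_network(rng, n_nodes=40, p=0.08)
        oracle = census_oracle(net)
        assert sum(census(net).values()) == sum(oracle.values())

    def test_two_node_census_matches_oracle(self, rng):
        net = random_typed_network(rng, n_nodes=30, p=0.1, signed=True)
        assert census(net, size=2, signed=True) == \
            census_oracle(net, size=2, signed=True)

    def test_signed_census_drops_sign_zero_edges(self):
        net = _mini_net([("t1", "g1", "TF>gene", 0), ("m1", "g1", "miRNA>gene", -1),
                         ("m1", "t1", "miRNA>TF", -1)],
                        {"t1": "TF", "g1": "gene", "m1": "miRNA"})
        unsigned = census(net)
        signed = census(net, signed=True)
        assert sum(unsigned.values()) == 1
        assert sum(signed.values()) == 1  # m1's two edges remain, t1 edge dropped


def _stratified_degrees(net, signed=False):
    out = {}
    cols = ["etype", "sign"] if signed else ["etype"]
    for key, sub in net.edges.groupby(cols):
        out[key] = (sub.groupby("source").size().to_dict(),
                    sub.groupby("target").size().to_dict())
    return out


class TestRewireNull:
    def test_preserves_stratified_degrees(self, small_network):
        base = _stratified_degrees(small_network)
        null = rewire_null(small_network, q=20, seed=1)
        assert _stratified_degrees(null) == base

    def test_signed_rewire_preserves_signed_degrees(self, rng):
        net = random_typed_network(rng, n_nodes=60, p=0.1, signed=True)
        base = _stratified_degrees(net, signed=True)
        null = rewire_null(net, q=20, seed=2, signed=True)
        assert _stratified_degrees(null, signed=True) == base

    def test_no_duplicates_or_new_self_loops(self, small_network):
        null = rewire_null(small_network, q=20, seed=3)
        assert not null.edges.duplicated(["source", "target", "etype"]).any()
        loops = null.edges[null.edges.source == null.edges.target]
        assert (loops.etype == "TF>TF").all()

    def test_same_seed_same_network(self, small_network):
        a = rewire_null(small_network, q=10, seed=9)
        b = rewire_null(small_network, q=10, seed=9)
        pd.testing.assert_frame_equal(a.edges, b.edges)

    def test_tiny_stratum_left_unrewired(self):
        net = _mini_net([("t1", "g1", "TF>gene", 0), ("m1", "g2", "miRNA>gene", -1),
                         ("m1", "g1", "miRNA>gene", -1)],
                        {"t1": "TF", "g1": "gene", "g2": "gene", "m1": "miRNA"})
        null = rewire_null(net, q=10, seed=0)
        tf_rows = null.edges[null.edges.etype == "TF>gene"]
        assert list(zip(tf_rows.source, tf_rows.target)) == [("t1", "g1")]

    def test_randomization_mixes_edges(self, small_network, rng):
        """Overlap with the original drops as the swap budget grows."""
        e0 = set(map(tuple, small_network.edges[["source", "target"]].values))
        overlaps = []
        for q in (1, 100):
            ovl = []
            for s in range(5):
                null = rewire_null(small_network, q=q, seed=100 + s)
                e1 = set(map(tuple, null.edges[["source", "target"]].values))
                ovl.append(len(e0 & e1) / len(e0))
            overlaps.append(np.mean(ovl))
        assert overlaps[1] < overlaps[0]


class TestEnrichment:
    def test_sigma_zero_flagged(self):
        net = _mini_net([("t1", "g1", "TF>gene", 0), ("t1", "g2", "TF>gene", 0)],
                        {"t1": "TF", "g1": "gene", "g2": "gene"})
        # only one fan-out triple exists and rewiring cannot change it
        enr = motif_enrichment(net, n_null=20, q=10, seed=0)
        assert len(enr) == 1
        m = enr[0]
        assert np.isnan(m.z) and m.p_empirical == 1.0

    def test_empirical_p_never_zero(self, rng):
        net = random_typed_network(rng, n_nodes=30, p=0.1)
        enr = motif_enrichment(net, n_null=10, q=10, seed=1)
        assert all(0 < m.p_empirical <= 1 for m in enr)


class TestCompositeMotifs:
    def test_comirna_ppi_incidence_counted(self):
        net = _mini_net([("m1", "g1", "miRNA>gene", -1), ("m1", "g2", "miRNA>gene", -1),
                         ("m2", "g3", "miRNA>gene", -1), ("m2", "g1", "miRNA>gene", -1)],
                        {"m1": "miRNA", "m2": "miRNA",
                         "g1": "gene", "g2": "gene", "g3": "gene"})
        net.ppi = pd.DataFrame([("g1", "g2")], columns=["source", "target"])
        rep = composite_ppi_motifs(net, n_null=20, q=10, seed=0)
        assert rep.ppi_comirna_count == 1

    def test_one_way_tf_mirna_is_not_a_loop(self):
        net = _mini_net([("t1", "m1", "TF>miRNA", 1), ("t2", "m2", "TF>miRNA", 1),
                         ("m2", "t2", "miRNA>TF", -1), ("m1", "t2", "miRNA>TF", -1)],
                        {"t1": "TF", "t2": "TF", "m1": "miRNA", "m2": "miRNA"})
        rep = composite_ppi_motifs(net, n_null=20, q=10, seed=0)
        assert rep.feedback_loop_count == 1  # only t2<->m2 reciprocates

    def test_autoregulation_split_by_sign(self):
        net = _mini_net([("t1", "t1", "TF>TF", 1), ("t2", "t2", "TF>TF", -1),
                         ("t1", "t2", "TF>TF", 1), ("t2", "g", "TF>gene", -1)],
                        {"t1": "TF", "t2": "TF", "g": "gene"})
        rep = composite_ppi_motifs(net, n_null=20, q=10, seed=0)
        assert rep.autoregulation_count == 2
        assert rep.par_tfs == ("t1",) and rep.nar_tfs == ("t2",)

    def test_no_ppi_skips_cotargeting(self):
        net = _mini_net([("m1", "g1", "miRNA>gene", -1), ("m1", "g2", "miRNA>gene", -1)],
                        {"m1": "miRNA", "g1": "gene", "g2": "gene"})
        rep = composite_ppi_motifs(net, n_null=10, q=10, seed=0)
        assert rep.ppi_comirna_count is None and rep.ppi_comirna_p is None
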