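"""Conservation filtering, network assembly and topology statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from regnet import (assemble_network, degree_statistics, filter_conserved_sites,
                    read_annotation, target_overlap_matrix)
from regnet.io_formats import MiRNASiteTable
from regnet.network_builder import IntegratedNetwork
from regnet.synthetic import SPECIES

ANN = """\
chrI\ts\tgene\t1001\t4000\t.\t+\t.\tID=gA
chrI\ts\tmRNA\t1001\t4000\t.\t+\t.\tID=gA.t1;Parent=gA
chrI\ts\tthree_prime_UTR\t3801\t4000\t.\t+\t.\tParent=gA.t1
chrI\ts\tmRNA\t1301\t4000\t.\t+\t.\tID=gA.t2;Parent=gA
chrI\ts\tthree_prime_UTR\t3801\t4000\t.\t+\t.\tParent=gA.t2
chrI\ts\tgene\t10001\t13000\t.\t+\t.\tID=gB;is_tf=1
chrI\ts\tmRNA\t10001\t13000\t.\t+\t.\tID=gB.t1;Parent=gB
chrI\ts\tthree_prime_UTR\t12801\t13000\t.\t+\t.\tParent=gB.t1
chrI\ts\tgene\t20001\t23000\t.\t+\t.\tID=gC
chrI\ts\tmRNA\t20001\t23000\t.\t+\t.\tID=gC.t1;Parent=gC
chrI\ts\tpre_miRNA\t30001\t30080\t.\t+\t.\tID=mir-1
"""


@pytest.fixture
def ann():
    return read_annotation(ANN)


def _sites(rows):
    cols = ["mirna_id", "transcript_id", "chrom", "start", "end", *SPECIES]
    return MiRNASiteTable(species=SPECIES, sites=pd.DataFrame(rows, columns=cols))


class TestConservationFilter:
    def test_five_way_site_passes_both_modes(self, ann):
        t = _sites([["mir-1", "gA.t1", "chrI", 3810, 3817, 1, 1, 1, 1, 1]])
        assert filter_conserved_sites(t, ann, 3) == [("mir-1", "gA")]
        assert filter_conserved_sites(t, ann, 5) == [("mir-1", "gA")]

    def test_two_species_site_never_passes(self, ann):
        t = _sites([["mir-1", "gA.t1", "chrI", 3810, 3817, 1, 1, 0, 0, 0]])
        assert filter_conserved_sites(t, ann, 3) == []
        assert filter_conserved_sites(t, ann, 5) == []

    def test_three_way_site_fails_strict_mode(self, ann):
        t = _sites([["mir-1", "gA.t1", "chrI", 3810, 3817, 1, 1, 1, 0, 0]])
        assert filter_conserved_sites(t, ann, 3) == [("mir-1", "gA")]
        assert filter_conserved_sites(t, ann, 5) == []

    def test_site_on_second_transcript_suffices(self, ann):
        t = _sites([["mir-1", "gA.t2", "chrI", 3810, 3817, 1, 1, 1, 1, 1]])
        assert filter_conserved_sites(t, ann, 3) == [("mir-1", "gA")]

    def test_invalid_mode_rejected(self, ann):
        with pytest.raises(ValueError):
            filter_conserved_sites(_sites([]), ann, 4)


class TestAssembleNetwork:
    def test_gene_without_utr_excluded(self, ann):
        net = assemble_network([("gB", "gC", "gene"), ("gB", "gA", "gene")],
                               [], None, ann)
        assert "gC" not in net.nodes
        assert set(net.edges.target) == {"gA"}

    def test_tf_self_loop_retained(self, ann):
        net = assemble_network([("gB", "gB", "gene")], [], None, ann)
        assert len(net.edges) == 1
        assert net.edges.iloc[0].etype == "TF>TF"

    def test_tf_target_typed_as_tf_tf(self, ann):
        net = assemble_network([("gB", "gA", "gene")], [("mir-1", "gB")], None, ann)
        assert set(net.edges.etype) == {"TF>gene", "miRNA>TF"}

    def test_empty_mirna_edges_ok(self, ann):
        net = assemble_network([("gB", "gA", "gene")], [], None, ann)
        assert net.nodes["mir-1"] == "miRNA"
        assert (net.edges.etype != "miRNA>gene").all()

    def test_unknown_id_raises(self, ann):
        with pytest.raises(ValueError, match="gZ"):
            assemble_network([("gB", "gZ", "gene")], [], None, ann)

    def test_universe_filter_idempotent(self, small_bundle):
        from regnet import build_network_from_bundle

        net, _ = build_network_from_bundle(small_bundle)
        again = assemble_network(
            [(s, t, "mirna" if net.nodes[t] == "miRNA" else "gene")
             for s, t in zip(net.edges[net.edges.etype.str.startswith("TF")].source,
                             net.edges[net.edges.etype.str.startswith("TF")].target)],
            [(s, t) for s, t in
             zip(net.edges[net.edges.etype.str.startswith("miRNA")].source,
                 net.edges[net.edges.etype.str.startswith("miRNA")].target)],
            small_bundle.ppi, small_bundle.annotation)
        assert len(again.edges) == len(net.edges)


class TestDegreeStatistics:
    def test_exact_exponential_histogram(self):
        # network whose tfs-per-gene histogram is exactly exp(-0.5 k);
        # the 10 TF nodes themselves sit in the degree-0 bin
        nodes = {"m0": "miRNA"}
        rows = []
        gi = 0
        counts = {k: int(round(1000 * math.exp(-0.5 * k))) for k in range(0, 9)}
        tfs = [f"t{i}" for i in range(10)]
        for t in tfs:
            nodes[t] = "TF"
        counts[0] -= len(tfs)
        for k, n in counts.items():
            for _ in range(n):
                g = f"g{gi}"
                gi += 1
                nodes[g] = "gene"
                for t in tfs[:k]:
                    rows.append((t, g, "TF>gene", 0))
        edges = pd.DataFrame(rows, columns=["source", "target", "etype", "sign"])
        net = IntegratedNetwork(nodes=nodes, edges=edges)
        rep = degree_statistics(net)
        fit = rep.fits["tfs_per_gene"]
        assert fit.rate == pytest.approx(0.5, rel=0.02)
        assert fit.r_squared > 0.999

    def test_degenerate_fit_flagged(self):
        nodes = {"t0": "TF", "g0": "gene", "g1": "gene"}
        edges = pd.DataFrame([("t0", "g0", "TF>gene", 0), ("t0", "g1", "TF>gene", 0)],
                             columns=["source", "target", "etype", "sign"])
        rep = degree_statistics(IntegratedNetwork(nodes=nodes, edges=edges))
        assert rep.fits["tfs_per_gene"] is None

    def test_ppi_not_counted_in_regulatory_degrees(self, small_network):
        rep = degree_statistics(small_network)
        total = sum(k * v for k, v in rep.histograms["tfs_per_gene"].items())
        expect = len(small_network.edges[
            small_network.edges.etype.isin(["TF>gene", "TF>TF"])])
        assert total == expect


class TestTargetOverlap:
    def _net(self, targets_a, targets_b, universe_size=8):
        # target universe = genes + the 2 TF nodes (TFs are genes too)
        nodes = {"ta": "TF", "tb": "TF"}
        genes = [f"g{i}" for i in range(universe_size)]
        rows = []
        for g in genes:
            nodes[g] = "gene"
        for g in targets_a:
            rows.append(("ta", g, "TF>gene", 0))
        for g in targets_b:
            rows.append(("tb", g, "TF>gene", 0))
        edges = pd.DataFrame(rows, columns=["source", "target", "etype", "sign"])
        return IntegratedNetwork(nodes=nodes, edges=edges)

    def test_exhaustive_oracle_small_universe(self):
        # |A|=5, |B|=4, overlap 4 in a universe of 10: p = 5/210
        net = self._net([f"g{i}" for i in range(5)], [f"g{i}" for i in range(4)])
        df = target_overlap_matrix(net, "tf-tf")
        assert len(df) == 1  # self pairs excluded
        assert df.iloc[0].p == pytest.approx(5 / 210, rel=1e-9)

    def test_disjoint_targets_p_one(self):
        net = self._net(["g0", "g1"], ["g5", "g6"])
        assert target_overlap_matrix(net, "tf-tf").iloc[0].p == 1.0

    def test_zero_target_regulator_flagged(self):
        net = self._net(["g0"], [])
        net.edges = pd.concat([net.edges, pd.DataFrame(
            [("tb", "m0", "TF>miRNA", 0)], columns=net.edges.columns)],
            ignore_index=True)
        net.nodes["m0"] = "miRNA"
        df = target_overlap_matrix(net, "tf-tf", target_type="gene")
        assert bool(df.iloc[0].zero_target_flag)
        assert df.iloc[0].p == 1.0
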