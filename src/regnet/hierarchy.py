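"""Three-layer TF hierarchy and the four interleaved miRNA layers.

The core hierarchy is built from TF→TF edges alone (self-loops are
ignored: auto-regulation says nothing about rank among *other* TFs):
TFs regulated by no other TF sit at the top; of the rest, those that
regulate no other TF sit at the bottom; everything else — regulating
at least one other TF and regulated by at least one — is the middle.
miRNAs are then slotted in by sequential set difference: those
regulating a top TF go above the top layer, then (of the remainder)
those regulating a middle TF, then a bottom TF, and miRNAs with only
incoming edges fall to the lowest layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .stats import kruskal, ranksum

logger = logging.getLogger("regnet")

TF_LAYERS = ("top", "middle", "bottom")


@dataclass
class HierarchyAssignment:
    tf_layers: dict[str, str]
    mirna_layers: dict[str, int] = field(default_factory=dict)
    universe: tuple[str, ...] = ()

    def tfs_in(self, layer: str) -> list[str]:
        return sorted(t for t, l in self.tf_layers.items() if l == layer)

    def mirnas_in(self, layer: int) -> list[str]:
        return sorted(m for m, l in self.mirna_layers.items() if l == layer)


def build_core_hierarchy(tf_edges, universe=None) -> HierarchyAssignment:
    """Assign every TF in the universe to top/middle/bottom.

    ``tf_edges`` is an iterable of (source_tf, target_tf) pairs;
    ``universe`` defaults to all endpoints.  Self-loops are ignored.
    A TF that neither regulates nor is regulated by another TF is
    unregulated, so it goes to the top.
    """
    edges = [(s, t) for s, t in tf_edges if s != t]
    if universe is None:
        universe = sorted({x for e in tf_edges for x in e})
    universe = list(universe)
    uset = set(universe)
    regulated = {t for s, t in edges if s in uset and t in uset}
    regulates = {s for s, t in edges if s in uset and t in uset}
    layers = {}
    for tf in universe:
        if tf not in regulated:
            layers[tf] = "top"
        elif tf not in regulates:
            layers[tf] = "bottom"
        else:
            layers[tf] = "middle"
    return HierarchyAssignment(tf_layers=layers, universe=tuple(universe))


def place_mirnas(core: HierarchyAssignment, mirna_tf_edges,
                 all_mirnas=None) -> HierarchyAssignment:
    """Add the four miRNA layers to a built TF core.

    ``mirna_tf_edges`` is an iterable of (mirna_id, tf_id); layer 1 sits
    above the top TFs, layer 4 below everything.  Assignment order gives
    the top layer priority: a miRNA regulating both a top and a bottom
    TF lands in layer 1.
    """
    targets: dict[str, set] = {}
    for m, t in mirna_tf_edges:
        targets.setdefault(m, set()).add(t)
    if all_mirnas is None:
        all_mirnas = sorted(targets)
    tops = set(core.tfs_in("top"))
    mids = set(core.tfs_in("middle"))
    bots = set(core.tfs_in("bottom"))
    layers = {}
    for m in all_mirnas:
        ts = targets.get(m, set())
        if ts & tops:
            layers[m] = 1
        elif ts & mids:
            layers[m] = 2
        elif ts & bots:
            layers[m] = 3
        else:
            layers[m] = 4
    return HierarchyAssignment(tf_layers=dict(core.tf_layers),
                               mirna_layers=layers, universe=core.universe)


@dataclass
class LayerReport:
    """Per-layer property means and cross-layer tests."""

    layer_sizes: dict[str, int]
    means: dict[str, dict[str, float]]          # property -> layer -> mean
    kruskal_p: dict[str, float]                 # property -> p (NaN if skipped)
    pairwise_p: dict[str, dict[tuple, float]]   # property -> (layerA, layerB) -> p
    essential_counts: dict[str, tuple[int, int]]  # layer -> (essential, total)
    essential_fisher_p: float                   # bottom-vs-top enrichment


def layer_property_report(hierarchy: HierarchyAssignment, network=None,
                          ppi_edges=None, tsps_scores: dict | None = None,
                          essentiality: dict | None = None) -> LayerReport:
    """Compare TF properties across the three hierarchy layers.

    Properties: PPI degree, number of regulatory miRNAs, tissue
    specificity, essentiality.  Means are over TFs with a value;
    Kruskal-Wallis across layers and pairwise two-sided rank-sum tests
    are run when every layer has >= 2 values, otherwise skipped with a
    flag (NaN).  Essentiality gets per-layer counts and a bottom-vs-top
    Fisher exact test.
    """
    from scipy.stats import fisher_exact

    by_layer = {l: hierarchy.tfs_in(l) for l in TF_LAYERS}
    props: dict[str, dict[str, float]] = {}
    if ppi_edges is not None and len(ppi_edges):
        deg: dict[str, int] = {}
        for _, e in ppi_edges.iterrows():
            deg[e.source] = deg.get(e.source, 0) + 1
            deg[e.target] = deg.get(e.target, 0) + 1
        props["ppi_degree"] = {tf: float(deg.get(tf, 0)) for tf in hierarchy.tf_layers}
    if network is not None:
        sub = network.edges[network.edges.etype == "miRNA>TF"]
        counts = sub.groupby("target").size()
        props["n_regulatory_mirnas"] = {tf: float(counts.get(tf, 0))
                                        for tf in hierarchy.tf_layers}
    if tsps_scores:
        props["tsps"] = {tf: float(v) for tf, v in tsps_scores.items()
                         if tf in hierarchy.tf_layers}

    means: dict[str, dict[str, float]] = {}
    kw: dict[str, float] = {}
    pairwise: dict[str, dict[tuple, float]] = {}
    for name, values in props.items():
        groups = {l: [values[tf] for tf in tfs if tf in values]
                  for l, tfs in by_layer.items()}
        means[name] = {l: (float(np.mean(g)) if g else float("nan"))
                       for l, g in groups.items()}
        nonempty = [g for g in groups.values() if g]
        if len(nonempty) < len([l for l in TF_LAYERS if by_layer[l]]) or \
                any(len(g) < 2 for g in nonempty) or len(nonempty) < 2:
            logger.info("layer report: tests skipped for %s (insufficient data)", name)
            kw[name] = float("nan")
            pairwise[name] = {}
            continue
        kw[name] = kruskal(nonempty)
        pw = {}
        layers_present = [l for l in TF_LAYERS if len(groups[l]) >= 2]
        for i, la in enumerate(layers_present):
            for lb in layers_present[i + 1:]:
                pw[(la, lb)] = ranksum(groups[la], groups[lb])
        pairwise[name] = pw

    ess_counts: dict[str, tuple[int, int]] = {}
    fisher_p = float("nan")
    if essentiality:
        for l, tfs in by_layer.items():
            known = [tf for tf in tfs if tf in essentiality]
            ess_counts[l] = (sum(essentiality[tf] for tf in known), len(known))
        eb, nb = ess_counts.get("bottom", (0, 0))
        et, nt = ess_counts.get("top", (0, 0))
        if nb and nt:
            table = [[eb, nb - eb], [et, nt - et]]
            fisher_p = float(fisher_exact(table, alternative="greater")[1])
    return LayerReport(layer_sizes={l: len(t) for l, t in by_layer.items()},
                       means=means, kruskal_p=kw, pairwise_p=pairwise,
                       essential_counts=ess_counts, essential_fisher_p=fisher_p)
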