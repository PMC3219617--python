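"""Integrated-network assembly, conservation filtering and topology stats.

The integrated network joins three directed regulatory layers —
TF→gene (incl. TF→TF), TF→miRNA and miRNA→gene/TF — over the gene
universe for which both TF binding data and miRNA site predictions
exist, plus an undirected protein-protein interaction scaffold that is
never counted in regulatory degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import GenomeAnnotation, MiRNASiteTable
from .stats import ExponentialFit, bh_adjust, fit_exponential, hypergeom_upper_tail

logger = logging.getLogger("regnet")

REG_ETYPES = ("TF>gene", "TF>TF", "TF>miRNA", "miRNA>gene", "miRNA>TF")


@dataclass
class IntegratedNetwork:
    """Typed nodes and signed directed regulatory edges plus PPI edges.

    ``nodes`` maps id -> {'TF', 'gene', 'miRNA'}; ``edges`` has columns
    source, target, etype, sign; ``ppi`` has columns source, target
    (undirected, no regulatory meaning).
    """

    nodes: dict[str, str]
    edges: pd.DataFrame
    ppi: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["source", "target"]))

    def validate(self) -> "IntegratedNetwork":
        expect = {"TF>gene": ("TF", "gene"), "TF>TF": ("TF", "TF"),
                  "TF>miRNA": ("TF", "miRNA"), "miRNA>gene": ("miRNA", "gene"),
                  "miRNA>TF": ("miRNA", "TF")}
        for _, e in self.edges.iterrows():
            st, tt = expect[e.etype]
            if self.nodes.get(e.source) != st or self.nodes.get(e.target) != tt:
                raise ValueError(f"edge {e.source}->{e.target} typed {e.etype} but nodes "
                                 f"are {self.nodes.get(e.source)}/{self.nodes.get(e.target)}")
            if e.source == e.target and e.etype != "TF>TF":
                raise ValueError(f"self-loop only allowed as TF>TF: {e.source}")
        dup = self.edges.duplicated(subset=["source", "target", "etype"])
        if dup.any():
            raise ValueError(f"{int(dup.sum())} duplicate edges")
        return self

    def nodes_of_type(self, t: str) -> list[str]:
        return sorted(n for n, nt in self.nodes.items() if nt == t)

    def edges_of_type(self, *etypes: str) -> pd.DataFrame:
        return self.edges[self.edges.etype.isin(etypes)]

    def copy(self) -> "IntegratedNetwork":
        return IntegratedNetwork(dict(self.nodes), self.edges.copy(), self.ppi.copy())


def filter_conserved_sites(sites: MiRNASiteTable, annotation: GenomeAnnotation,
                           min_species: int = 3) -> list[tuple[str, str]]:
    """Gene-level miRNA targets supported by conserved seed sites.

    A site passes when its conservation flags cover the named species
    set — the first 3 species of the table (3-way, default) or all 5
    (strict).  A gene becomes a target of a miRNA if at least one
    transcript of the gene carries at least one passing site.  Returns
    deduplicated (mirna_id, gene_id) pairs.
    """
    if min_species not in (3, 5):
        raise ValueError("min_species must be 3 or 5")
    if len(sites.species) < min_species:
        raise ValueError(f"site table has {len(sites.species)} species, "
                         f"need >= {min_species}")
    required = list(sites.species[:min_species])
    df = sites.sites
    ok = df[required].all(axis=1)
    tx2gene = annotation.gene_of_transcript()
    pairs = {(m, tx2gene[t]) for m, t in
             zip(df.loc[ok, "mirna_id"], df.loc[ok, "transcript_id"])
             if t in tx2gene}
    return sorted(pairs)


def assemble_network(tf_edges: list[tuple[str, str, str]],
                     mirna_edges: list[tuple[str, str]],
                     ppi_edges: pd.DataFrame | None,
                     annotation: GenomeAnnotation) -> IntegratedNetwork:
    """Join the regulatory layers over the eligible gene universe.

    ``tf_edges`` are (tf_id, target_id, target_type in {gene, mirna})
    from peak calling; ``mirna_edges`` are (mirna_id, gene_id) from the
    conservation filter.  The gene universe is restricted to genes with
    an annotated TSS *and* at least one annotated 3′UTR (the site
    prediction input universe); edges touching excluded genes are
    dropped with logged counts.  Gene targets flagged ``is_tf`` yield
    TF>TF / miRNA>TF typed edges.
    """
    has_utr = {g for g, sub in annotation.transcripts.groupby("gene_id")
               if any(len(u) for u in sub["utr3"])}
    universe = [g for g in annotation.genes.index if g in has_utr]
    excluded = set(annotation.genes.index) - set(universe)
    is_tf = dict(annotation.genes["is_tf"])
    nodes: dict[str, str] = {}
    for g in universe:
        nodes[g] = "TF" if is_tf.get(g, False) else "gene"
    for m in annotation.mirnas.index:
        nodes[m] = "miRNA"

    known = set(annotation.genes.index) | set(annotation.mirnas.index)
    bad = sorted({x for tf, tgt, _ in tf_edges for x in (tf, tgt) if x not in known} |
                 {x for m, g in mirna_edges for x in (m, g) if x not in known})
    if bad:
        raise ValueError(f"edges reference unknown ids: {bad[:10]}")

    rows, dropped = [], 0
    for tf, tgt, ttype in tf_edges:
        if nodes.get(tf) != "TF":
            dropped += 1  # assayed TF itself outside universe
            continue
        if ttype == "mirna":
            rows.append((tf, tgt, "TF>miRNA"))
        elif tgt in nodes:
            rows.append((tf, tgt, "TF>TF" if nodes[tgt] == "TF" else "TF>gene"))
        else:
            dropped += 1
    for m, g in mirna_edges:
        if g in nodes:
            rows.append((m, g, "miRNA>TF" if nodes[g] == "TF" else "miRNA>gene"))
        else:
            dropped += 1
    if dropped:
        logger.info("assemble_network: dropped %d edges outside the gene universe", dropped)
    edges = pd.DataFrame(rows, columns=["source", "target", "etype"]).drop_duplicates()
    edges["sign"] = 0
    edges = edges.sort_values(["etype", "source", "target"]).reset_index(drop=True)

    if ppi_edges is not None and len(ppi_edges):
        pp = ppi_edges[ppi_edges["source"].isin(nodes) & ppi_edges["target"].isin(nodes)]
        canon = pd.DataFrame({
            "source": np.minimum(pp["source"], pp["target"]),
            "target": np.maximum(pp["source"], pp["target"])}).drop_duplicates()
        canon = canon[canon.source != canon.target].reset_index(drop=True)
    else:
        canon = pd.DataFrame(columns=["source", "target"])
    return IntegratedNetwork(nodes=nodes, edges=edges, ppi=canon).validate()


# ---------------------------------------------------------------------------
# Topology statistics
# ---------------------------------------------------------------------------

@dataclass
class DegreeReport:
    """Degree histograms with exponential fits and the miRNA in/out link."""

    histograms: dict[str, dict[int, int]]
    fits: dict[str, ExponentialFit | None]
    mirna_inout_r: float
    mirna_inout_p: float


def _hist(values) -> dict[int, int]:
    out: dict[int, int] = {}
    for v in values:
        out[v] = out.get(v, 0) + 1
    return dict(sorted(out.items()))


def degree_statistics(network: IntegratedNetwork) -> DegreeReport:
    """Regulatory degree distributions by node class.

    Four histograms: regulatory TFs per gene, regulatory TFs per miRNA,
    regulatory miRNAs per gene, and targets per miRNA; each fitted by
    least squares of ln(count) vs degree (count ∝ exp(−λk)).  PPI edges
    are excluded.  Also reports the Pearson correlation between miRNA
    in-degree (regulatory TFs) and out-degree (targets).
    """
    if not len(network.edges):
        raise ValueError("degree_statistics needs a non-empty network")
    genes = [n for n, t in network.nodes.items() if t in ("gene", "TF")]
    mirnas = network.nodes_of_type("miRNA")
    e = network.edges

    def indeg(targets, sub):
        c = sub.groupby("target").size()
        return [int(c.get(n, 0)) for n in targets]

    def outdeg(sources, sub):
        c = sub.groupby("source").size()
        return [int(c.get(n, 0)) for n in sources]

    tf_per_gene = indeg(genes, e[e.etype.isin(["TF>gene", "TF>TF"])])
    tf_per_mirna = indeg(mirnas, e[e.etype == "TF>miRNA"])
    mirna_per_gene = indeg(genes, e[e.etype.isin(["miRNA>gene", "miRNA>TF"])])
    targets_per_mirna = outdeg(mirnas, e[e.etype.isin(["miRNA>gene", "miRNA>TF"])])

    hists = {"tfs_per_gene": _hist(tf_per_gene),
             "tfs_per_mirna": _hist(tf_per_mirna),
             "mirnas_per_gene": _hist(mirna_per_gene),
             "targets_per_mirna": _hist(targets_per_mirna)}
    fits = {}
    for name, h in hists.items():
        fit = fit_exponential(h)
        if fit is None:
            logger.info("degree fit skipped for %s: <3 occupied degrees", name)
        fits[name] = fit
    if len(mirnas) >= 3 and (np.std(tf_per_mirna) > 0 and np.std(targets_per_mirna) > 0):
        r, p = sps.pearsonr(tf_per_mirna, targets_per_mirna)
    else:
        r, p = float("nan"), float("nan")
    return DegreeReport(histograms=hists, fits=fits,
                        mirna_inout_r=float(r), mirna_inout_p=float(p))


def target_overlap_matrix(network: IntegratedNetwork, class_pair: str = "tf-mirna",
                          target_type: str = "gene") -> pd.DataFrame:
    """Shared-target enrichment for regulator pairs (hypergeometric).

    For every unordered pair of regulators of the requested classes
    ('tf-tf', 'tf-mirna' or 'mirna-mirna'), tests whether their target
    sets (restricted to ``target_type``) overlap more than expected by
    chance within the network's target universe: an upper-tail
    hypergeometric p with Benjamini-Hochberg q-values across the matrix.
    Self pairs are excluded; a regulator with 0 targets yields p = 1.
    """
    if class_pair not in ("tf-tf", "tf-mirna", "mirna-mirna"):
        raise ValueError(f"unknown class_pair {class_pair!r}")
    if target_type == "gene":
        universe = [n for n, t in network.nodes.items() if t in ("gene", "TF")]
        sub = network.edges[network.edges.target.isin(universe)]
    elif target_type == "mirna":
        universe = network.nodes_of_type("miRNA")
        sub = network.edges[network.edges.etype == "TF>miRNA"]
    else:
        raise ValueError(f"unknown target_type {target_type!r}")
    targets: dict[str, set] = {}
    for _, e in sub.iterrows():
        targets.setdefault(e.source, set()).add(e.target)
    # regulators = nodes of the class with any outgoing regulatory edge;
    # those whose edges all fell outside the target_type get 0 targets (flagged)
    active_tfs = sorted({s for s in network.edges.source if network.nodes[s] == "TF"})
    active_mirnas = sorted({s for s in network.edges.source
                            if network.nodes[s] == "miRNA"})
    a_side, b_side = {
        "tf-tf": (active_tfs, active_tfs),
        "tf-mirna": (active_tfs, active_mirnas),
        "mirna-mirna": (active_mirnas, active_mirnas),
    }[class_pair]
    if len(a_side) < 1 or len(b_side) < 1:
        raise ValueError("need regulators on both sides")
    n_universe = len(universe)
    rows = []
    seen = set()
    for a in a_side:
        for b in b_side:
            if a == b:
                continue
            key = (a, b) if class_pair == "tf-mirna" else tuple(sorted((a, b)))
            if key in seen:
                continue
            seen.add(key)
            ta = targets.get(a, set())
            tb = targets.get(b, set())
            ov = len(ta & tb)
            flagged = (len(ta) == 0 or len(tb) == 0)
            p = 1.0 if flagged else hypergeom_upper_tail(ov, len(ta), len(tb), n_universe)
            rows.append((a, b, len(ta), len(tb), ov, p, flagged))
    df = pd.DataFrame(rows, columns=["regulator_a", "regulator_b", "n_targets_a",
                                     "n_targets_b", "overlap", "p", "zero_target_flag"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values("p").reset_index(drop=True)


def network_summary(network: IntegratedNetwork) -> dict:
    """Node and edge counts by type plus mean regulators per target."""
    counts = network.edges.groupby("etype").size().to_dict()
    node_counts = {}
    for t in ("TF", "gene", "miRNA"):
        node_counts[t] = len(network.nodes_of_type(t))
    genes = [n for n, t in network.nodes.items() if t in ("gene", "TF")]
    reg = network.edges[network.edges.target.isin(genes)]
    mean_regs = len(reg) / len(genes) if genes else 0.0
    return {"nodes": node_counts, "edges": {k: int(v) for k, v in counts.items()},
            "n_ppi": int(len(network.ppi)),
            "mean_regulators_per_gene": mean_regs}
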