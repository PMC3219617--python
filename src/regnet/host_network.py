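"""Intronic miRNA / host-gene pairs and the miRNA-host network.

A pre-miRNA is intronic in a gene when its locus lies wholly inside the
gene span without touching any exon of any transcript of that gene —
i.e. it sits in intronic sequence under every isoform.  Sense-embedded
miRNAs (same strand as the host) are presumed co-transcribed with the
host; the miRNA-host network connects miRNA m_a to the host gene of
m_b whenever that host is a predicted target of m_a, including the
auto-regulatory case a = b.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io_formats import GenomeAnnotation
from .stats import binomial_upper_tail

logger = logging.getLogger("regnet")


@dataclass(frozen=True)
class HostPair:
    mirna_id: str
    host_gene_id: str
    orientation: str  # 'sense' | 'antisense'
    ambiguous: bool = False  # miRNA contained in more than one gene


def find_host_pairs(annotation: GenomeAnnotation) -> list[HostPair]:
    """All intronic miRNA/host-gene containments with orientation.

    A miRNA inside more than one gene is reported once per containment,
    flagged ambiguous.
    """
    pairs: list[HostPair] = []
    genes = annotation.genes
    tx_by_gene: dict[str, list] = {}
    for tid, t in annotation.transcripts.iterrows():
        tx_by_gene.setdefault(t.gene_id, []).append(t)
    for mid, m in annotation.mirnas.iterrows():
        hosts = []
        cand = genes[(genes.chrom == m.chrom) & (genes.start <= m.start)
                     & (genes.end >= m.end)]
        for gid, g in cand.iterrows():
            hits_exon = any(
                s < m.end and m.start < e
                for t in tx_by_gene.get(gid, ())
                for s, e in t.exons)
            if not hits_exon:
                hosts.append(gid)
        ambiguous = len(hosts) > 1
        if ambiguous:
            logger.info("miRNA %s intronic in %d genes (ambiguous)", mid, len(hosts))
        for gid in hosts:
            orient = "sense" if genes.loc[gid, "strand"] == m.strand else "antisense"
            pairs.append(HostPair(mid, gid, orient, ambiguous))
    return sorted(pairs, key=lambda p: (p.mirna_id, p.host_gene_id))


def strand_bias_test(n_sense: int, n_total: int) -> float:
    """One-sided exact binomial p for sense-strand embedding bias.

    Under the null each intronic miRNA lands on either strand of its
    host with probability 1/2; returns P[X >= n_sense] for
    X ~ Binomial(n_total, 0.5).
    """
    if n_total <= 0:
        raise ValueError("strand bias undefined with no intronic miRNAs")
    if not 0 <= n_sense <= n_total:
        raise ValueError("n_sense must lie in [0, n_total]")
    return binomial_upper_tail(n_sense, n_total, 0.5)


def build_host_network(pairs: list[HostPair],
                       mirna_gene_edges) -> pd.DataFrame:
    """Directed miRNA -> host-gene regulation among sense pairs.

    ``mirna_gene_edges`` is an iterable of (mirna_id, gene_id) predicted
    targets.  An edge m_a -> host(m_b) exists when host(m_b) is a
    predicted target of m_a; the row is flagged auto-regulated when
    a = b.  All edges are repressive (sign -1).
    """
    sense = [p for p in pairs if p.orientation == "sense"]
    host_of = {p.mirna_id: p.host_gene_id for p in sense}
    targets = set(tuple(e) for e in mirna_gene_edges)
    rows = []
    for pa in sense:
        for pb in sense:
            if (pa.mirna_id, pb.host_gene_id) in targets:
                rows.append((pa.mirna_id, pb.host_gene_id, pb.mirna_id,
                             pa.mirna_id == pb.mirna_id, -1))
    df = pd.DataFrame(rows, columns=["mirna_id", "host_gene_id", "host_of_mirna",
                                     "auto_regulated", "sign"])
    return df.drop_duplicates(subset=["mirna_id", "host_gene_id"]).sort_values(
        ["mirna_id", "host_gene_id"]).reset_index(drop=True)


def host_pairs_table(pairs: list[HostPair]) -> pd.DataFrame:
    """Pairs as a TSV-ready table (miRNA, host, orientation, ambiguity)."""
    return pd.DataFrame([(p.mirna_id, p.host_gene_id, p.orientation,
                          int(p.ambiguous)) for p in pairs],
                        columns=["mirna_id", "host_gene_id", "orientation",
                                 "ambiguous"])
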