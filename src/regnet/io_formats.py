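"""Readers/writers and the shared coordinate model.

Every module speaks 0-based half-open genomic coordinates internally
(the BED convention); GFF3's 1-based inclusive coordinates are converted
on read and restored on write.  The TSS of a + strand feature is its
interval start; of a − strand feature, ``end - 1`` (the biological 5′
end).  The same convention anchors pre-miRNA "start positions".
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger("regnet")

STRANDS = ("+", "-", ".")

# edge-type vocabulary used everywhere downstream
EDGE_TYPES = ("TF>gene", "TF>TF", "TF>miRNA", "miRNA>gene", "miRNA>TF", "PPI")


class ParseError(ValueError):
    """Malformed record in an input stream; message names the line."""


# ---------------------------------------------------------------------------
# Core domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def contains(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.start and other.end <= self.end)

    @property
    def five_prime(self) -> int:
        """Strand-aware 5′ end (the TSS anchor for genes/pre-miRNAs)."""
        return self.start if self.strand != "-" else self.end - 1


def tss_of(start: int, end: int, strand: str) -> int:
    return start if strand != "-" else end - 1


@dataclass
class GenomeAnnotation:
    """Genes, transcripts (with exon/3′UTR structure) and pre-miRNA loci.

    ``genes``: index gene_id; columns chrom, start, end, strand, tss, is_tf.
    ``transcripts``: index transcript_id; columns gene_id, chrom, strand,
        tss, exons (tuple of (start, end)), utr3 (tuple of (start, end)).
    ``mirnas``: index mirna_id; columns chrom, start, end, strand, start5.
    """

    genes: pd.DataFrame
    transcripts: pd.DataFrame
    mirnas: pd.DataFrame

    def validate(self) -> "GenomeAnnotation":
        for df, name in ((self.genes, "gene"), (self.transcripts, "transcript"),
                         (self.mirnas, "miRNA")):
            if not df.index.is_unique:
                dupes = df.index[df.index.duplicated()].tolist()
                raise ValueError(f"duplicate {name} ids: {dupes[:5]}")
        missing = set(self.transcripts["gene_id"]) - set(self.genes.index)
        if missing:
            raise ValueError(f"transcripts reference unknown genes: {sorted(missing)[:5]}")
        for gid, row in self.genes.iterrows():
            expect = tss_of(row.start, row.end, row.strand)
            if row.tss != expect:
                raise ValueError(f"gene {gid}: TSS {row.tss} != strand-aware 5' end {expect}")
        return self

    def gene_of_transcript(self) -> dict[str, str]:
        return dict(zip(self.transcripts.index, self.transcripts["gene_id"]))


@dataclass
class PeakSet:
    """Binding peaks of one TF under one condition (stage)."""

    tf_id: str
    condition: str
    peaks: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "center", "score"]))

    def __post_init__(self):
        p = self.peaks
        if len(p):
            if ((p["center"] < p["start"]) | (p["center"] >= p["end"])).any():
                raise ValueError(f"{self.tf_id}: peak center outside its interval")
            if (p["score"] < 0).any():
                raise ValueError(f"{self.tf_id}: negative peak score")


@dataclass
class MiRNASiteTable:
    """miRNA seed sites on transcript 3′UTRs with per-species conservation.

    ``species`` is the ordered species list; conservation flags live in
    boolean columns named after each species.  The first three species
    are the core (3-way) conservation set, all five the strict set.
    """

    species: tuple[str, ...]
    sites: pd.DataFrame  # mirna_id, transcript_id, chrom, start, end, <species flags>

    def __post_init__(self):
        missing = [s for s in self.species if s not in self.sites.columns]
        if missing:
            raise ValueError(f"site table missing conservation columns: {missing}")


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

_GFF_TYPES = {"gene", "mRNA", "exon", "three_prime_UTR", "pre_miRNA"}


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_annotation(stream) -> GenomeAnnotation:
    """Parse GFF3-style annotation into the internal coordinate model.

    Recognized feature types: gene, mRNA, exon, three_prime_UTR,
    pre_miRNA.  Unknown feature types are ignored with a logged warning;
    malformed lines raise :class:`ParseError` naming the line number.
    A gene is flagged as a TF via an ``is_tf=1`` attribute.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    genes, tx, exons, utr3, mirnas = {}, {}, {}, {}, {}
    skipped: dict[str, int] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ParseError(f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}")
        chrom, _src, ftype, start1, end1, _score, strand, _frame, attr_text = cols
        try:
            start1, end1 = int(start1), int(end1)
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer coordinates") from None
        if end1 < start1:
            raise ParseError(f"line {lineno}: end < start")
        if ftype not in _GFF_TYPES:
            skipped[ftype] = skipped.get(ftype, 0) + 1
            continue
        start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
        attrs = _parse_attrs(attr_text)
        fid = attrs.get("ID", "")
        if ftype == "gene":
            genes[fid] = dict(chrom=chrom, start=start, end=end, strand=strand,
                              tss=tss_of(start, end, strand),
                              is_tf=attrs.get("is_tf", "0") == "1")
        elif ftype == "mRNA":
            tx[fid] = dict(gene_id=attrs.get("Parent", ""), chrom=chrom, strand=strand,
                           start=start, end=end, tss=tss_of(start, end, strand))
        elif ftype == "exon":
            exons.setdefault(attrs.get("Parent", ""), []).append((start, end))
        elif ftype == "three_prime_UTR":
            utr3.setdefault(attrs.get("Parent", ""), []).append((start, end))
        elif ftype == "pre_miRNA":
            mirnas[fid] = dict(chrom=chrom, start=start, end=end, strand=strand,
                               start5=tss_of(start, end, strand))
    for ftype, n in skipped.items():
        logger.warning("read_annotation: ignored %d records of unknown type %r", n, ftype)

    genes_df = pd.DataFrame.from_dict(genes, orient="index")
    tx_df = pd.DataFrame.from_dict(tx, orient="index")
    if len(tx_df):
        tx_df["exons"] = [tuple(sorted(exons.get(t, ()))) for t in tx_df.index]
        tx_df["utr3"] = [tuple(sorted(utr3.get(t, ()))) for t in tx_df.index]
    else:
        tx_df = pd.DataFrame(columns=["gene_id", "chrom", "strand", "start", "end",
                                      "tss", "exons", "utr3"])
    mirna_df = pd.DataFrame.from_dict(mirnas, orient="index")
    if not len(genes_df):
        genes_df = pd.DataFrame(columns=["chrom", "start", "end", "strand", "tss", "is_tf"])
    if not len(mirna_df):
        mirna_df = pd.DataFrame(columns=["chrom", "start", "end", "strand", "start5"])
    return GenomeAnnotation(genes_df, tx_df, mirna_df).validate()


def write_annotation(ann: GenomeAnnotation, sink) -> None:
    """Serialize annotation back to GFF3 (inverse of :func:`read_annotation`)."""
    w = sink.write
    w("##gff-version 3\n")
    for gid, g in ann.genes.iterrows():
        attrs = f"ID={gid}" + (";is_tf=1" if g.is_tf else "")
        w(f"{g.chrom}\tregnet\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
        for tid, t in ann.transcripts[ann.transcripts["gene_id"] == gid].iterrows():
            w(f"{t.chrom}\tregnet\tmRNA\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t"
              f"ID={tid};Parent={gid}\n")
            for s, e in t.exons:
                w(f"{t.chrom}\tregnet\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\tParent={tid}\n")
            for s, e in t.utr3:
                w(f"{t.chrom}\tregnet\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                  f"Parent={tid}\n")
    for mid, m in ann.mirnas.iterrows():
        w(f"{m.chrom}\tregnet\tpre_miRNA\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\tID={mid}\n")


# ---------------------------------------------------------------------------
# BED / narrowPeak peaks
# ---------------------------------------------------------------------------

def read_peaks(stream, tf_id: str, condition: str = "") -> PeakSet:
    """Parse BED3+/narrowPeak text into a :class:`PeakSet`.

    BED coordinates are already 0-based half-open and kept as-is.  The
    peak center is the narrowPeak summit (column 10, ``start + offset``)
    when present and non-negative, else ``floor((start + end) / 2)``.
    Column 5 is the score when present.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    rows = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split()
        if len(cols) < 3:
            raise ParseError(f"line {lineno}: BED needs >=3 columns")
        chrom = cols[0]
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer coordinates") from None
        if end <= start:
            raise ParseError(f"line {lineno}: end <= start")
        score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
        summit = int(cols[9]) if len(cols) > 9 else -1
        center = start + summit if summit >= 0 else (start + end) // 2
        rows.append((chrom, start, end, center, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "center", "score"])
    return PeakSet(tf_id=tf_id, condition=condition, peaks=df)


# ---------------------------------------------------------------------------
# Network edge lists
# ---------------------------------------------------------------------------

def write_network(network, sink) -> None:
    """Write an IntegratedNetwork as a sorted TSV edge list.

    One row per edge: source_id, source_type, target_id, target_type,
    edge_type, sign; unsigned edges carry sign 0.  Rows sort by
    (edge_type, source, target) so output is deterministic.
    """
    rows = []
    for _, e in network.edges.iterrows():
        rows.append((e.source, network.nodes[e.source], e.target,
                     network.nodes[e.target], e.etype, int(e.sign)))
    for _, e in network.ppi.iterrows():
        rows.append((e.source, network.nodes[e.source], e.target,
                     network.nodes[e.target], "PPI", 0))
    rows.sort(key=lambda r: (r[4], r[0], r[2]))
    sink.write("source_id\tsource_type\ttarget_id\ttarget_type\tedge_type\tsign\n")
    for r in rows:
        sink.write("\t".join(map(str, r)) + "\n")


def read_network(stream):
    """Inverse of :func:`write_network` (node types recovered from columns)."""
    from .network_builder import IntegratedNetwork

    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", dtype={"sign": int})
    nodes: dict[str, str] = {}
    for _, r in df.iterrows():
        nodes[r.source_id] = r.source_type
        nodes[r.target_id] = r.target_type
    reg = df[df.edge_type != "PPI"]
    ppi = df[df.edge_type == "PPI"]
    edges = pd.DataFrame({"source": reg.source_id, "target": reg.target_id,
                          "etype": reg.edge_type, "sign": reg.sign}).reset_index(drop=True)
    ppi_df = pd.DataFrame({"source": ppi.source_id,
                           "target": ppi.target_id}).reset_index(drop=True)
    return IntegratedNetwork(nodes=nodes, edges=edges, ppi=ppi_df)


# ---------------------------------------------------------------------------
# Plain TSV tables
# ---------------------------------------------------------------------------

def read_expression(path_or_stream) -> pd.DataFrame:
    """Expression TSV: header row of conditions, first column entity id."""
    df = pd.read_csv(path_or_stream, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("expression matrix contains negative values")
    if not df.index.is_unique or not df.columns.is_unique:
        raise ValueError("expression row/column ids must be unique")
    return df


def write_expression(df: pd.DataFrame, path_or_stream) -> None:
    df.to_csv(path_or_stream, sep="\t")


def read_site_table(path_or_stream) -> MiRNASiteTable:
    df = pd.read_csv(path_or_stream, sep="\t")
    fixed = ["mirna_id", "transcript_id", "chrom", "start", "end"]
    species = tuple(c for c in df.columns if c not in fixed)
    for s in species:
        df[s] = df[s].astype(bool)
    return MiRNASiteTable(species=species, sites=df)


def write_site_table(table: MiRNASiteTable, path_or_stream) -> None:
    df = table.sites.copy()
    for s in table.species:
        df[s] = df[s].astype(int)
    df.to_csv(path_or_stream, sep="\t", index=False)


def read_ppi(path_or_stream) -> pd.DataFrame:
    """PPI edge list TSV with columns source, target (undirected)."""
    df = pd.read_csv(path_or_stream, sep="\t")
    return df[["source", "target"]]


def read_flags(path_or_stream) -> dict[str, bool]:
    """Two-column TSV of (id, 0/1 flag) — e.g. essentiality calls."""
    df = pd.read_csv(path_or_stream, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(bool)))
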