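"""Activator/repressor classification from binding-expression correlation.

The region from 2 kb upstream to 2 kb downstream of each transcript's
TSS is divided into 40 bins of 100 bp (strand-aware: bin 1 is always
the far upstream bin).  Reads contribute to a bin in proportion to
their overlap.  Per bin, the Pearson correlation between binding signal
and transcript expression is computed across transcripts; a TF whose
per-bin correlations are consistently positive (negative) is called a
positive (negative) regulator, and all its outgoing edges inherit that
sign.  miRNA regulation is always repressive, so every miRNA edge is
signed −1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import GenomeAnnotation

logger = logging.getLogger("regnet")

N_BINS = 40
BIN_BP = 100
FLANK = N_BINS * BIN_BP // 2  # 2000 bp each side of the TSS


@dataclass
class BinnedSignalMatrix:
    """Per-transcript, per-bin overlap-weighted binding signal for one TF."""

    tf_id: str
    values: pd.DataFrame  # transcripts x N_BINS, columns 0..N_BINS-1
    n_bins: int = N_BINS
    bin_bp: int = BIN_BP

    def __post_init__(self):
        if self.values.shape[1] != self.n_bins:
            raise ValueError(f"expected {self.n_bins} bins, got {self.values.shape[1]}")
        if (self.values.values < 0).any():
            raise ValueError("binned signal must be non-negative")


@dataclass(frozen=True)
class SignCall:
    """Per-TF regulator class with its per-bin correlation profile."""

    tf_id: str
    bin_correlations: tuple[float, ...]  # NaN where undefined
    klass: str  # 'positive' | 'negative' | 'ambiguous'
    consistency: float

    @property
    def sign(self) -> int:
        return {"positive": 1, "negative": -1}.get(self.klass, 0)


def binned_signal(reads: pd.DataFrame, annotation: GenomeAnnotation, tf_id: str,
                  n_bins: int = N_BINS, bin_bp: int = BIN_BP) -> BinnedSignalMatrix:
    """Bin read intervals around every transcript TSS.

    ``reads`` has columns chrom, start, end (0-based half-open).  Each
    read adds (overlap bp with bin) / (read length) to a bin, so one
    read distributes at most 1.0 of weight across the window.  Bins are
    ordered 5′→3′: for − strand transcripts the genomic bins are
    mirror-imaged so bin 0 is always the far-upstream bin.
    """
    flank = n_bins * bin_bp // 2
    by_chrom = {}
    for chrom, sub in reads.groupby("chrom"):
        s = sub["start"].to_numpy(dtype=np.int64)
        e = sub["end"].to_numpy(dtype=np.int64)
        order = np.argsort(s)
        by_chrom[chrom] = (s[order], e[order], int((e - s).max()) if len(s) else 0)
    mat = np.zeros((len(annotation.transcripts), n_bins))
    for row, (tid, t) in enumerate(annotation.transcripts.iterrows()):
        if t.chrom not in by_chrom:
            continue
        starts, ends, max_len = by_chrom[t.chrom]
        wstart = int(t.tss) - flank
        wend = int(t.tss) + flank
        if wstart < 0:
            logger.debug("transcript %s window clipped at chromosome start", tid)
        lo = int(np.searchsorted(starts, wstart - max_len, side="left"))
        hi = int(np.searchsorted(starts, wend, side="left"))
        for i in range(lo, hi):
            rs, re = int(starts[i]), int(ends[i])
            if re <= wstart:
                continue
            rlen = re - rs
            first = max((rs - wstart) // bin_bp, 0)
            last = min((re - 1 - wstart) // bin_bp, n_bins - 1)
            for b in range(first, last + 1):
                bs = wstart + b * bin_bp
                ov = min(re, bs + bin_bp) - max(rs, bs)
                if ov > 0:
                    g = b if t.strand != "-" else n_bins - 1 - b
                    mat[row, g] += ov / rlen
    df = pd.DataFrame(mat, index=annotation.transcripts.index,
                      columns=range(n_bins))
    return BinnedSignalMatrix(tf_id=tf_id, values=df, n_bins=n_bins, bin_bp=bin_bp)


def classify_regulator(signal: BinnedSignalMatrix, expr: pd.DataFrame, condition: str,
                       consistency_cutoff: float = 0.7,
                       log_transform: bool = True) -> SignCall:
    """Call a TF positive/negative/ambiguous from its bin correlations.

    Per bin b, r_b = Pearson(signal[:, b], expression) across the
    transcripts shared by both tables (>=10 required).  Expression is
    log2(x+1)-transformed by default.  ``consistency`` is the larger of
    the fraction of defined bins with r_b > 0 and with r_b < 0; the
    class is the sign of mean(r_b) when consistency reaches the cutoff,
    else ambiguous.  Bins with zero signal variance have no defined
    correlation and are dropped from the denominator.
    """
    if condition not in expr.columns:
        raise ValueError(f"condition {condition!r} not in expression matrix")
    shared = signal.values.index.intersection(expr.index)
    if len(shared) < 10:
        raise ValueError(f"need >=10 transcripts with both signal and expression, "
                         f"got {len(shared)}")
    y = expr.loc[shared, condition].to_numpy(dtype=float)
    if log_transform:
        y = np.log2(y + 1.0)
    if np.all(y == y[0]):
        raise ValueError(f"{signal.tf_id}: zero-variance expression vector "
                         f"under condition {condition!r}")
    sig = signal.values.loc[shared].to_numpy(dtype=float)
    rs = np.full(signal.n_bins, np.nan)
    for b in range(signal.n_bins):
        x = sig[:, b]
        if np.all(x == x[0]):
            continue  # undefined correlation, dropped from consistency
        rs[b] = sps.pearsonr(x, y).statistic
    defined = rs[~np.isnan(rs)]
    if defined.size == 0:
        return SignCall(signal.tf_id, tuple(rs), "ambiguous", 0.0)
    frac_pos = float(np.mean(defined > 0))
    frac_neg = float(np.mean(defined < 0))
    consistency = max(frac_pos, frac_neg)
    mean_r = float(defined.mean())
    if consistency >= consistency_cutoff and mean_r != 0:
        klass = "positive" if mean_r > 0 else "negative"
    else:
        klass = "ambiguous"
    return SignCall(signal.tf_id, tuple(rs), klass, consistency)


def assign_edge_signs(network, sign_calls: dict[str, SignCall]):
    """Sign every regulatory edge in place and return the network.

    TF out-edges inherit the TF's class sign (0 for ambiguous); all
    miRNA edges are repressive (−1); PPI edges stay unsigned.  Raises
    if any TF with outgoing edges has no sign call.
    """
    edges = network.edges
    tf_sources = sorted(set(edges.loc[edges.etype.str.startswith("TF"), "source"]))
    missing = [tf for tf in tf_sources if tf not in sign_calls]
    if missing:
        raise ValueError(f"no SignCall for TFs with out-edges: {missing}")
    signs = np.zeros(len(edges), dtype=int)
    for i, (_, e) in enumerate(edges.iterrows()):
        if e.etype.startswith("miRNA"):
            signs[i] = -1
        else:
            signs[i] = sign_calls[e.source].sign
    network.edges = edges.assign(sign=signs)
    return network


def correlation_profile_table(calls: list[SignCall]) -> pd.DataFrame:
    """Per-TF bin-correlation profiles as a tidy table (TF x bin)."""
    rows = {c.tf_id: list(c.bin_correlations) for c in calls}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "tf_id"
    return df
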