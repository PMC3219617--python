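"""TF target calling from ChIP peaks via strand-aware promoter windows.

A gene (or miRNA) is a target of a TF when the *center* of at least one
binding peak falls inside the promoter window anchored at a transcript
TSS (or the pre-miRNA 5′ end).  Highly Occupied Target (HOT) regions —
short loci bound by many distinct factors at once, where binding is
thought to be non-specific — can be detected and their peaks excluded
before calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeAnnotation, PeakSet

logger = logging.getLogger("regnet")


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware promoter window around a TSS.

    For a + strand TSS ``t`` the window is ``[t - upstream, t + downstream)``
    in 0-based half-open coordinates; for − strand it mirrors to
    ``[t - downstream + 1, t + upstream + 1)``.
    """

    upstream: int = 1000
    downstream: int = 500

    def __post_init__(self):
        if self.upstream < 0 or self.downstream < 0 or self.upstream + self.downstream <= 0:
            raise ValueError("promoter window must have non-negative, non-empty extent")

    def around(self, tss: int, strand: str) -> tuple[int, int]:
        if strand == "-":
            return tss - self.downstream + 1, tss + self.upstream + 1
        return tss - self.upstream, tss + self.downstream

    @property
    def length(self) -> int:
        return self.upstream + self.downstream


#: named presets from the sensitivity analysis
WINDOW_PRESETS = {
    "default": PromoterWindow(1000, 500),
    "strict": PromoterWindow(500, 300),
    "relaxed": PromoterWindow(2000, 500),
}


@dataclass
class HotRegionSet:
    """Merged genomic intervals bound by >= threshold distinct TFs."""

    regions: pd.DataFrame  # chrom, start, end, occupancy
    window_bp: int
    threshold: int

    def __len__(self) -> int:
        return len(self.regions)

    def to_bed(self, sink) -> None:
        for _, r in self.regions.iterrows():
            sink.write(f"{r.chrom}\t{r.start}\t{r.end}\thot\t{r.occupancy}\n")


def detect_hot_regions(peaksets: list[PeakSet], window_bp: int = 400,
                       threshold: int = 15) -> HotRegionSet:
    """Find HOT regions by sliding a window over stacked per-TF peaks.

    A genomic position x is HOT-covered when peaks of >= ``threshold``
    distinct TFs overlap the ``window_bp`` window centered on x; maximal
    runs of HOT-covered positions are merged into intervals.  Multiple
    conditions of the same TF count as one factor.

    Implemented as a sweep line: a peak [s, e) of some TF makes
    positions (s - w//2, e + w//2) eligible for that TF (half-open after
    integer tightening: [s - w//2 + 1, e + w//2)); per-TF eligibility
    intervals are merged first so each factor counts once.
    """
    if threshold < 1:
        raise ValueError("HOT threshold must be >= 1")
    if not peaksets:
        raise ValueError("need at least one PeakSet")
    half = window_bp // 2
    # per-TF merged eligibility intervals, per chromosome
    events: dict[str, list[tuple[int, int]]] = {}
    by_tf: dict[str, list[PeakSet]] = {}
    for ps in peaksets:
        by_tf.setdefault(ps.tf_id, []).append(ps)
    for tf, sets in by_tf.items():
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for ps in sets:
            for _, p in ps.peaks.iterrows():
                per_chrom.setdefault(p.chrom, []).append(
                    (int(p.start) - half + 1, int(p.end) + half))
        for chrom, ivals in per_chrom.items():
            ivals.sort()
            merged: list[list[int]] = []
            for s, e in ivals:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            ev = events.setdefault(chrom, [])
            for s, e in merged:
                ev.append((s, 1))
                ev.append((e, -1))
    rows = []
    for chrom, ev in events.items():
        ev.sort()
        depth, run_start, run_max = 0, None, 0
        cur = None  # [start, end, max_occupancy] of current merged HOT interval
        for pos, delta in ev:
            prev = depth
            depth += delta
            if prev < threshold <= depth:
                run_start, run_max = pos, depth
            elif prev >= threshold <= depth:
                run_max = max(run_max, depth)
            elif prev >= threshold > depth:
                s, e = max(run_start, 0), pos
                if cur is not None and s <= cur[1]:
                    cur[1] = max(cur[1], e)
                    cur[2] = max(cur[2], run_max)
                else:
                    if cur is not None:
                        rows.append((chrom, cur[0], cur[1], cur[2]))
                    cur = [s, e, run_max]
        if cur is not None:
            rows.append((chrom, cur[0], cur[1], cur[2]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "occupancy"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return HotRegionSet(regions=df, window_bp=window_bp, threshold=threshold)


def auto_hot_threshold(n_assayed_tfs: int, fraction: float = 15 / 22) -> int:
    """Scale the occupancy threshold to the assayed TF count.

    Preserves the reference occupancy fraction (15 of 22 factors) when a
    run assays fewer or more TFs than the reference panel.
    """
    import math
    return max(1, math.ceil(fraction * n_assayed_tfs))


def _filter_hot_peaks(peaks: pd.DataFrame, hot: HotRegionSet | None,
                      hot_mode: str) -> pd.DataFrame:
    if hot_mode == "keep":
        return peaks
    if hot is None:
        raise ValueError(f"hot_mode={hot_mode!r} requires a HotRegionSet")
    if hot_mode not in ("exclude_overlap", "exclude_center"):
        raise ValueError(f"unknown hot_mode {hot_mode!r}")
    if not len(hot.regions) or not len(peaks):
        return peaks
    keep = np.ones(len(peaks), dtype=bool)
    for chrom, sub in hot.regions.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        mask = (peaks["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        if hot_mode == "exclude_overlap":
            ps = peaks.loc[mask, "start"].to_numpy()
            pe = peaks.loc[mask, "end"].to_numpy()
            # overlap iff any hot interval with start < peak_end and end > peak_start
            hit = np.array([np.any((starts < e) & (ends > s)) for s, e in zip(ps, pe)])
        else:
            pc = peaks.loc[mask, "center"].to_numpy()
            hit = np.array([np.any((starts <= c) & (c < ends)) for c in pc])
        keep[np.flatnonzero(mask)[hit]] = False
    dropped = int((~keep).sum())
    if dropped:
        logger.info("HOT filter (%s): dropped %d/%d peaks", hot_mode, dropped, len(peaks))
    return peaks[keep]


def _window_index(annotation: GenomeAnnotation, window: PromoterWindow):
    """Per-chromosome sorted window starts with target ids.

    All windows share length ``window.length`` so membership of a peak
    center c in some window reduces to a binary search over starts in
    ``(c - L, c]``.
    """
    per_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for tid, t in annotation.transcripts.iterrows():
        ws, _we = window.around(int(t.tss), t.strand)
        per_chrom.setdefault(t.chrom, []).append((ws, t.gene_id, "gene"))
    for mid, m in annotation.mirnas.iterrows():
        ws, _we = window.around(int(m.start5), m.strand)
        per_chrom.setdefault(m.chrom, []).append((ws, mid, "mirna"))
    out = {}
    for chrom, entries in per_chrom.items():
        entries.sort(key=lambda x: x[0])
        out[chrom] = (np.array([e[0] for e in entries]), entries)
    return out


def call_tf_targets(peakset: PeakSet, annotation: GenomeAnnotation,
                    window: PromoterWindow = WINDOW_PRESETS["default"],
                    hot: HotRegionSet | None = None,
                    hot_mode: str = "keep") -> list[tuple[str, str, str]]:
    """Call (tf_id, target_id, target_type) edges for one peak set.

    A gene is a target when a surviving peak center falls in the
    promoter window of *any* of its transcripts; a miRNA when a center
    falls in the window anchored at its pre-miRNA 5′ end.  Edges are
    deduplicated.
    """
    peaks = _filter_hot_peaks(peakset.peaks, hot, hot_mode)
    idx = _window_index(annotation, window)
    L = window.length
    found: set[tuple[str, str]] = set()
    for chrom, sub in peaks.groupby("chrom"):
        if chrom not in idx:
            continue
        starts, entries = idx[chrom]
        for c in sub["center"].to_numpy():
            lo = int(np.searchsorted(starts, c - L, side="right"))
            hi = int(np.searchsorted(starts, c, side="right"))
            for k in range(lo, hi):
                _ws, target_id, ttype = entries[k]
                found.add((target_id, ttype))
    return sorted((peakset.tf_id, tid, tt) for tid, tt in found)


def call_all_targets(peaksets: list[PeakSet], annotation: GenomeAnnotation,
                     window: PromoterWindow = WINDOW_PRESETS["default"],
                     hot: HotRegionSet | None = None,
                     hot_mode: str = "keep") -> list[tuple[str, str, str]]:
    """Union of target calls across all peak sets (conditions merged per TF)."""
    edges: set[tuple[str, str, str]] = set()
    for ps in peaksets:
        edges.update(call_tf_targets(ps, annotation, window, hot, hot_mode))
    return sorted(edges)
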