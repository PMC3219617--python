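"""Synthetic regulome generator with planted, recoverable structure.

Emulates the full input set the pipeline consumes — annotation, ChIP
peaks, binned binding signal, stage/tissue expression, miRNA seed-site
tables with conservation flags, PPI edges, essentiality flags — with
known ground truth: planted regulator signs, planted motif instances,
planted HOT loci, and a controllable sense-strand bias for intronic
miRNAs.  Every true TF edge gets a peak whose center lies inside the
default promoter window, so truth is recoverable by construction and
parameter-recovery tests are exact.

All randomness flows from one integer seed; each component draws from
its own sub-stream at a fixed offset so partial reruns reproduce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (GenomeAnnotation, MiRNASiteTable, PeakSet, tss_of,
                         write_annotation, write_expression, write_site_table)
from .sign_classifier import BIN_BP, FLANK, N_BINS, BinnedSignalMatrix

SPECIES = ("C_elegans", "C_briggsae", "C_remanei", "C_brenneri", "C_japonica")
STAGES = ("EE", "LE", "L1", "L2", "L3", "L4", "YA")


@dataclass
class SimulationParams:
    """Knobs of the synthetic regulome; defaults are the study conditions.

    Scale mirrors the reference panel's order of magnitude (22 assayed
    TFs, 160 miRNAs, thousands of genes) at desk size.
    """

    n_genes: int = 1000
    n_tfs_annotated: int = 60      # genes flagged as TFs
    n_tfs_assayed: int = 20        # TFs with ChIP data and a planted sign
    n_mirnas: int = 60
    n_tissues: int = 8
    n_stages: int = 7
    n_chromosomes: int = 4
    chrom_bp: int = 2_500_000
    fraction_intronic_mirnas: float = 0.34   # worm: 60 of ~174 annotated miRNAs
    sense_probability: float = 0.8
    fraction_no_utr3: float = 0.05           # genes outside the 3'UTR universe
    fraction_two_transcripts: float = 0.1
    positive_tf_fraction: float = 0.5
    mean_gene_targets_per_tf: float = 80.0
    mean_mirna_targets_per_tf: float = 8.0
    mean_gene_targets_per_mirna: float = 25.0
    peak_jitter_bp: float = 250.0            # truncated to the promoter window
    peak_halfwidth_bp: int = 150
    background_peaks_per_tf: float = 40.0
    hot_region_count: int = 5
    hot_tf_count: int = 16                   # distinct TFs stacked per HOT locus
    beta: float = 1.0                        # binding -> log2 expression effect
    expression_sigma: float = 1.0            # log2 baseline spread
    noise_sigma: float = 0.3                 # log2 residual noise
    site_all5_probability: float = 0.6       # true sites conserved in all 5 species
    decoy_sites_per_mirna: float = 10.0      # conserved in <=2 species, never pass
    ppi_mean_degree: float = 4.0
    essential_fraction: float = 0.25
    n_planted_ffl: int = 10
    n_planted_feedback: int = 5
    n_planted_comirna_ppi: int = 10
    seed: int = 0

    def validate(self) -> "SimulationParams":
        for name in ("fraction_intronic_mirnas", "sense_probability",
                     "fraction_no_utr3", "positive_tf_fraction",
                     "site_all5_probability", "essential_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")
        if self.n_tfs_assayed > self.n_tfs_annotated:
            raise ValueError("cannot assay more TFs than are annotated")
        if self.hot_tf_count > self.n_tfs_assayed:
            raise ValueError("HOT occupancy cannot exceed the assayed TF count")
        if min(self.n_genes, self.n_mirnas, self.n_stages) < 1:
            raise ValueError("counts must be positive")
        return self


# sub-stream offsets: one RNG lineage per generator component
_STREAM = {"annotation": 1, "regulome": 2, "signal": 3, "expression": 4,
           "sites": 5, "ppi": 6, "flags": 7}


def _rng(params: SimulationParams, component: str) -> np.random.Generator:
    return np.random.default_rng((params.seed, _STREAM[component]))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(params: SimulationParams) -> GenomeAnnotation:
    """Lay out non-overlapping genes (>=2.5 kb apart) and pre-miRNA loci.

    Genes get 3 exons / 2 introns; a fraction of miRNAs is placed
    wholly inside an intron of a host gene (sense strand with
    probability ``sense_probability``), the rest midway between genes.
    """
    params.validate()
    rng = _rng(params, "annotation")
    max_span = 4800 + 4500  # max gene length + max gap
    per_chrom = int(np.ceil(params.n_genes / params.n_chromosomes))
    if 3000 + per_chrom * max_span > params.chrom_bp:
        raise ValueError(f"chrom_bp={params.chrom_bp} too small for "
                         f"{per_chrom} genes per chromosome")
    genes, tx, mirna_rows = {}, {}, {}
    intron_slots = []      # (gene_id, intron_start, intron_end, gene_strand)
    gap_slots = []         # (chrom, midpoint)
    gid_no = 0
    is_tf_ids = set(f"g{1 + i:04d}" for i in rng.choice(
        params.n_genes, size=params.n_tfs_annotated, replace=False))
    for c in range(params.n_chromosomes):
        chrom = f"chr{c + 1}"
        pos = 3000
        for _ in range(per_chrom):
            if gid_no >= params.n_genes:
                break
            gid_no += 1
            gid = f"g{gid_no:04d}"
            length = int(rng.integers(2400, 4801))
            gap = int(rng.integers(2500, 4501))
            start, end = pos, pos + length
            strand = "+" if rng.random() < 0.5 else "-"
            genes[gid] = dict(chrom=chrom, start=start, end=end, strand=strand,
                              tss=tss_of(start, end, strand),
                              is_tf=gid in is_tf_ids)
            exon_len = 400
            e1 = (start, start + exon_len)
            e3 = (end - exon_len, end)
            mid = (start + end) // 2
            e2 = (mid - exon_len // 2, mid + exon_len // 2)
            exons = (e1, e2, e3)
            intron_slots.append((gid, e1[1], e2[0], strand))
            intron_slots.append((gid, e2[1], e3[0], strand))
            has_utr = rng.random() >= params.fraction_no_utr3
            n_tx = 2 if rng.random() < params.fraction_two_transcripts else 1
            for k in range(n_tx):
                tid = f"{gid}.t{k + 1}"
                if k == 0:
                    ts, te = start, end
                else:  # alternative TSS 300 bp into the gene body
                    ts, te = (start + 300, end) if strand == "+" else (start, end - 300)
                if has_utr:
                    utr = ((te - 200, te),) if strand == "+" else ((ts, ts + 200),)
                else:
                    utr = ()
                tx[tid] = dict(gene_id=gid, chrom=chrom, strand=strand,
                               start=ts, end=te, tss=tss_of(ts, te, strand),
                               exons=exons, utr3=utr)
            gap_slots.append((chrom, end + gap // 2))
            pos = end + gap
    n_intronic = int(round(params.fraction_intronic_mirnas * params.n_mirnas))
    pre_len = 80
    slots = [s for s in intron_slots if s[2] - s[1] >= pre_len + 40]
    idx = rng.choice(len(slots), size=n_intronic, replace=False)
    for m, si in enumerate(idx, start=1):
        gid, istart, iend, gstrand = slots[si]
        offset = int(rng.integers(20, iend - istart - pre_len - 19))
        s = istart + offset
        sense = rng.random() < params.sense_probability
        strand = gstrand if sense else ("-" if gstrand == "+" else "+")
        mirna_rows[f"mir-{m:03d}"] = dict(chrom=genes[gid]["chrom"], start=s,
                                          end=s + pre_len, strand=strand,
                                          start5=tss_of(s, s + pre_len, strand))
    gap_idx = rng.choice(len(gap_slots), size=params.n_mirnas - n_intronic,
                         replace=False)
    for m, gi in enumerate(gap_idx, start=n_intronic + 1):
        chrom, mid = gap_slots[gi]
        s = mid - pre_len // 2
        strand = "+" if rng.random() < 0.5 else "-"
        mirna_rows[f"mir-{m:03d}"] = dict(chrom=chrom, start=s, end=s + pre_len,
                                          strand=strand,
                                          start5=tss_of(s, s + pre_len, strand))
    ann = GenomeAnnotation(
        pd.DataFrame.from_dict(genes, orient="index"),
        pd.DataFrame.from_dict(tx, orient="index"),
        pd.DataFrame.from_dict(mirna_rows, orient="index"))
    return ann.validate()


# ---------------------------------------------------------------------------
# Regulome
# ---------------------------------------------------------------------------

@dataclass
class TruthBundle:
    """Everything the pipeline consumes plus the generating truth."""

    params: SimulationParams
    annotation: GenomeAnnotation
    tf_ids: list[str]
    tf_signs: dict[str, int]
    tf_conditions: dict[str, str]
    true_tf_edges: list[tuple[str, str, str]]     # (tf, target, 'gene'|'mirna')
    true_mirna_edges: list[tuple[str, str]]       # (mirna, gene)
    peaksets: list[PeakSet]
    signal: dict[str, BinnedSignalMatrix]
    expression_stage: pd.DataFrame                # transcripts x stages
    expression_tissue: pd.DataFrame               # genes x tissues
    sites: MiRNASiteTable
    ppi: pd.DataFrame
    essentiality: dict[str, bool]
    planted: dict = field(default_factory=dict)
    hot_loci: list[tuple[str, int, int]] = field(default_factory=list)


def _promoter_center(rng, tss: int, strand: str, jitter: float,
                     upstream: int = 1000, downstream: int = 500) -> int:
    o = int(np.clip(round(rng.normal(0.0, jitter)), -upstream, downstream - 1))
    return tss + o if strand != "-" else tss - o


def simulate_regulome(annotation: GenomeAnnotation,
                      params: SimulationParams) -> TruthBundle:
    """Plant a signed regulome on an annotation and emit all input data."""
    params.validate()
    rng = _rng(params, "regulome")
    genes = annotation.genes
    universe = list(genes.index)
    tf_pool = [g for g in universe if genes.loc[g, "is_tf"]]
    # assayed TFs must sit inside the 3'UTR universe so their own node survives
    has_utr = {t.gene_id for _, t in annotation.transcripts.iterrows() if t.utr3}
    tf_ids = [g for g in tf_pool if g in has_utr][:params.n_tfs_assayed]
    if len(tf_ids) < params.n_tfs_assayed:
        raise ValueError("not enough annotated TFs with 3'UTRs to assay")
    mirnas = list(annotation.mirnas.index)
    n_pos = int(round(params.positive_tf_fraction * len(tf_ids)))
    signs = {tf: (1 if i < n_pos else -1) for i, tf in enumerate(tf_ids)}
    stages = [STAGES[i % len(STAGES)] for i in range(params.n_stages)]
    conditions = {tf: stages[i % len(stages)] for i, tf in enumerate(tf_ids)}

    # --- true regulatory edges ---------------------------------------------
    tf_edges: set[tuple[str, str, str]] = set()
    for tf in tf_ids:
        ng = 1 + rng.poisson(params.mean_gene_targets_per_tf - 1)
        targets = rng.choice(universe, size=min(ng, len(universe)), replace=False)
        for t in targets:
            if t != tf:  # self-loops planted separately below
                tf_edges.add((tf, str(t), "gene"))
        nm = 1 + rng.poisson(params.mean_mirna_targets_per_tf - 1)
        for t in rng.choice(mirnas, size=min(nm, len(mirnas)), replace=False):
            tf_edges.add((tf, str(t), "mirna"))
    mirna_edges: set[tuple[str, str]] = set()
    for m in mirnas:
        ng = 1 + rng.poisson(params.mean_gene_targets_per_mirna - 1)
        for t in rng.choice(universe, size=min(ng, len(universe)), replace=False):
            mirna_edges.add((m, str(t)))

    # --- planted motif instances -------------------------------------------
    non_tf_genes = [g for g in universe if g not in set(tf_ids)]
    ffl = 0
    while ffl < params.n_planted_ffl:
        t1, t2 = rng.choice(len(tf_ids), size=2, replace=False)
        t1, t2 = tf_ids[t1], tf_ids[t2]
        g = str(rng.choice(non_tf_genes))
        tf_edges.update({(t1, t2, "gene"), (t1, g, "gene"), (t2, g, "gene")})
        ffl += 1
    fb = 0
    while fb < params.n_planted_feedback:
        tf = tf_ids[int(rng.integers(len(tf_ids)))]
        m = str(rng.choice(mirnas))
        tf_edges.add((tf, m, "mirna"))
        mirna_edges.add((m, tf))
        fb += 1
    ppi_extra = []
    for _ in range(params.n_planted_comirna_ppi):
        m = str(rng.choice(mirnas))
        g1, g2 = rng.choice(len(non_tf_genes), size=2, replace=False)
        g1, g2 = non_tf_genes[g1], non_tf_genes[g2]
        mirna_edges.update({(m, g1), (m, g2)})
        ppi_extra.append((min(g1, g2), max(g1, g2)))

    # --- peaks ---------------------------------------------------------------
    gene_tss = {g: (int(genes.loc[g, "tss"]), genes.loc[g, "strand"],
                    genes.loc[g, "chrom"]) for g in universe}
    mirna_anchor = {m: (int(annotation.mirnas.loc[m, "start5"]),
                        annotation.mirnas.loc[m, "strand"],
                        annotation.mirnas.loc[m, "chrom"]) for m in mirnas}
    chrom_names = sorted(genes["chrom"].unique())
    hw = params.peak_halfwidth_bp
    hot_loci = []
    hot_rng = rng
    for _ in range(params.hot_region_count):
        chrom = chrom_names[int(hot_rng.integers(len(chrom_names)))]
        s = int(hot_rng.integers(5000, params.chrom_bp - 5000))
        hot_loci.append((chrom, s, s + 400))
    hot_tfs = {h: list(rng.choice(tf_ids, size=params.hot_tf_count, replace=False))
               for h in range(len(hot_loci))}
    peaksets = []
    for tf in tf_ids:
        rows = []
        for (src, tgt, ttype) in sorted(tf_edges):
            if src != tf:
                continue
            tss, strand, chrom = gene_tss[tgt] if ttype == "gene" else mirna_anchor[tgt]
            c = _promoter_center(rng, tss, strand, params.peak_jitter_bp)
            rows.append((chrom, max(c - hw, 0), c + hw + 1, c,
                         float(rng.uniform(1, 10))))
        for _ in range(rng.poisson(params.background_peaks_per_tf)):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            c = int(rng.integers(1000, params.chrom_bp - 1000))
            rows.append((chrom, c - hw, c + hw + 1, c, float(rng.uniform(1, 10))))
        for h, (chrom, s, e) in enumerate(hot_loci):
            if tf in hot_tfs[h]:
                c = (s + e) // 2
                rows.append((chrom, s, e, c, float(rng.uniform(1, 10))))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "center", "score"])
        peaksets.append(PeakSet(tf_id=tf, condition=conditions[tf], peaks=df))

    # --- binned signal and expression ---------------------------------------
    srng = _rng(params, "signal")
    tids = list(annotation.transcripts.index)
    tx2gene = annotation.gene_of_transcript()
    gene_targets_of = {tf: {t for s, t, ty in tf_edges if s == tf and ty == "gene"}
                       for tf in tf_ids}
    bins = np.arange(N_BINS)
    profile = 0.2 + np.exp(-((bins - (N_BINS - 1) / 2) / 8.0) ** 2)
    strength: dict[str, np.ndarray] = {}
    signal: dict[str, BinnedSignalMatrix] = {}
    for tf in tf_ids:
        amp = np.zeros(len(tids))
        members = gene_targets_of[tf]
        for i, tid in enumerate(tids):
            if tx2gene[tid] in members:
                amp[i] = 0.5 + abs(srng.normal(0.0, 1.0))
        noise = srng.exponential(0.2, size=(len(tids), N_BINS))
        mat = amp[:, None] * profile[None, :] + noise
        signal[tf] = BinnedSignalMatrix(
            tf_id=tf, values=pd.DataFrame(mat, index=tids, columns=range(N_BINS)))
        strength[tf] = amp
    erng = _rng(params, "expression")
    base = erng.normal(5.0, params.expression_sigma, size=len(tids))
    expr = {}
    for stage in stages:
        y = base.copy()
        for tf in tf_ids:
            y += signs[tf] * params.beta * strength[tf]
        y += erng.normal(0.0, params.noise_sigma, size=len(tids))
        expr[stage] = np.maximum(np.exp2(y) - 1.0, 0.0)
    expression_stage = pd.DataFrame(expr, index=tids)
    tissue_rng = erng
    alpha = tissue_rng.uniform(0.3, 3.0, size=len(universe))
    frac = np.vstack([tissue_rng.dirichlet([a] * params.n_tissues) for a in alpha])
    totals = np.exp2(tissue_rng.normal(8.0, 1.0, size=len(universe)))
    expression_tissue = pd.DataFrame(
        frac * totals[:, None], index=universe,
        columns=[f"tissue{i + 1}" for i in range(params.n_tissues)])

    # --- miRNA seed sites ----------------------------------------------------
    site_rng = _rng(params, "sites")
    utr_tx_of_gene: dict[str, list[tuple[str, tuple]]] = {}
    for tid, t in annotation.transcripts.iterrows():
        if t.utr3:
            utr_tx_of_gene.setdefault(t.gene_id, []).append((tid, t.utr3))
    site_rows = []
    realized_mirna_edges = set()
    for (m, g) in sorted(mirna_edges):
        choices = utr_tx_of_gene.get(g)
        if not choices:
            continue  # gene outside the 3'UTR universe: edge not realizable
        tid, utrs = choices[int(site_rng.integers(len(choices)))]
        us, ue = utrs[0]
        s = int(site_rng.integers(us, ue - 7))
        all5 = site_rng.random() < params.site_all5_probability
        flags = [True, True, True, all5, all5]
        site_rows.append([m, tid, annotation.transcripts.loc[tid, "chrom"],
                          s, s + 7] + flags)
        realized_mirna_edges.add((m, g))
    n_decoys = site_rng.poisson(params.decoy_sites_per_mirna, size=len(mirnas))
    utr_genes = sorted(utr_tx_of_gene)
    for m, nd in zip(mirnas, n_decoys):
        for _ in range(nd):
            g = utr_genes[int(site_rng.integers(len(utr_genes)))]
            tid, utrs = utr_tx_of_gene[g][0]
            us, ue = utrs[0]
            s = int(site_rng.integers(us, ue - 7))
            k = int(site_rng.integers(0, 3))  # conserved in <=2 species
            flags = [i < k for i in range(5)]
            site_rows.append([m, tid, annotation.transcripts.loc[tid, "chrom"],
                              s, s + 7] + flags)
    sites = MiRNASiteTable(species=SPECIES, sites=pd.DataFrame(
        site_rows, columns=["mirna_id", "transcript_id", "chrom", "start", "end",
                            *SPECIES]))

    # --- PPI and essentiality ------------------------------------------------
    prng = _rng(params, "ppi")
    n_ppi = int(params.ppi_mean_degree * len(universe) / 2)
    pairs = set(ppi_extra)
    while len(pairs) < n_ppi + len(ppi_extra):
        i, j = prng.integers(0, len(universe), size=2)
        if i != j:
            a, b = universe[i], universe[j]
            pairs.add((min(a, b), max(a, b)))
    ppi = pd.DataFrame(sorted(pairs), columns=["source", "target"])
    frng = _rng(params, "flags")
    essentiality = {g: bool(frng.random() < params.essential_fraction)
                    for g in universe}

    return TruthBundle(
        params=params, annotation=annotation, tf_ids=tf_ids, tf_signs=signs,
        tf_conditions=conditions, true_tf_edges=sorted(tf_edges),
        true_mirna_edges=sorted(realized_mirna_edges), peaksets=peaksets,
        signal=signal, expression_stage=expression_stage,
        expression_tissue=expression_tissue, sites=sites, ppi=ppi,
        essentiality=essentiality,
        planted={"n_ffl": params.n_planted_ffl,
                 "n_feedback": params.n_planted_feedback,
                 "n_comirna_ppi": params.n_planted_comirna_ppi},
        hot_loci=hot_loci)


def simulate(params: SimulationParams) -> TruthBundle:
    """Convenience: annotation + regulome in one call."""
    return simulate_regulome(simulate_annotation(params), params)


# ---------------------------------------------------------------------------
# Fixture export
# ---------------------------------------------------------------------------

def write_fixture(bundle: TruthBundle, outdir) -> dict[str, str]:
    """Write the full input set as plain-text files; returns path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    with open(out / "annotation.gff3", "w") as fh:
        write_annotation(bundle.annotation, fh)
    paths["annotation"] = "annotation.gff3"
    peaks_dir = out / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    for ps in bundle.peaksets:
        fname = f"{ps.tf_id}_{ps.condition}.narrowPeak"
        with open(peaks_dir / fname, "w") as fh:
            for _, p in ps.peaks.iterrows():
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t.\t{p.score:.3f}\t.\t0\t-1\t-1\t"
                         f"{int(p.center - p.start)}\n")
    paths["peaks_dir"] = "peaks"
    write_expression(bundle.expression_stage, out / "expression_stage.tsv")
    write_expression(bundle.expression_tissue, out / "expression_tissue.tsv")
    with open(out / "sites.tsv", "w") as fh:
        write_site_table(bundle.sites, fh)
    bundle.ppi.to_csv(out / "ppi.tsv", sep="\t", index=False)
    pd.DataFrame({"id": list(bundle.essentiality),
                  "essential": [int(v) for v in bundle.essentiality.values()]}
                 ).to_csv(out / "essential.tsv", sep="\t", index=False)
    truth = {"tf_signs": bundle.tf_signs,
             "tf_conditions": bundle.tf_conditions,
             "true_tf_edges": [list(e) for e in bundle.true_tf_edges],
             "true_mirna_edges": [list(e) for e in bundle.true_mirna_edges],
             "planted": bundle.planted,
             "hot_loci": [list(h) for h in bundle.hot_loci],
             "params": asdict(bundle.params)}
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    for name in ("expression_stage.tsv", "expression_tissue.tsv", "sites.tsv",
                 "ppi.tsv", "essential.tsv", "truth.json"):
        paths[name.split(".")[0]] = name
    return paths
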