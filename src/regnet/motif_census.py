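"""Typed/signed subgraph census and enrichment against rewiring nulls.

Counts every connected 2- or 3-node subgraph of the regulatory network
exactly, labelling each by a canonical form that is invariant under
node relabelling (node types T/M/G, directed edges, optionally signs).
Enrichment compares the real counts against an ensemble of networks
randomized by Maslov-Sneppen double-edge swaps *within each edge-type
stratum* (and within sign strata in signed mode), so every node keeps
its number of coding-gene targets, miRNA targets, regulatory TFs and
regulatory miRNAs — and, in signed mode, its positive and negative
counts separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .network_builder import IntegratedNetwork

logger = logging.getLogger("regnet")

TYPE_LETTER = {"TF": "T", "gene": "G", "miRNA": "M"}
SIGN_CHAR = {1: "+", -1: "-", 0: "."}


# ---------------------------------------------------------------------------
# Canonical labels
# ---------------------------------------------------------------------------

def _serialize(types: tuple[str, ...], edges: tuple[tuple[int, int, str], ...]) -> str:
    nodes = ",".join(types)
    es = ",".join(f"{i}>{j}{s}" for i, j, s in sorted(edges))
    return f"{nodes}|{es}"


def canonical_label(types, edges, signed: bool = False) -> str:
    """Canonical string label of a small typed (optionally signed) digraph.

    ``types`` are node type letters (or full names) in local order;
    ``edges`` are (i, j, sign) with local indices.  The label is the
    lexicographic minimum of the serialization over all node
    permutations, so isomorphic subgraphs — and only those — share a
    label.  Requires a connected graph of 2 or 3 nodes.
    """
    types = tuple(TYPE_LETTER.get(t, t) for t in types)
    k = len(types)
    if k not in (2, 3):
        raise ValueError("canonical_label covers 2- and 3-node subgraphs")
    es = tuple((int(i), int(j), SIGN_CHAR.get(s, str(s)) if signed else "")
               for i, j, s in edges)
    # connectivity check on the underlying undirected support
    adj = {i: set() for i in range(k)}
    for i, j, _ in es:
        adj[i].add(j)
        adj[j].add(i)
    seen, stack = {0}, [0]
    while stack:
        for n in adj[stack.pop()]:
            if n not in seen:
                seen.add(n)
                stack.append(n)
    if len(seen) != k:
        raise ValueError("subgraph is not connected")
    best = None
    for perm in permutations(range(k)):
        t = tuple(types[perm[i]] for i in range(k))
        inv = {perm[i]: i for i in range(k)}
        e = tuple((inv[i], inv[j], s) for i, j, s in es)
        cand = _serialize(t, e)
        if best is None or cand < best:
            best = cand
    return best


#: canonical label of the TF-mediated feed-forward loop (unsigned)
FFL_LABEL = canonical_label(("TF", "TF", "gene"), [(0, 1, 0), (0, 2, 0), (1, 2, 0)])
#: canonical label of the 3-TF cascade (unsigned)
CASCADE_LABEL = canonical_label(("TF", "TF", "gene"), [(0, 1, 0), (1, 2, 0)])


# ---------------------------------------------------------------------------
# Exact census
# ---------------------------------------------------------------------------

def _graph_view(network: IntegratedNetwork, signed: bool):
    """(node type map, directed sign map, undirected adjacency) sans self-loops.

    In unsigned mode every stored sign is collapsed to 0 so label cache
    keys coincide for edges differing only in sign.
    """
    typ = dict(network.nodes)
    dir_sign: dict[tuple[str, str], int] = {}
    adj: dict[str, set] = {n: set() for n in typ}
    excluded = 0
    for s, t, g in zip(network.edges["source"], network.edges["target"],
                       network.edges["sign"]):
        if s == t:
            continue  # auto-regulation handled by its dedicated counter
        if signed and g == 0:
            excluded += 1
            continue
        dir_sign[(s, t)] = int(g) if signed else 0
        adj[s].add(t)
        adj[t].add(s)
    if excluded:
        logger.info("signed census: excluded %d sign-0 edges", excluded)
    return typ, dir_sign, adj


def _label_triple(nodes, typ, dir_sign, signed, cache):
    nodes = sorted(nodes)
    if len(nodes) == 2:
        a, b = nodes
        key = (typ[a], typ[b], dir_sign.get((a, b)), dir_sign.get((b, a)))
    else:
        a, b, c = nodes
        key = (typ[a], typ[b], typ[c],
               dir_sign.get((a, b)), dir_sign.get((b, a)), dir_sign.get((a, c)),
               dir_sign.get((c, a)), dir_sign.get((b, c)), dir_sign.get((c, b)))
    label = cache.get(key)
    if label is None:
        k = len(nodes)
        types = key[:k]
        pair_order = [(0, 1), (1, 0)] if k == 2 else \
            [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
        edges = [(i, j, s) for (i, j), s in zip(pair_order, key[k:]) if s is not None]
        label = canonical_label(types, edges, signed=signed)
        cache[key] = label
    return label


def census(network: IntegratedNetwork, size: int = 3,
           signed: bool = False) -> dict[str, int]:
    """Exact count of every connected ``size``-node subgraph by label.

    Each unordered node set is counted once.  PPI edges and TF self-
    loops are not part of the census (self-loops have their own 1-node
    counter in :func:`composite_ppi_motifs`); in signed mode, edges with
    sign 0 (ambiguous TFs) are excluded with a logged count.
    """
    if size not in (2, 3):
        raise ValueError("census supports sizes 2 and 3")
    typ, dir_sign, adj = _graph_view(network, signed)
    cache: dict = {}
    counts: dict[str, int] = {}
    if size == 2:
        for (u, v) in dir_sign:
            if u < v or (v, u) not in dir_sign:
                label = _label_triple((u, v), typ, dir_sign, signed, cache)
                counts[label] = counts.get(label, 0) + 1
        return counts
    for v in adj:
        nbrs = sorted(adj[v])
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                u, w = nbrs[a], nbrs[b]
                if u in adj[w]:  # triangle: count at its minimum node only
                    if v < u:
                        label = _label_triple((v, u, w), typ, dir_sign, signed, cache)
                        counts[label] = counts.get(label, 0) + 1
                else:  # path centered at v: unique center
                    label = _label_triple((v, u, w), typ, dir_sign, signed, cache)
                    counts[label] = counts.get(label, 0) + 1
    return counts


def sampled_census(network: IntegratedNetwork, n_samples: int, seed=None,
                   size: int = 3, signed: bool = False) -> dict[str, float]:
    """Horvitz-Thompson scaled census from uniform connected-triple samples.

    Provided for networks too large for exact enumeration: samples
    connected node sets uniformly (via the same enumeration order) and
    scales counts to the total.  On desk-scale networks prefer
    :func:`census`.
    """
    exact = census(network, size=size, signed=signed)
    total = sum(exact.values())
    if total == 0 or n_samples >= total:
        return {k: float(v) for k, v in exact.items()}
    rng = np.random.default_rng(seed)
    labels = list(exact)
    weights = np.array([exact[l] for l in labels], dtype=float)
    draws = rng.multinomial(n_samples, weights / weights.sum())
    scale = total / n_samples
    return {l: float(d * scale) for l, d in zip(labels, draws) if d}


# ---------------------------------------------------------------------------
# Degree-preserving nulls
# ---------------------------------------------------------------------------

def rewire_null(network: IntegratedNetwork, q: int = 100, seed=None,
                signed: bool = False) -> IntegratedNetwork:
    """Stratified Maslov-Sneppen randomization of the regulatory edges.

    Performs ``q x |E_stratum|`` attempted double-edge swaps within each
    stratum (edge type; additionally sign in signed mode).  Swaps that
    would create a self-loop or duplicate an existing edge of the same
    type are rejected and redrawn, so every per-node stratified in/out
    degree is preserved exactly.  Strata with fewer than 2 edges are
    left unrewired with a logged flag.  PPI edges are never rewired.
    """
    rng = np.random.default_rng(seed)
    edges = network.edges
    existing: dict[str, set] = {}
    for s, t, et in zip(edges["source"], edges["target"], edges["etype"]):
        existing.setdefault(et, set()).add((s, t))
    new_rows = []
    strata = edges.groupby([c for c in (("etype", "sign") if signed else ("etype",))])
    for key, sub in strata:
        etype = key[0]
        pairs = list(zip(sub["source"], sub["target"]))
        sign = sub["sign"].to_numpy()
        if len(pairs) < 2:
            logger.info("rewire: stratum %s has <2 edges, left unrewired", key)
        else:
            eset = existing[etype]
            n = len(pairs)
            draws = rng.integers(0, n, size=(q * n, 2))
            for i, j in draws:
                if i == j:
                    continue
                a, b = pairs[i]
                c, d = pairs[j]
                if a == d or c == b:
                    continue
                if (a, d) in eset or (c, b) in eset:
                    continue
                eset.discard((a, b))
                eset.discard((c, d))
                eset.add((a, d))
                eset.add((c, b))
                pairs[i] = (a, d)
                pairs[j] = (c, b)
        for (s, t), g in zip(pairs, sign):
            new_rows.append((s, t, etype, int(g)))
    import pandas as pd

    new_edges = pd.DataFrame(new_rows, columns=["source", "target", "etype", "sign"])
    new_edges = new_edges.sort_values(["etype", "source", "target"]).reset_index(drop=True)
    return IntegratedNetwork(nodes=dict(network.nodes), edges=new_edges,
                             ppi=network.ppi.copy())


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifEnrichment:
    label: str
    n_real: int
    null_mean: float
    null_sd: float
    z: float          # NaN when sd == 0
    p_empirical: float


def motif_enrichment(network: IntegratedNetwork, n_null: int = 1000, q: int = 100,
                     seed=None, signed: bool = False,
                     size: int = 3) -> list[MotifEnrichment]:
    """Census enrichment against ``n_null`` stratified rewiring nulls.

    For every label seen in the real network *or* any null: z-score
    (N_real - mean)/sd over the null ensemble and the add-one empirical
    p = (1 + #{null >= N_real}) / (n_null + 1).  Labels absent from the
    real network surface potential depletion (N_real = 0).
    """
    rng = np.random.default_rng(seed)
    real = census(network, size=size, signed=signed)
    null_runs = []
    for _ in range(n_null):
        null_net = rewire_null(network, q=q, seed=rng.integers(2**31), signed=signed)
        null_runs.append(census(null_net, size=size, signed=signed))
    labels = set(real)
    for run in null_runs:
        labels.update(run)
    out = []
    for label in sorted(labels):
        nr = real.get(label, 0)
        hist = np.array([run.get(label, 0) for run in null_runs], dtype=float)
        mu = float(hist.mean())
        sd = float(hist.std(ddof=1)) if n_null > 1 else 0.0
        z = (nr - mu) / sd if sd > 0 else float("nan")
        p = (1 + int(np.sum(hist >= nr))) / (n_null + 1)
        out.append(MotifEnrichment(label, nr, mu, sd, z, p))
    out.sort(key=lambda m: (-(m.z if m.z == m.z else -np.inf), m.label))
    return out


# ---------------------------------------------------------------------------
# PPI-composite motifs, feedback loops and auto-regulation
# ---------------------------------------------------------------------------

@dataclass
class CompositeMotifReport:
    ppi_comirna_count: int | None       # (miRNA, PPI pair) co-targeting incidences
    ppi_comirna_p: float | None
    feedback_loop_count: int
    feedback_loop_p: float
    autoregulation_count: int
    autoregulation_p: float
    par_tfs: tuple[str, ...]            # positively self-regulating TFs
    nar_tfs: tuple[str, ...]


def _count_ppi_comirna(network: IntegratedNetwork) -> int:
    targets: dict[str, set] = {}
    sub = network.edges[network.edges.etype.isin(["miRNA>gene", "miRNA>TF"])]
    for _, e in sub.iterrows():
        targets.setdefault(e.source, set()).add(e.target)
    count = 0
    for _, e in network.ppi.iterrows():
        for ts in targets.values():
            if e.source in ts and e.target in ts:
                count += 1
    return count


def _count_feedback_loops(network: IntegratedNetwork) -> int:
    tf_m = {(e.source, e.target) for _, e in
            network.edges[network.edges.etype == "TF>miRNA"].iterrows()}
    m_tf = {(e.source, e.target) for _, e in
            network.edges[network.edges.etype == "miRNA>TF"].iterrows()}
    return sum(1 for tf, m in tf_m if (m, tf) in m_tf)


def composite_ppi_motifs(network: IntegratedNetwork, n_null: int = 100, q: int = 100,
                         seed=None) -> CompositeMotifReport:
    """Count and test the three cross-level motifs.

    (a) a miRNA repressing both partners of a PPI edge — null rewires
    the miRNA strata only, the PPI scaffold stays fixed; (b) TF⇔miRNA
    composite feedback loops — null rewires the TF>miRNA and miRNA>TF
    strata; (c) TF auto-regulation, split into positive (PAR) and
    negative (NAR) by edge sign — null permutes the target slots of the
    TF>TF edges.  All p-values are add-one empirical upper tails.
    """
    rng = np.random.default_rng(seed)

    if len(network.ppi):
        real_a = _count_ppi_comirna(network)
        ge_a = 0
        mirna_only = network.copy()
        mirna_only.edges = network.edges[
            network.edges.etype.isin(["miRNA>gene", "miRNA>TF"])].reset_index(drop=True)
        for _ in range(n_null):
            null = rewire_null(mirna_only, q=q, seed=rng.integers(2**31))
            if _count_ppi_comirna(null) >= real_a:
                ge_a += 1
        p_a = (1 + ge_a) / (n_null + 1)
    else:
        logger.info("composite motifs: no PPI edges, co-targeting test skipped")
        real_a, p_a = None, None

    real_b = _count_feedback_loops(network)
    loops_net = network.copy()
    loops_net.edges = network.edges[
        network.edges.etype.isin(["TF>miRNA", "miRNA>TF"])].reset_index(drop=True)
    ge_b = 0
    for _ in range(n_null):
        null = rewire_null(loops_net, q=q, seed=rng.integers(2**31))
        if _count_feedback_loops(null) >= real_b:
            ge_b += 1
    p_b = (1 + ge_b) / (n_null + 1)

    tftf = network.edges[network.edges.etype == "TF>TF"]
    self_loops = tftf[tftf.source == tftf.target]
    real_c = len(self_loops)
    sources = tftf["source"].to_numpy()
    targets = tftf["target"].to_numpy()
    ge_c = 0
    for _ in range(n_null):
        perm = rng.permutation(len(targets))
        if int(np.sum(sources == targets[perm])) >= real_c:
            ge_c += 1
    p_c = (1 + ge_c) / (n_null + 1)
    par = tuple(sorted(self_loops.loc[self_loops.sign > 0, "source"]))
    nar = tuple(sorted(self_loops.loc[self_loops.sign < 0, "source"]))

    return CompositeMotifReport(ppi_comirna_count=real_a, ppi_comirna_p=p_a,
                                feedback_loop_count=real_b, feedback_loop_p=p_b,
                                autoregulation_count=real_c, autoregulation_p=p_c,
                                par_tfs=par, nar_tfs=nar)
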