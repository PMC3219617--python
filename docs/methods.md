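# Methods

This note records the models, conventions and open design choices
behind `regnet`, in the spirit of a model-documentation page: what is
computed, under which assumptions, and what the bundled simulations do
and do not establish.

## Coordinates and annotation model

All internal coordinates are 0-based half-open (the BED convention);
GFF3 input is converted on read and restored on write, so
read→write→read is the identity. The TSS of a + strand feature is its
interval start; of a − strand feature, `end − 1`. A pre-miRNA's
"start position" is defined the same way — the strand-aware 5′ end of
the hairpin locus. Annotation dialects differ in how they encode
pre-miRNAs; we accept a dedicated `pre_miRNA` feature type. Unknown
feature types are skipped with a logged count, never silently.

## TF target calling

A gene is a target of a TF when the **center** of at least one peak
lies in the promoter window of any of its transcripts; membership is
decided on the center, while HOT-region exclusion removes peaks by
**overlap** — the two rules are deliberately different because they
answer different questions (where is the binding event, versus does it
touch a promiscuous locus). The default window is 1,000 bp upstream to
500 bp downstream of the TSS, with `strict` (500/300) and `relaxed`
(2000/500) presets. The window is half-open: position `t − upstream`
is included, `t + downstream` excluded; for − strand features the
window mirrors to `[t − downstream + 1, t + upstream + 1)`. The choice
of boundary inclusion is a convention the data cannot distinguish;
both the boundary and the presets are parameters.

HOT regions are found by a sweep line equivalent to sliding a 400-bp
window across the genome: a position is HOT-covered when peaks of at
least `threshold` **distinct** TFs (a TF's multiple conditions count
once) overlap the window centered there; maximal covered runs are
merged. The reference threshold of 15 factors corresponds to a panel
of 22 assayed TFs; `auto_hot_threshold` rescales it as
`ceil(15/22 × n_assayed)` so smaller panels keep the same occupancy
fraction. Edges from a TF's multiple conditions are unioned by
default; per-condition networks remain available by calling per
peak set.

## Regulator sign classification

The ±2 kb around each transcript TSS is divided into 40 bins of
100 bp, ordered 5′→3′; a read contributes (overlap with bin)/(read
length) to each bin it touches. Per bin, the Pearson correlation
between signal and `log2(x+1)`-transformed expression is computed
across transcripts (≥10 required). The classification rule — which
the source material describes only as "consistent" correlation — is
operationalized as: *consistency* = the larger fraction of defined
bins sharing one correlation sign; a TF is positive/negative when
consistency ≥ 0.7 and the mean correlation has that sign, else
ambiguous. Bins with zero signal variance have no defined correlation
and are dropped from the denominator. Cutoff, log transform and the
expression condition paired with each TF (default: the ChIP
experiment's own stage) are all parameters. Under a structureless
null — binding noise independent across bins, expression unrelated —
bin-correlation signs are near-independent coin flips, so at cutoff
0.7 the chance of a non-ambiguous call is ≈ 2·P[Binom(40, ½) ≥ 28] ≈
1.7 %; the acceptance script measures this rate by simulation. When
binding has real cross-transcript structure but expression is merely
uncorrelated, bin correlations share a common random component and the
false-call rate is higher — a limitation of any consistency-based
rule, mitigated by the magnitude of the mean correlation being
reported alongside the class.

Ambiguous TFs propagate sign 0; such edges are excluded (with a
logged count) from the signed census only. All miRNA edges are signed
−1: miRNA regulation is repressive by mechanism.

## Network assembly and topology

The gene universe is the intersection of the two input universes:
genes with an annotated TSS *and* at least one annotated 3′UTR.
Edges touching excluded genes are dropped with logged counts; the
filter is idempotent. TF→TF self-loops (auto-regulation) are the only
permitted self-edges. PPI edges live in the same structure but are
never counted in regulatory degrees and never rewired in regulatory
nulls.

Degree histograms (regulatory TFs per gene, per miRNA, regulatory
miRNAs per gene, targets per miRNA) are fitted by least squares of
`ln(count)` against degree — `count ∝ exp(−λk)` — over occupied
degree bins only; zero-count bins are excluded rather than
pseudocounted, and fits with fewer than three occupied degrees are
skipped. The fit is on the raw histogram, not the cumulative
distribution; with sparse tails the log-scale R² is noticeably noisy,
which the fit-recovery simulation quantifies. Shared-target
enrichment between regulator pairs uses the upper-tail hypergeometric
p over the network's target universe; Benjamini–Hochberg q-values are
reported as an additional column without replacing the raw statistic.

## Hierarchy

The TF core hierarchy uses only TF→TF edges, ignoring self-loops:
TFs regulated by no *other* TF form the top layer; of the remainder,
TFs that regulate no other TF form the bottom; everything else —
regulating and regulated — is the middle. This three-bucket rule
leaves one case the original description does not address: a TF
regulated only by middle-layer TFs (never by a top TF). Our rule
places it in the middle, which guarantees a total assignment for any
digraph, including cycles. miRNAs are layered by sequential set
difference — first those repressing a top TF (layer 1, drawn above
the TF layers), then of the rest those repressing a middle TF, then a
bottom TF, then miRNAs with only incoming edges (layer 4) — so the
four miRNA layers partition the miRNA set and a miRNA hitting both
top and bottom TFs resolves upward. Per-layer property comparisons
(PPI degree, regulatory-miRNA count, tissue specificity,
essentiality) use Kruskal–Wallis across layers, pairwise rank-sum
tests, and Fisher's exact test for bottom-vs-top essentiality
enrichment; layers with fewer than two values skip the tests but keep
the means.

## Motif census and nulls

2- and 3-node connected subgraphs of the regulatory layers are
enumerated **exactly** (triangles counted at their minimum node, paths
at their center), rather than estimated by subgraph sampling as
FANMOD-class motif tools do — desk-scale networks make the
approximation unnecessary; a Horvitz–Thompson-scaled sampling mode
exists for large inputs. Labels are canonical forms: the lexicographic minimum over
all node permutations of the typed (T/M/G), directed, optionally
signed edge serialization, so isomorphic subgraphs — and only those —
share a label. Auto-regulation self-loops are excluded from the
triple census and counted by their own one-node counter.

Null networks are produced by Maslov–Sneppen double-edge swaps within
each edge-type stratum (TF→gene, TF→TF, TF→miRNA, miRNA→gene,
miRNA→TF), and within (type, sign) strata in signed mode; swaps that
would create a self-loop or duplicate an edge of the same type are
rejected and redrawn, so every per-node stratified in/out degree —
and, in signed mode, every per-node positive/negative degree — is
preserved exactly. The swap budget is Q = 100 attempted swaps per
edge, enough for the edge overlap with the original network to reach
its asymptote; Q is exposed as a parameter. Enrichment reports both
z = (N_real − μ)/σ over the ensemble — the z formula itself being the
standard one — and the add-one empirical p = (1 + #{null ≥
N_real})/(N + 1), which can never be exactly 0; labels present only
in nulls are reported with N_real = 0 as the depletion surface. σ = 0
(a count the null cannot change) flags z as undefined with p = 1.

Three cross-level motifs have dedicated permutation tests: a miRNA
repressing both partners of a PPI edge (null rewires miRNA strata
only, PPI fixed); reciprocal TF⇔miRNA feedback loops (null rewires
both connecting strata); and TF auto-regulation split into positive
and negative by the TF's sign (null permutes the target slots of the
TF→TF edges).

## Tissue/stage specificity

The specificity score of an expression row is the relative entropy of
its fractional profile against the uniform null, Σ p_i log2(p_i·K),
with 0·log 0 = 0: zero for uniform expression, log2 K for a point
mass. The logarithm base (here 2, i.e. bits) is a pure rescaling and
is exposed as a parameter; bounds are stated base-aware. An all-zero
row is an error, not a zero score. Stage specificity is the same
score over the stage axis.

## Host-gene analysis

Intron containment takes the strictest isoform reading: the pre-miRNA
must avoid the exons of *every* transcript of the candidate host.
Strand bias uses the exact one-sided binomial tail P[X ≥ n_sense] at
p₀ = ½, computed in log space (the log tail stays finite far beyond
double-precision underflow). For the worm-scale count of 39 sense
pairs among 60 the exact test gives p ≈ 0.0138, not the 0.007
sometimes quoted for that configuration; the test behind the quoted
figure is not documented, so we report the exact tail and note the
discrepancy rather than reverse-engineer it. The miRNA-host network
connects m_a → host(m_b) whenever the host is a predicted target of
m_a, flagging a = b as auto-regulation; antisense pairs are excluded
since co-transcription is the premise.

## Synthetic regulome

The generator is the package's study-condition definition, not a
tuning surface. Defaults: 1,000 genes (3 exons, ≥2.5 kb apart so
promoter windows cannot collide between genes), 60 annotated TFs of
which 20 are assayed, 60 miRNAs, 8 tissues, 7 stages — the reference
panel's proportions at desk scale. 34 % of miRNAs are intronic
(60/174 in the reference annotation), sense-embedded with probability
0.8 (the human-scale fraction 482/588 ≈ 0.82). Every true TF edge
receives one peak whose center is normal-jittered (σ = 250 bp) and
truncated to the default promoter window, so truth is recoverable by
construction; background peaks are uniform (Poisson mean 40 per TF),
and HOT loci are built by stacking peaks of 16 distinct TFs in 400-bp
windows. Expression in log2 space is baseline + Σ sign·β·binding
amplitude + noise (β = 1, σ_noise = 0.3), with the binding profile
strictly positive across all 40 bins so a true regulator's bin
correlations share its sign. True miRNA edges are realized as seed
sites conserved in at least the 3-way species set (all five with
probability 0.6); decoys are conserved in ≤2 species and can never
pass the filter. All draws descend from one integer seed through
fixed-offset sub-streams, so partial reruns reproduce.

What the generator does **not** emulate: nucleotide sequence (sites
are positional records), read-level noise, correlated TF binding (TFs
choose targets independently except planted motifs), expression
dynamics across stages (stages differ only by noise), and realistic
PPI topology (Erdős–Rényi). Consequently, passing parameter-recovery
tests shows the algorithms implement their definitions correctly
under the stated noise model — not that the defaults are optimal for
real ChIP-Seq data.

One interaction worth knowing: intergenic pre-miRNAs sit midway in
the ≥2.5 kb inter-gene gaps, so a gene's promoter window can contain
a nearby miRNA anchor (and vice versa). With zero background peaks,
target calling therefore attains exact recall and ~95–100 % precision
— the residual false positives are these genuine window coincidences,
not algorithmic errors.

## Problem sizes and determinism

Default analysis sizes were chosen to keep a full pipeline run (two
motif-enrichment passes at 100 nulls each) in the minutes range on one
core: exact census cost grows as Σ_v deg(v)², about 10⁵ triples at
the default scale. The acceptance script uses 60 random graphs for
census/oracle agreement, 50 rewiring invariance checks, 100 nulls for
planted-motif enrichment, 60 null classifications, exhaustive 4-node
plus 20,000 sampled 5-node digraphs for the hierarchy rules, and
n = 2,000 for fit recovery. Every artifact is deterministic given the
seed; the pipeline manifest records SHA-256 checksums to make this
checkable.
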