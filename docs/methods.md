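# Methods

## Problem and model

Affymetrix 3'-IVT expression chips quantify a transcript's 3' end with probe
sets of 11–16 probes. Many genes carry several *alternative* probe sets that
map to different regions of the same gene; whether two alternative probe sets
respond identically (and therefore probably target the same transcripts) is
not decidable from sequence annotation alone. probesim decides it from
*covariation*: each probe set carries an ordered string of ternary calls —
increased (I), decreased (D) or not changed (N) — over a fixed series of
condition-versus-condition comparisons (the calls themselves are produced
upstream by a rank-difference analysis and are an input here). Several such
comparison series, each crossing two disjoint groups of biological
conditions (g×g comparisons per series), give several *networks*, and the
consistency of a pair's behaviour across networks is what defines its
similarity.

### Covariation networks

For two call strings, positions where both calls are N carry no information.
Over the informative positions,

    corr = 100 · #(II or DD) / n_informative
    anti = 100 · #(ID or DI) / n_informative.

Positions with exactly one N are informative but neither concordant nor
discordant: they dilute both percentages, which is the desired behaviour for
noisy probe sets. Pair values enter a network only when they beat an
empirical null built from random probe-set pairs of the same call matrix:
the add-one upper-tail estimate p = (#null ≥ value + 1)/(n + 1), kept at
p ≤ α (default α = 0.05; the null has 2000 pairs sampled without
replacement, or all pairs when fewer exist). Each network gets its own null
because each network has its own comparison series. Pairs with zero
informative positions are excluded entirely.

### Neighbourhood overlap

The neighbourhood of a probe set is the set of probe sets it has a stored
significant *positive* correlation with (negative partners are excluded by
default but available as an option). For two neighbourhoods of sizes N1, N2
in a network of M probe sets, the chance of an overlap of at least N is the
hypergeometric tail

    p = Σ_{k=N..min(N1,N2)} C(N1,k)·C(M−N1,N2−k) / C(M,N2),

carried as log10 p (computed in log space via `scipy.stats.hypergeom.logsf`,
finite for M up to ~1e5). The population is the network, not the chip,
because neighbourhoods are network-relative.

### Calibration and the three-condition similarity test

Bona fide similar pairs should be positively correlated in *every* network.
The calibration set is exactly those alternative pairs (by default further
restricted to pairs whose two members each target a single gene, removing
cross-hybridisation ambiguity). Their per-network corr, anti and log10
overlap values are pooled over pairs × networks, and three limits are taken
as nearest-rank percentiles of the pooled distributions:

    corr_5th   = 5th percentile of positive correlations
    anti_95th  = 95th percentile of negative correlations
    overlap_95th = 95th percentile of the overlap log10 p-values.

A pair is similar in network i iff

    corr_i ≥ corr_5th  and  anti_i ≤ anti_95th  and  overlap_i ≤ overlap_95th,

with absent (filtered) values entered as 0 for corr and anti and as
log10 p = 0 (p = 1) for the overlap, so that non-significance never helps a
pair pass the corr or overlap conditions. Limits are applied unrounded;
display rounds to integers. The fraction of networks passed maps to a
similarity class: 0 (never), 1 (at least one network), 25/50/75 (at least
that percentage), 100 (all networks). Classes are reported per pair and are
monotone in the pass count by construction.

Reproducibility between two runs/chips uses the equivalence bands
{0, 1} and {75, 100}: rep0 is the percentage of class-0 pairs of the first
run falling in {0, 1} in the second, rep100 analogously for class 100; a
gene-level variant conditions on genes whose pairs are all in one extreme
class.

## Biclusters and gene assignment

The probe-set/gene targeting relation at a probe-number limit (a cell is set
when the probe set places at least `limit` probes in the gene; default 7,
with 1 also supported) forms a bipartite graph. Biclusters are its connected
components, found by an alternating closure from a seed probe set; the
number of alternation steps needed defines the component depth. Because
depth depends on the seed, a component's depth is the *minimum* over all its
probe-set seeds, which makes the class label seed-order invariant:
SS/SM/MS for single-sided components, and MM (depth 1), CX (depth 2),
HX (depth ≥ 3) for multiple×multiple components. Cell density is reported
but never used for classification.

Each probe set is assigned to exactly one gene by a six-criterion cascade:
most targeting probes; best target type (exon > intron > upstream >
downstream, compared first by category then by the probe count in the best
category); maximal ratio of targeting probe sets to transcript-groups
(probe sets grouped by identical targeted-transcript sets); fewest targeting
probe sets; gene source (Ensembl > AceView > GOP); alphabetic order.
Alternative pairs are pairs of probe sets assigned to the same gene.

## Grouping similar probe sets

Within a similarity class, all triangles of pairwise-similar probe sets are
found and triangles sharing an edge (two probe sets) are merged; a group's
members are the union of its triangles' vertices. Member pairs that are not
themselves similar ("bad links") are recorded — aggregating (ABC) and (ABD)
admits the possibly dissimilar pair (C, D). Two triangles sharing a single
probe set stay separate and the shared probe set is listed as a pivot.
Similar pairs belonging to no triangle form two-member groups (dropping them
would silently lose similar pairs); such groups do not create pivots.
Groups sharing only a pivot are never merged.

## Network reduction and Markov clustering

Groups of similar probe sets can be collapsed to single nodes whose corr and
anti values against the rest of the network are the arithmetic means of the
members' values (absent entries counted as 0); intra-group edges are
dropped. MCL is implemented in-package and runs on the positive-correlation
matrix only (negative correlations are not valid random-walk weights), with
self-loops at each node's maximum incident weight, column normalisation, and
the expansion → inflation (default 2.0) → pruning (default threshold 1e-4)
loop until the elementwise change falls below 1e-8 (at most 100 iterations).
Clusters are read from attractors (positive diagonal); ties in the node
assignment go to the lexicographically smallest attractor. The pruning score
is floor(100 · mean retained column mass at the pruning steps) — 100 means
pruning discarded nothing. Clustering reproducibility between two results is
the weighted mean, over the k (default 10) largest clusters of the first,
of 100·|common|/√(|c_a|·|c_b|) against the best-overlapping cluster of the
second, with weights 1/√(|c_a|·|c_b|).

## Rank-difference analysis

Raw signals are rank-normalised per biological condition (average-tie ranks
mapped to 0–100). For each alternative pair the empirical CDF of the
absolute rank difference over conditions is evaluated on the integer grid
0..100, and classes report the pointwise mean CDF over their pairs, with a
seeded random-pair reference class. Higher similarity should give
stochastically smaller rank differences.

## Synthetic data

The generator emulates the pipeline's inputs with planted ground truth.
Latent *modules* draw a call per comparison with P(I) = P(D) = p_change;
each probe set copies its module's call, substitutes N with probability ε
and flips I↔D with probability δ, independently per position. Probe sets of
the same gene either share one module (planted "same" pairs), use
sign-flipped copies of one module ("anti"), or get independent modules.
Signals are exp-transformed module levels (s.d. 2.0) plus unit noise, so
same-module pairs are rank-correlated. The annotation table plants shared
transcripts and exons for same-module pairs (including the flipped group of
an anti gene, which is a module of its own) and disjoint ones otherwise.
Everything regenerates byte-identically from one seed, with per-network
sub-seeds so single networks can be regenerated alone.

Default conditions: 200 genes, 1–3 probe sets per gene (uniform), 5
networks from 10×10 cross designs over disjoint fresh condition groups
(so 100 conditions), p_change = 0.25, ε = 0.2, δ = 0.02, half of the
multi-probe-set genes planted "same" and 10% "anti". These sizes keep a
full fit under a second while leaving ~250 alternative pairs and a
404-probe-set network — enough for stable percentile calibration. Under
these conditions an independent pair's expected concordance among
informative positions is 2p²/(1−(1−2p)²) ≈ 16.7%, far below the
calibrated corr_5th (~52), while same-module pairs sit near 64%.

What the generator does *not* emulate: probe-level intensities and the
upstream call-making, cross-hybridisation, correlated condition structure
between networks (real networks share condition groups; synthetic ones do
not), chip-specific probe-set universes, and realistic transcript/exon
architectures. Passing the planted-recovery tests therefore shows the
machinery is correct and well-calibrated under the stated noise model, not
that any particular chip's published similarity tables are reproduced.

## Numerical and design choices

- Nearest-rank (ceiling) percentiles everywhere, so limits computed from
  integer-valued pools are reproducible integers.
- Degenerate pairs (no informative position) report (0, 0) with a flag and
  never enter networks.
- Null sampling is without replacement over unordered pairs; when the
  requested sample exceeds the number of distinct pairs, all pairs are used
  and the fact is logged.
- α defaults to 0.05 and is configurable; edge sets shrink monotonically as
  α decreases.
- The neighbourhood definition (positive-only partners) and the calibration
  pool (per-network values pooled, not per-pair means; single-gene filter)
  are configurable where the design was genuinely open.
- GOPs: probes on one chromosome/strand are sorted internally and split
  where the inter-probe gap exceeds 2000 bases (a gap of exactly 2 kb stays
  together).
- Exon-probe sharing scores attribute a probe set's exon-located probes
  uniformly over its targeted exons, because the annotation records per-set
  counts, not per-exon counts; the last-exon score summarises a pair by the
  maximum of the two members' last-exon fractions.
- Localisation summaries default to pairs of single-gene probe sets with at
  least 11 probes on the common gene.

## Known limitations

- The empirical null treats random pairs as exchangeable; on tiny universes
  dominated by planted co-varying pairs the null is contaminated and the
  significance filter loses power (the synthetic defaults avoid this by
  construction).
- The MCL pruning score is this implementation's retained-mass definition;
  other MCL implementations report differently computed scores on the same
  0–100 orientation.
- Gene-level reproducibility requires both runs to provide assignments over
  comparable gene identifier spaces; no identifier mapping is attempted.
- Per-comparison correlated-pair statistics use raw concordance/discordance
  of single comparisons without a per-comparison significance filter (no
  such null exists for a single position).
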