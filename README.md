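# probesim

Estimating the similarity of **alternative microarray probe sets** —
distinct Affymetrix probe sets that map to different regions of the same
gene — from **transcriptional covariation networks**.

On 3'-IVT Affymetrix chips, up to two thirds of probe sets share their gene
with another probe set. Whether two such probe sets respond identically
(and so probably measure the same transcripts) matters for anyone
interpreting differential-expression results, and especially for detecting
3' alternative poly-adenylation, where alternative probe sets *should*
diverge. Sequence annotation alone cannot settle the question; probesim
settles it from behaviour across many biological conditions.

## The method

Each probe set carries a ternary call string over a series of
condition-vs-condition comparisons: **I** (increased), **D** (decreased),
**N** (not changed). For a pair of probe sets, over the informative
positions (at least one call ≠ N):

```
corr = 100 · #(II or DD) / n_informative     (positive correlation, %)
anti = 100 · #(ID or DI) / n_informative     (negative correlation, %)
```

Values that do not beat an empirical random-pair null (p ≤ α, add-one
upper-tail estimate) are discarded, leaving one sparse CORR/ANTI network per
comparison series. A pair's neighbourhood overlap in a network of M probe
sets is scored by the hypergeometric tail P(overlap ≥ N | N1, N2, M),
carried as log10 p.

Pairs positively correlated in **all** networks calibrate three limits —
corr^5th, anti^95th, overlap^95th (nearest-rank percentiles of the pooled
per-network values) — and a pair is *similar in network i* iff

```
corr_i ≥ corr^5th   and   anti_i ≤ anti^95th   and   overlap_i ≤ overlap^95th .
```

The fraction of networks passed maps to a similarity class
**0 / 1 / 25 / 50 / 75 / 100 %**. Downstream, the package classifies
probe-set/gene biclusters (SS/SM/MS/MM/CX/HX by shape and recursion depth),
assigns each probe set to a single gene, aggregates similar probe sets into
groups via shared-edge triangles (with pivots and "bad links"), relates
similarity to shared transcripts/exons, compares per-condition signal ranks
across classes, and merges similar probe sets before Markov clustering
(MCL) of the network.

## Worked example

Everything runs on seeded synthetic data with planted ground truth — no
downloads. Two hundred genes carry 1–3 probe sets each; probe sets of the
same latent module are planted "same", sign-flipped modules "anti", the
rest independent. Five networks of 10×10 comparisons, 20 % N-substitution
and 2 % I↔D flip noise:

```python
from probesim import (SyntheticSpec, generate_dataset,
                      ProbeSetSimilarity, truth_recovery_report)

dataset, truth = generate_dataset(SyntheticSpec(seed=1))
results = ProbeSetSimilarity(dataset).fit(seed=1)
print(results.summary())
```

```
Probe-set similarity from covariation networks
====================================================
networks:            5
probe sets:          400
alternative pairs:   264
calibration pairs:   118
edge significance:   alpha = 0.05

similarity test limits (calibrated)
  corr_5th    >=     52   (unrounded 52.38)
  anti_95th   <=      0   (unrounded 0.00)
  overlap_95th<=     -1   (log10 p, unrounded -1.18)

similarity class distribution (% of alternative pairs)
    0%:   55.3
    1%:    0.0
   25%:    0.0
   50%:    3.0
   75%:   13.3
  100%:   28.4

groups at class >= 100%: 55 (pivots: 0)
groups at class >= 50%: 66 (pivots: 0)
```

The calibrated limits say: a pair counts as similar in a network when its
positive correlation is at least 52 %, it has no significant negative
correlation, and its neighbourhood overlap is at least ten-fold enriched
(log10 p ≤ −1.18). Scoring against the planted truth:

```python
confusion = truth_recovery_report(truth, results.pairs)
print(confusion)
```

```
similarity_class  0    50   75   100
label
anti               14    0    0    0
independent       132    0    0    0
same                0    8   35   75
```

93.2 % of planted same-module pairs reach class ≥ 75 and 100 % of planted
independent pairs stay at class ≤ 1 — the method separates the two
populations almost perfectly at these noise levels.

The same pipeline is scriptable from the shell:

```
probesim simulate  --seed 1 --out-dir data
probesim similarity --seed 1 --data-dir data --out-dir out
probesim group     --seed 1 --pairs out/pair_similarity.tsv --out-dir out
probesim mcl       --seed 1 --data-dir data --out-dir out
```

(further subcommands: `network`, `biclusters`, `rankdiff`, `compstats`;
all accept `--config` with YAML overrides).

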