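# exocnv

Copy-number variant (CNV) discovery from whole-exome sequencing (WES)
read depth, on a single machine. `exocnv` implements the XHMM-style
pipeline — per-target coverage, PCA-based read-depth normalization, and
3-state hidden-Markov-model calling — together with an iterative
truncated-SVD algorithm that certifies the number of principal
components to remove without computing the full decomposition, and a
synthetic-cohort generator so every stage can be validated against known
ground truth.

It is written for statistical-genetics and methods developers who want a
tested, importable implementation of read-depth CNV calling: every
numerically delicate step (rank selection, Viterbi, scaled
forward–backward, quality scores) is pinned against an independent
brute-force oracle in the test suite.

## The method

**Coverage.** For each sample, the mean per-base depth over each exome
target is computed from coordinate-sorted SAM/BAM alignments, with
GATK-DepthOfCoverage-compatible filtering (mapping quality ≥ 20, no
duplicates/secondary/supplementary reads, overlapping mates counted once
per fragment). The cohort forms an *s* samples × *t* targets read-depth
matrix.

**Normalization.** Systematic biases (capture batch, GC, sequencing
depth) dominate WES depth variance. After protocol filters, the matrix
is target-centered and the top *K* principal components are removed,
where *K* counts the components whose variance v<sub>i</sub> = σ<sub>i</sub>²
satisfies the relative-variance rule

&nbsp;&nbsp;&nbsp;&nbsp;v<sub>i</sub> ≥ 0.7 · Σv / n

for n candidate components. Rather than decompose all n components,
`determine_K` runs a truncated SVD of k components (k = n/10 initially)
and brackets the unknown total variance between

- over-estimate: Σ<sub>i≤k</sub> v<sub>i</sub> + (n−k−1)·v<sub>k</sub>
- under-estimate: Σ<sub>i≤k</sub> v<sub>i</sub>

If the first retained component falls below the cutoff implied by the
under-estimate, *K* is certified exact (it provably equals the
full-spectrum answer); otherwise k is doubled. Each sample row is then
z-scored.

**Discovery.** Per sample, a 3-state HMM over {DEL, DIP, DUP} with
unit-variance normal emissions at means −M, 0, +M (M = 3 z-units) and
distance-attenuated transitions T(d) = f·T0 + (1−f)·Π, f = exp(−d/D)
(D = 70 kb), is decoded with log-space Viterbi. Each called segment gets
five phred-scaled qualities (Q_EXACT, Q_SOME, Q_NON_DIPLOID, Q_START,
Q_STOP) from constrained scaled-forward passes; calls with Q_SOME ≥ 30
are written as an XHMM-style `.xcnv` table.

## Worked example

`examples/03_rank_selection.py` simulates a 40 × 300 cohort with rank-3
batch structure and runs the rank-selection algorithm:

```
candidate components n = 40
computed k = 8 components in 2 iteration(s)
total-variance bracket: [6647537.9, 7373499.2]
K = 4 components certified for removal
full-spectrum rule agrees: K = 4
```

Only 8 of 40 components were decomposed, yet the certified K equals the
exhaustive rule's answer. `examples/04_discover_cnvs.py` continues to
discovery:

```
normalization removed K=4 components; 25 samples x 250 targets survive filtering
28 calls at Q_SOME >= 30:
SAMPLE   TYPE  INTERVAL            NUM_TARG  Q_SOME  MEAN_RD  MEAN_ORIG_RD
SYN001   DEL   2:64401-72599              7      99    -5.18          52.6
SYN004   DUP   2:19594-24775              6      99     5.87         190.9
...
truth recovery: 8 exact + 0 overlap of 8 embedded CNVs
```

A deletion call shows a negative mean z-score (MEAN_RD) and roughly
half-depth raw coverage (MEAN_ORIG_RD ≈ 53x against a ~110x cohort); all
8 embedded CNVs are recovered with exact breakpoints. The remaining
calls arise from residual correlated structure the 0.7/n rule leaves in
place — the expected behavior of this class of caller on low-noise data.

## Command line

```bash
exocnv simulate --out-prefix syn --n-samples 30 --n-targets 500 --seed 1
exocnv coverage sample1.sam sample2.sam --targets targets.bed --out matrix.txt
exocnv normalize matrix.txt --out zscores.txt --orig-out orig.txt
exocnv discover zscores.txt --original orig.txt --out calls.xcnv
exocnv pipeline syn.matrix.txt --out calls.xcnv        # all stages at once
exocnv match calls_a.xcnv calls_b.xcnv                 # concordance report
```

Exit codes: 0 success, 1 data error, 2 usage error.

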