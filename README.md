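# nmfcc — consensus clustering of expression matrices by NMF

`nmfcc` clusters the samples of a non-negative genes × samples expression
matrix (bulk RNA-seq or scRNA-seq counts) by non-negative matrix
factorization with consensus model selection. It is aimed at analysts who
want the classical NMF consensus workflow — many random restarts per
candidate rank, a consensus matrix per rank, cophenetic stability scoring —
as a plain Python library and command-line tool operating on GCT files.

## Method

The expression matrix *V* (*n* genes × *m* samples, all entries ≥ 0) is
approximated as *V ≈ WH* where *W* is *n × k* and *H* is *k × m*, both
non-negative. Each of the *k* factor components is a *metagene*: a
non-negative combination of genes whose sample-wise activity is the
corresponding row of *H*. The factors minimize the generalized
Kullback–Leibler divergence

    D(V ‖ WH) = Σᵢⱼ [ Vᵢⱼ log(Vᵢⱼ / (WH)ᵢⱼ) − Vᵢⱼ + (WH)ᵢⱼ ]

by the standard multiplicative updates (H first, then W, with WH
recomputed in between):

    H_au ← H_au · (Σᵢ W_ia Vᵢᵤ/(WH)ᵢᵤ) / (Σᵢ W_ia)
    W_ia ← W_ia · (Σᵤ H_au Vᵢᵤ/(WH)ᵢᵤ) / (Σᵤ H_au)

Sample *j* is assigned to its dominant metagene, `argmax_a H[a, j]`.
Because the optimization is non-convex, the factorization is repeated
from many random starts for every candidate rank *k* in a user range.
Each run yields a binary *connectivity matrix* (1 where two samples share
a cluster); their average over runs is the *consensus matrix*, whose
entries are the fraction of runs in which two samples co-clustered. A
stable clustering drives the consensus toward a 0/1 block matrix. Per-rank
stability is the *cophenetic correlation coefficient* — the Pearson
correlation between the distances 1 − consensus and the ultrametric
distances of their average-linkage dendrogram — and the rank with the
highest coefficient is selected (ties go to the smaller rank).

Three execution strategies are built in: `serial` (one worker),
`kfactor` (all restarts for one rank assigned wholly to one worker), and
`input-matrix` (every worker holds full *W*, *H* but only a block of *V*
— columns for the H update, rows for the W update — with partial results
exchanged so all workers keep identical factors). Per-run seeds are
derived as `base_seed + 10000·k + run_index`, so all strategies reproduce
the same runs.

## Worked example

Generate a small planted-cluster dataset (3 clusters of 8 samples,
200 genes) and cluster it:

```python
from nmfcc import generate_planted_data, write_gct
d = generate_planted_data(200, 24, 3, separation=5.0, noise_scale=0.5, seed=42)
write_gct(d.matrix, "example.gct")
```

```sh
nmfcc --input example.gct --out-dir results_example \
      --k-min 2 --k-max 4 --num-clusterings 10 --stop-convergence 10 --seed 42
```

The log (stderr) reports per-rank progress and the selection:

```
INFO input example.gct: 200 rows x 24 columns
INFO k=2: 10 runs, mean iterations 101.0, stop causes {'no-change checks': 7, 'divergence delta': 3}, cophenetic 0.994459
INFO k=3: 10 runs, mean iterations 97.0, stop causes {'divergence delta': 5, 'no-change checks': 5}, cophenetic 1.000000
INFO k=4: 10 runs, mean iterations 115.0, stop causes {'no-change checks': 10}, cophenetic 1.000000
INFO selected k = 3
```

At k = 3 every one of the 10 restarts produced the same partition
(cophenetic coefficient 1.0, a perfect 0/1 consensus), and that partition
matches the planted clusters; k = 2 is slightly less stable (0.9945).
k = 4 is also perfectly stable here — its extra cluster is consistently
empty-ish — and the tie is resolved toward the smaller rank among the
maxima, selecting 3 over 4.

The output directory contains, per rank, `consensus.k.<k>.gct` (always),
`consensus.sorted.k.<k>.gct` (dendrogram-sorted; emitted when the input
has under 1,000 columns) and `consensus.k.<k>.pdf` (heatmap; under 100
columns), plus `stability.report.txt`:

```
k	cophenetic	selected
2	0.994459346286088	0
3	1.0	1
4	1.0	0
```

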