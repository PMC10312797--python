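# Methods

## Model and procedure

`nmfcc` factorizes a non-negative genes × samples matrix V as V ≈ WH,
W and H non-negative, minimizing the generalized Kullback–Leibler
divergence D(V‖WH) = Σ [V log(V/WH) − V + WH] with the classical
multiplicative updates. The update order is fixed — H first, then W,
with WH recomputed between the two — because a fixed order is required
for bit-reproducibility. These updates never increase the divergence;
the test suite asserts this within 1e-9·(1+|D|) per step, the slack
covering floating-point accumulation only.

Clustering follows the consensus scheme: for each rank k in a user
range, `num_clusterings` factorizations are run from independent
uniform(0,1) random initializations. Each run assigns every sample to
its dominant metagene (argmax over its H column; ties break to the
smallest index) and is summarized as a binary connectivity matrix. The
per-k consensus matrix is the entrywise mean of these connectivity
matrices, i.e. the *fraction* of runs in which two samples co-cluster.
Storing the fraction rather than the raw count keeps entries in [0,1]
and comparable across different restart counts; the count is always
recoverable as value × n_runs.

Rank stability is scored by the cophenetic correlation coefficient:
Pearson correlation between the condensed distances 1 − consensus and
the cophenetic (ultrametric) distances of their average-linkage
dendrogram, both computed with scipy's hierarchical-clustering
routines. Average linkage is also used to reorder the consensus matrix
for display. The coefficient is undefined (reported as NA) when either
distance vector has zero variance — e.g. a consensus whose off-diagonal
entries are all equal. The selected rank is the one with the maximum
defined coefficient; ties resolve to the smallest rank (parsimony).
A consequence worth knowing: on very clean data several ranks can be
*perfectly* stable (coefficient exactly 1.0) simultaneously — e.g. k=2
may consistently merge the same two of three true clusters — and the
parsimony rule then selects the smallest of the tied ranks, which can
sit below the planted rank. The per-k report makes this visible rather
than hiding it behind a single number.

## Stopping rules

Every `stop_frequency` iterations (default 10) the run evaluates its
connectivity matrix and KL divergence. A run stops when

1. the connectivity matrix has been unchanged for `stop_convergence`
   consecutive checks (default 40),
2. the absolute divergence change between consecutive checks falls
   below `max_error_difference` (default 1e-8), or
3. `max_iterations` is reached (default 2000),

whichever fires first; the cause is recorded on the run result. Both
convergence rules are active simultaneously since no interaction rule
is prescribed for them. Checks begin at iteration `stop_frequency`, not
at iteration 0, so a run always performs at least one update between
checks.

## Numerical choices

- Epsilon floor 1e-16 on the WH product, on update denominators and on
  the factor entries after each update. This guards the divisions and
  logs without perturbing well-scaled problems, and keeps the factors
  strictly positive so the multiplicative updates can never lock onto
  an exact zero.
- Reductions are row-major and the update order is fixed, so a run is
  bitwise reproducible on one backend. Cross-worker agreement for the
  blocked update is required only to 1e-6 relative, since reduction
  order differs across block boundaries.
- Per-run seeds derive as `base_seed + 10000·k + run_index`, making
  every (k, run) pair reproducible independently of scheduling order —
  this is what makes the serial and kfactor strategies produce
  identical consensus matrices.

## Execution strategies and the worker backend

- `serial`: all runs on one worker in (k, run) order.
- `kfactor`: all restarts for one k are assigned wholly to a single
  worker; k values are spread greedily to the least-loaded worker, so
  per-worker loads differ by at most one k's worth of runs. Restarts of
  one k are never split across workers.
- `input-matrix`: every worker participates in every run. The H update
  partitions V by columns, the W update by rows (balanced contiguous
  blocks, larger first); W and H are fully replicated. Each worker
  computes its slice of the updated factor and an allreduce of the
  zero-padded slices reassembles identical complete factors everywhere.
  Convergence checks read the replicated H, so stopping decisions are
  globally consistent. This is the strategy that allows matrices larger
  than a single device's memory.

The backend contract is deliberately minimal — broadcast a matrix and
sum-reduce partials — so a message-passing or accelerator pool can
stand in. The package ships `SimulatedBackend`, which executes the
workers' block computations inside one process while enforcing the same
exchange contract (it verifies post-exchange copies are identical and
raises on divergence). With one worker the blocked update is bitwise
identical to the serial kernel.

## GCT input/output

Input and all matrix outputs use the GCT #1.2 tab-delimited dialect:
version line, `<nrows>\t<ncols>`, a `Name\tDescription\t<samples...>`
header, one row per feature. Values are written with shortest
round-trip (`repr`) precision so consensus fractions such as multiples
of 1/n_runs survive a write/read cycle exactly. Negative input values
are a hard error rather than being shifted — silent shifting would
change the factorization. Duplicate row or column names are rejected.
Per-rank artifacts are gated by input width: the consensus GCT is
always written; the dendrogram-sorted GCT when the input has fewer than
1,000 columns; the PDF heatmap when fewer than 100. Heatmaps use a
fixed [0,1] color scale and strip PDF timestamps so identical inputs
yield identical bytes.

## Synthetic data generator

`generate_planted_data(n_genes, n_samples, k_true, separation,
noise_scale, seed)` builds V = W_true·H_true + half-normal noise,
clipped at zero. W_true has disjoint gene blocks of weight
0.1 + separation over a 0.1 background (disjoint blocks make the
planted metagenes identifiable, removing rotational ambiguity); H_true
elevates each sample's planted cluster by the same separation; samples
are assigned round-robin so clusters are balanced. Defaults are
separation 5.0 and noise_scale 0.1 — a strongly separated, low-noise
regime in which a correct method should recover the planted partition
essentially always, which is what the recovery tests assert. Half-normal
noise is the simplest non-negative noise model and avoids zero-inflating
the signal blocks.

The generator emulates only the block structure NMF assumes. It does
not model dropout, library-size variation or overdispersion, so passing
tests demonstrate algorithmic correctness, not performance on real
scRNA-seq data.

## Problem sizes used in tests

The test suite and `scripts/acceptance.py` run at desk scale: recovery
and rank-stability checks use 500 genes × 60 samples over 20 simulated
datasets (with 8–10 restarts per rank and `stop_convergence` 10);
strategy-equivalence checks use 100 × 30; oracle comparisons use
instances up to 8 × 8 against a triple-loop reference implementation.
These sizes exercise every code path while keeping the full suite under
a minute of compute.

## Known limitations

- Only the KL-divergence objective and uniform random initialization
  are implemented (no Euclidean NMF, no NNDSVD).
- The shipped backend simulates workers in-process; distributed and
  GPU pools must implement the two collectives themselves.
- Model selection offers the cophenetic coefficient only (no
  silhouette, PAC or consensus-CDF criteria), and inherits its known
  behaviour of tolerating ties between very stable ranks.
- Dense matrices only; inputs must fit in host memory per worker block.
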