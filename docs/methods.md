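# Methods

## Model

For a fixed anchor k-mer and direction (upstream/downstream), let X_n be
the indicator that the n-th observed target k-mer founds a new target
cluster, and C_N = Σ X_n the cluster count after N targets. Assuming the
X_n independent Bernoulli(p_n), C_N follows a Poisson-Binomial
distribution. Anchors adjacent to diversifying loci (MGE termini, CRISPR
repeats, hyper-variable coding regions) produce far more clusters than
the background process of point mutations and sequencing errors, so
hyper-variability is detected as a right-tail excess of C_N.

The null probabilities p_n are estimated rank-wise by pooling the
trajectories of *all* anchors (the overwhelming majority of which are not
near diversifying loci): p̂_n = Σ_m x_{m,n} / Σ_m 1{N_m ≥ n}. Including
the rare truly-diverse anchors only inflates p̂_n, making the test
conservative. Trajectories of every length contribute to the ranks they
reach; upstream and downstream trajectories are pooled, since the
clustering process is symmetric in direction and pooling doubles the
calibration sample. Only anchor×directions with N ≥ Nmin are tested.

The tail P[C_N ≥ c] is evaluated by sampling the characteristic function
at the (N+1)-th roots of unity R^l = exp(2πil/(N+1)):

P[C_N = k] = (N+1)^{-1} Σ_l R^{-lk} Π_n (1 + (R^l − 1) p̂_n),

an exact discrete Fourier inversion (each factor has modulus ≤ 1). For
N > 30 the product is accumulated in complex log-space; a factor of
exactly zero short-circuits the product. The pmf is clipped to [0, 1]
and the tail accumulated from above; p-values are floored at the
smallest positive double so −log10 q is always finite. Unit and
acceptance tests pin the inversion against DP convolution, exhaustive
2^N enumeration and the constant-p binomial closed form at 1e-9.

Effect size is α = log2(C_N / E[C_N|N]) with E[C_N|N] = Σ_{n≤N} p̂_n, the
Poisson-Binomial mean — the only expectation consistent with the fitted
null.

## Multiple testing

One test per anchor × direction; m counts all of them. To avoid holding
every p-value, only p ≤ 0.1 are retained with their ids; ranked
ascending, q(i) = p(i)·m/i. The raw product can be non-monotone in i, so
by default the standard step-up enforcement q(i) := min_{j≥i} p(j)·m/j
is applied (when every p-value is retained the two coincide); the raw
variant is selectable (`bh_correct(..., monotone=False)`). Dropped tests
get no q-value and are reported as "NA". Overlapping k-mers give
positively correlated p-values, a dependence regime under which BH still
controls FDR.

## Admission and retention

Both rules need the total record count L. L is fixed before the
analysis pass by a cheap line count of the input (capped at
`max_records` = 2.5M), or can be supplied directly (`--total-records`).

* Admission: with p_min = Nmin/L the slowest viable per-read target
  rate, an anchor first seen after l records has had probability
  (1 − p_min)^l of producing zero targets so far; when that drops below
  0.01 (≈ 18% into the file at the defaults) no new anchors are
  admitted. Existing anchors keep accumulating targets.
* Retention: after admission closes, every 100,000 reads each anchor's
  probability of reaching Nmin targets by end of file is predicted from
  its per-direction count x via a normal approximation (continuity
  corrected) to Binomial(L, x/l); anchors whose better direction falls
  below 0.5 are evicted. Anchors that already reached Nmin in either
  direction are never evicted. The per-100k schedule and the max-over-
  directions eviction rule are design choices: per-read evaluation would
  be wasteful, and an anchor viable in either direction is worth
  keeping.
* A direction stops accepting targets at Nmax; an anchor closed in both
  directions is skipped outright, which is what keeps the pass fast on
  high-copy k-mers.

Defaults: k = 27, g = 0 (gap between anchor and target), Nmin = 25,
Nmax = 75, Jaccard threshold 0.2 over overlapping 7-mers (21 per
27-mer), key-replacement probability 0.5, cap 2.5M records. The 0.2/7
pair balances cluster granularity against dictionary growth: at 0.2 two
27-mers sharing fewer than ~14 terminal bases of context split into
separate clusters, while single-substitution/sequencing-error variants
(JS ≥ 0.5) merge.

Reads are processed as written — no reverse-complement
canonicalisation, so a locus appears as two independent anchors, one per
strand; windows containing N are skipped; qualities are ignored;
paired-end mates are treated as two plain FASTQ inputs to one sample,
sharing the record cap.

## Determinism

One `random.Random(seed)` drives key replacement and is consumed in
stream order; all simulator randomness flows from one
`numpy.random.Generator(seed)`. Identical input and seed reproduce every
output file byte-for-byte. Cluster matching scans clusters in insertion
order and recruits to the first match; representative-anchor ties break
lexicographically.

## Simulator

The generator emulates isolate/metagenomic WGS of a clonal population
carrying a planted element:

* *ancestral*: `copy_number` copies placed at non-overlapping uniform
  loci in one ancestral genome; each of `n_genomes` descendants is an
  independently mutated copy (per-base mutation+indel rate `mir`, 9:1
  substitutions:indels, indel lengths geometric with mean 2); junction
  coordinates are mapped through the indels.
* *active*: each genome is first mutated from an ancestor carrying one
  copy, then receives `activity` fresh *exact* copies at independent
  loci (insertions postdate divergence, so fresh junctions flank exact
  element copies — asserted in tests; the ancestral copy itself mutates
  when mir > 0).

Reads are fixed-length single-end, uniform starts, strand flipped with
probability 0.5, uniform substitution errors at `error_rate`, and —
deliberately — pooled and shuffled across genomes into one FASTQ: the
admission/retention model assumes an anchor's reads arrive uniformly
over the file, which a pooled sample satisfies and a genome-ordered file
would systematically violate. Defaults mirror the benchmark scenario:
100 kb genome, 1.5 kb element, 10 genomes, 30X, 150 bp reads, MIR and
error rate 0.001.

What the simulator does not emulate: quality-dependent error profiles,
paired-end inserts, GC/coverage bias, abundance-mixtures of species.
Passing the benchmark therefore demonstrates the statistical machinery
end-to-end under idealised sequencing, not robustness to real platform
artefacts.

**Ground truth.** Each planted copy contributes its two junctions; the
*terminus k-mer set* contains, per junction, the element-side window
occupying the element's terminal k bases (the k-mer touching the
junction), in both orientations, as it appears in the final genome.
Junction-straddling chimeric k-mers are deliberately excluded: each such
k-mer is private to a single insertion site in a single genome, so it is
observed at ~1/10 of the coverage of element-internal k-mers, rarely
reaches Nmin, and carries no flanking diversity of its own — it is not a
sequence the method (or a biologist annotating termini) would call the
element terminus. A looser proximity labelling (all k-mers within a
window of a junction) is available via `SimTruth.proximal_kmers` for
sensitivity analysis. Evaluation scores each tested anchor by its best
direction (−log10 q, with q = 1 for tests dropped before BH ranking, or
α) and computes the Mann-Whitney mid-rank AUC over all tested anchors.

## Problem sizes

The benchmark scenario processes ~263k reads (~25M anchor windows);
the full pipeline completes in about two minutes on one core. Unit-test
fixtures use 20 kb genomes at 10X (~6k reads, seconds). Null-calibration
checks use 2,000 fitting and 5,000 simulated trajectories of length 75;
the FDR check uses 400 anchors × 40 random targets.

## Known limitations

* One sample per run; cross-sample analysis is a separate merge step
  (greedy target clustering, per-anchor binomial regression on one-hot
  covariates with optional first-order interactions).
* The e-value bands for annotation overlap at their boundaries as
  commonly quoted; resolved here as: annotated e ≤ 0.01 < questionable
  e < 0.25 ≤ unannotated.
* The retention rule assumes stationary anchor arrival; heavily sorted
  or demultiplexed-by-locus FASTQs violate it (shuffle first).
* p-values for overlapping anchors are correlated; q-values control FDR
  but significant-anchor counts overstate the number of independent
  loci — hence the edit-distance clustering step.
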