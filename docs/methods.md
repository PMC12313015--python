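# Methods

## Problem and model

`vicinitycover` treats genome-wide expression profiling as a covering
problem. The premise is empirical: genes in close genomic proximity tend to
have correlated tissue-expression profiles, so the profile of an unmeasured
gene can be approximated by copying the profile of a nearby measured
*reference* gene. Given an annotation and a proximity threshold *t* (bp),
the package answers two questions: what is the smallest set of reference
genes such that every gene lies within the vicinity of some reference, and
how much estimation accuracy does that economy cost?

All coordinates are handled 0-based half-open (`[left, right)`), the BED
convention; GTF/GFF3 input (1-based inclusive) is shifted on read. Genes on
a chromosome are totally ordered by `(left, right, id)` — the id component
resolves ties between nested or identically-placed genes, which do occur in
real annotations, so indices are reproducible regardless of input order.
Chromosomes are independent subproblems and are solved separately.

### Vicinity and distance

The vicinity of gene *i* at threshold *t* spans *t* bp upstream of its TSS
to *t* bp downstream of its TES. Since the TSS/TES are the two ends of the
gene's interval in strand-dependent order, the region is
`[left − t, right + t]` on genomic coordinates for either strand, and
membership reduces to a strand-agnostic criterion: gene *j* belongs to gene
*i*'s vicinity iff their **facing gap** (bp between nearest gene ends, 0 for
overlapping/nested pairs) is at most *t*. Membership is therefore symmetric,
and at *t* = 0 a vicinity is non-singleton exactly where genes overlap or
nest. We use the closed form of the extended region so the exact boundary
case gap = *t* counts as inside, keeping the membership ⇔ gap ≤ *t*
equivalence exact.

A strand-aware distance (|TSS−TSS| for same-orientation pairs, |TSS−TES|
otherwise) is provided as a diagnostic (`orientation_distance`); it is *not*
used for membership or tie-breaking, because the region definition above is
strand-agnostic and using an orientation-dependent distance for membership
would break the symmetry the solver depends on. Both are exposed so the
discrepancy can be studied.

### Contiguity closure

On idealized layouts the members of a vicinity form a run of consecutive
indices. A long gene spanning shorter ones can break this: the long gene's
end may reach a distant reference while an intervening short gene does not.
The dynamic program requires interval sets, so raw memberships are
canonicalized to the covering index range `[min member, max member]`; every
index added this way is recorded in a closure report. Closure only ever adds
members, so coverage guarantees are unaffected; assignment distances for
closure-added genes can exceed *t* (flagged in the report rather than
hidden).

### The dynamic program

Vicinity sets are ordered by their reference index. A valid solution is a
gapless chain: an index-increasing sequence of sets whose first set starts
at gene 1, where each successor starts at or before the previous set's end
+ 1, and whose last set reaches gene *n*. The recurrence

    R_i = 1                                         if a_i = 1
    R_i = 1 + min{ R_j : j < i, b_j ≥ a_i − 1 }     otherwise

computes the minimum chain length per set. Rather than materializing all
optimal paths (their number grows exponentially in *n* on overlapping set
families — `count_paths` demonstrates this), the solver keeps a single best
predecessor per state plus the count of tied predecessors, which preserves
the multiplicity information at linear memory. Minimum-length chains are
exactly the chains all of whose prefixes are optimal, so the per-state tie
counts compose into an exact count of optimal paths.

Tie-breaking is hierarchical and deterministic: minimum R first, then the
smallest accumulated per-set average estimation distance, then the smallest
predecessor index. This makes solutions bit-identical across runs with no
randomness anywhere in the solver.

Two design points were genuinely open:

- **Terminal condition.** Stopping the recursion once the state of the last
  set is computed forces the last gene's own set into every solution, which
  is suboptimal whenever an earlier set already covers through gene *n* (the
  `terminal_trap` fixture shows a forced extra reference). The default
  `terminal_mode="optimal"` minimizes over all sets reaching gene *n*;
  `terminal_mode="last_set"` retains the stop-at-the-last-set behaviour and
  warns when it costs an extra set.
- **Path score aggregation.** The tie-break score of a chain can average
  per-set average distances either uniformly over chosen sets
  (`score_mode="per_set"`, the default) or weighted by each set's
  non-reference member count (`"per_member"`). Both are implemented; the
  cover size is identical either way and tests pin the per-set variant.

The predecessor scan is O(n²) worst case. When the sets' start indices are
non-decreasing — always true for sets built from an annotation — a window
pointer discards predecessors that can never again be valid (the constraint
threshold aᵢ − 1 is non-decreasing), giving near-linear behaviour at
realistic thresholds; a 20 000-gene chromosome solves in seconds. The
pointer is an internal shortcut only: on inputs with non-monotone starts the
full scan runs, and both paths produce identical output.

### Baselines

`greedy_cover` picks the set covering the most uncovered elements (ties to
the smallest index) and carries the classical `optimum · (ln n + 1)` bound.
`branch_and_bound_cover` does depth-first include/exclude branching on the
smallest-index set containing the lowest uncovered element, bounding with
`current + ceil(uncovered / largest remaining set)` and seeding the
incumbent with the greedy solution; it is exact when it completes and
reports `proven_optimal=False` otherwise (default node limit 10⁶ — the
exact search becomes intractable within the first ~60 gene sets of a real
chromosome, which is what motivates the DP). Both operate on a generic
uniform-cost set system, so they also serve as independent oracles for the
DP in the tests.

### Estimation error

Each non-reference gene's error is `1 − PCC` between its profile and its
assigned reference's profile; references contribute 0. Genes covered by
several chosen sets are assigned to the reference with the smallest facing
gap (ties to the smaller index). Two averaging modes mirror two questions:
`estimated_only` (how good are the estimates?) excludes references;
`all_genes` (how good is the genome-wide profile set?) includes their zero
errors, so it is always ≤ the former.

PCC is computed on log2(TPM+1) by default. The log matters: PCC is
invariant to per-gene affine maps (hence unaffected by the z-score and
min-max steps of the display normalization, and by the choice of log base)
but not to the log itself, and TPM spans orders of magnitude. A pseudocount
of 1 is required because 0 TPM is common; `use_log=False` correlates raw
values for comparison. Profiles with missing values or zero variance carry
no correlation information and are dropped before scoring (reported, not
imputed). The normalization chain for display is log2(TPM+1) → per-gene
z-score (population SD, fixed for reproducibility of intermediates) →
min-max to [0, 1]; a flag on the matrix guards against applying the log
twice.

## Synthetic data

The generator produces the two structures the method assumes, without any
external downloads:

- **Layout.** Gene lengths and inter-gene gaps are drawn from clipped
  normals (defaults: length 20 ± 15 kb, gap 10 ± 8 kb, minimum gene length
  200 bp), a fraction of gaps (default 5%) is replaced by an overlap into
  the previous gene so the *t* = 0 edge case has work to do, and half the
  strands are flipped. The defaults describe a gene-dense chromosome arm;
  they put neighbouring midpoints ~30 kb apart so that correlation decays
  visibly across the threshold grid used throughout.
- **Expression.** Per tissue, a unit-variance latent field over gene
  midpoints has covariance `exp(−d/λ)` with λ = 60 kb by default — chosen to
  match the tens-of-kilobases range over which neighbouring genes' profiles
  are reported to stay similar. The exponential kernel is Markov along the
  ordering, so the field is drawn *exactly* by the AR(1) recursion
  `x_k = ρ_k x_{k−1} + √(1−ρ_k²) z_k`, `ρ_k = exp(−d_k/λ)` — O(n) per
  tissue, no covariance factorization, no numerical jitter. Midpoint
  distance (not facing gap) parameterizes the kernel: it is simpler and only
  the ordinal decay matters for what the tests assert. TPM is
  `exp(baseline_g + x + ε)` with a per-gene lognormal baseline
  (ln-scale 2 ± 1.5) and independent noise (σ = 0.7), so absolute levels
  span orders of magnitude and the log step of the normalization is
  exercised meaningfully. 54 tissues by default.

What this emulates — and what it does not: the simulation produces
distance-decaying co-expression with realistic dynamic range, but real
chromosomes have enhancer skipping, TAD boundaries, strand-specific
regulation and tissue-specific factors that make similarity decidedly
non-monotone in distance. Passing tests therefore demonstrate the
*algorithmic* guarantees (optimality, tie-break behaviour, monotone
trade-offs under the model's own assumptions), not that a given threshold
will achieve a particular error on a real genome.

## Numerical choices and degenerate inputs

- All indices exposed to users are 1-based gene ranks; coordinates are
  0-based half-open bp.
- Float ties in the distance tie-break are broken by exact equality of
  accumulated sums and then by the smallest predecessor index, so results
  are deterministic even when distances coincide.
- A set family that cannot cover the universe raises a coverage-gap error
  naming the first unreachable gene (impossible for sets built by
  `build_sets`, possible for hand-made systems).
- Path counting saturates at a configurable cap and returns a sentinel
  (`inf`) instead of overflowing or raising.
- Exhaustive cover enumeration (`enumerate_min_covers`) is a test oracle;
  it enforces an enumeration budget and refuses instances beyond it.
- Problem sizes in the test suite (≤ 20 sets for exhaustive cross-checks,
  120–300 genes for trade-off properties, one 20 000-gene instance for the
  scaling check) were chosen so independent oracles stay exact while each
  property is still exercised well away from trivial regimes.

## Known limitations

- One interval per gene: isoforms, alternative TSSs and transcript-level
  structure are out of scope.
- Thresholds are global; chromatin-informed or per-gene adaptive thresholds
  are not attempted.
- Non-uniform set costs are not supported (the covering formulation
  deliberately prices every reference equally).
- The estimation model copies profiles verbatim; no shrinkage, averaging of
  flanking references, or imputation.
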