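# vicinitycover

Genes that sit close together on a chromosome tend to have similar
tissue-expression profiles: when chromatin opens in a tissue, neighbouring
genes are switched on together. This regularity suggests an economy of
measurement — instead of profiling every gene across a tissue panel, one can
measure a carefully chosen subset of **reference genes** and estimate each
remaining gene's profile as identical to the nearest reference within a
proximity threshold *t*. `vicinitycover` selects a provably minimum set of
such references and quantifies the accuracy cost of the shortcut. It is
aimed at transcriptomics groups planning expression surveys in organisms or
tissue panels that lack an atlas, and at anyone studying the
distance–coexpression trade-off itself.

## The method

For a chromosome with *n* genes ordered by position (index 1…*n*), the
**vicinity** of gene *i* at threshold *t* is the region from *t* bp upstream
of its TSS to *t* bp downstream of its TES — on genomic coordinates,
`[left − t, right + t]` regardless of strand. Every gene overlapping that
region (equivalently: every gene whose facing gap to gene *i* is ≤ *t*)
belongs to gene *i*'s **vicinity set** gᵢ, a run of consecutive indices
[aᵢ, bᵢ]. Choosing the fewest reference genes whose vicinity sets jointly
cover 1…*n* is a set cover problem — NP-hard in general, but the consecutive
ordering admits an exact dynamic program:

    R_i = 1                                         if a_i = 1
    R_i = 1 + min{ R_j : j < i, b_j ≥ a_i − 1 }     otherwise

where Rᵢ is the minimum number of sets in a gapless chain of vicinity sets
covering genes 1…bᵢ. The optimum over all sets reaching gene *n* is the
minimum reference count, found in O(n²) worst case (near-linear for
realistic thresholds). Among tied optimal chains, the solver keeps the one
minimizing the accumulated **average estimation distance**

    d̄(g_i) = (1/m) Σ_{j ∈ g_i, j ≠ i} gap(j, i)

(mean facing gap from the m non-reference members to the reference), since
shorter distances mean better estimates. Greedy and branch-and-bound set
cover solvers are included as baselines: greedy is fast but only
ln(n)-approximate, branch-and-bound is exact but exponential.

Estimation quality is scored against a genes × tissues TPM matrix: each
estimated gene's error is `1 − PCC(gene, assigned reference)` (Pearson
correlation across tissues, computed on log2(TPM+1)), which ranges from 0
(profiles perfectly correlated) to 2 (perfectly anti-correlated).

## Worked example

The bundled generator simulates a gene-dense chromosome (300 genes, ~20 kb
genes with ~10 kb gaps) and an expression matrix whose pairwise correlation
decays with genomic distance (54 tissues):

```python
from vicinitycover import (SyntheticConfig, simulate_layout, simulate_expression,
    build_sets, solve, assign_references, assignment_to_ids, filter_profiles,
    estimation_error)

cfg = SyntheticConfig(seed=42, n_genes=300)
index = simulate_layout(cfg)
matrix, _ = filter_profiles(simulate_expression(index, cfg))

for t in (0, 20_000, 60_000, 120_000):
    sets, closure = build_sets(index, t)
    sol = solve(sets, threshold=t)
    assign_references(sol, index)
    err = estimation_error(matrix, assignment_to_ids(sol.assignment, index))
    print(f"t={t:>7,} bp  references={sol.R:>3}  "
          f"path_score={sol.path_score:>9,.0f} bp  "
          f"mean_error={err.mean:.3f}")
```

```
t=      0 bp  references=242  path_score=        0 bp  mean_error=0.468
t= 20,000 bp  references= 99  path_score=    7,583 bp  mean_error=0.576
t= 60,000 bp  references= 52  path_score=   25,711 bp  mean_error=0.683
t=120,000 bp  references= 30  path_score=   53,732 bp  mean_error=0.783
```

Reading the table: at *t* = 0 only overlapping/nested genes share a set, so
242 of 300 genes must be measured directly and the few estimated genes are
estimated well. Raising *t* shrinks the reference set (99 → 52 → 30) while
the mean per-chain average distance (`path_score`) and the mean estimation
error of the estimated genes grow — the trade-off the method exists to
navigate.

The same pipeline is available from the shell:

```bash
vicinity-cover simulate --seed 42 --n-genes 300 --out-dir demo/sim
vicinity-cover solve --annotation demo/sim/layout.bed -t 60000 --out-dir demo/solve
vicinity-cover evaluate --expression demo/sim/expression.gct \
    --assignment demo/solve/assignment_t60000.tsv --out-dir demo/eval
vicinity-cover sweep --annotation demo/sim/layout.bed \
    --expression demo/sim/expression.gct -t 0,20000,60000,120000 --out-dir demo/sweep
```

Every subcommand writes TSV/BED/JSON outputs plus a `summary.json` echoing
the exact configuration, so runs are reproducible byte for byte.

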