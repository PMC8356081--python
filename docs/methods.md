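# Methods

## The model

For a pedigree of `n` individuals ordered so that parents precede progeny,
the numerator relationship matrix **A** holds the additive genetic
relationships: `A_ij` is twice the coancestry (kinship) of `i` and `j`,
and `A_jj = 1 + F_j`, with `F_j` the inbreeding coefficient — the
probability that `j`'s two alleles at a locus are identical by descent.
With `s` and `d` the parents of `j` (unknown parents contributing zero):

```
A_ij = (A_si + A_di) / 2          (i < j)
A_jj = 1 + A_sd / 2
```

Founders (both parents unknown) are assumed unrelated and non-inbred, so
the base block of A is an identity. All entries are dyadic rationals,
which is why direct constructions can be compared for *exact* equality
and why exact zeros in A are meaningful (the sparsity statistics count
them as such by default).

A factors as `A = TDT'`, with T unit lower triangular (`T_ij` is the
expected fraction of `j`'s genome from ancestor `i`) and D diagonal — the
Mendelian sampling variances:

```
D_jj = (2 − F_s − F_d)/4   two known parents
D_jj = (3 − F_s)/4         one known parent
D_jj = 1                   founder
```

`T⁻¹ = I − J`, where J is the parent incidence matrix with entries 0.5;
it is assembled in a single pass because row `j` involves only `j`'s own
parents. This yields Henderson's sparse inverse `A⁻¹ = (T⁻¹)' D⁻¹ T⁻¹`
without forming A. Writing `L = T D^{1/2}` gives the Cholesky-style
`A = LL'`.

## Constructions of A and their contracts

Seven direct constructions are implemented (`nrm_direct`); the tabular
recurrence is the reference oracle and every other route must agree with
it to 1e-10 (iterative-D: 1e-4 at its default tolerance):

1. **tabular** — the element-wise recurrence, n(n+1)/2 scalar steps.
2. **array-tabular** — the same recurrence with the inner loop replaced
   by one vectorized slice per individual; arithmetic order is preserved,
   so results are identical, not merely close.
3. **TDT'** — T by the row recurrence, then a sparse triple product.
4. **TDT' via T⁻¹** — T obtained by sparse forward substitution of the
   one-pass T⁻¹; same product.
5. **iterative D** — starts from `D0_jj = 1 − p_j/4` (p_j = number of
   known parents, i.e. inbreeding ignored) and alternates `A = TDT'`
   with diagonal updates until `diag(A)` is stationary. The candidate
   diagonal is `1 + A_sd/2`; `D_jj` is reset to `1 − (A_ss + A_dd)/4`
   only for individuals whose diagonal still exceeds its candidate while
   both parents' diagonals have stabilized. The stationarity test is
   `|A_pp − candidate_p| ≤ ϵ` (default ϵ = 1e-5): a literal equality
   test is meaningless in floating point. Inbreeding propagates one
   generation per sweep, so `max_iter` defaults to the generation count
   plus a margin.
6. **LL'** — Henderson's indirect rules with parents sorted `s < d`.
   The diagonal closes each row as
   `L_jj² = 1 + ½·Σ_{i≤s} L_si·L_di − Σ_{i≤d} L_ji²`
   (the middle term is `A_sd/2`); the one-parent and founder cases drop
   the middle term. This form is validated against the LL' = A oracle.
7. **by generation** — A is enlarged one generation stratum at a time:
   cross block `J_i A_{i−1}`, within block `J_i A_{i−1} J_i'` plus the
   Mendelian residual `o = 1 + 2·diag(J_s A J_d') − diag(J A J')`. The
   incidence products reduce to row/column gathers of parent rows, so no
   J matrix is formed. Because a topological order need not make
   generations contiguous, the routine works in a stable generation sort
   internally and permutes the result back.

Block extraction computes `T[rows]·D·T[cols]'` (or the L analogue)
without forming A, and the dummy-progeny route returns a single
relationship as twice the inbreeding coefficient of a phantom offspring
appended to a copy of the pedigree.

## Inbreeding

F is computed by the Meuwissen–Luo recursion: for each individual the
nonzero entries of its row of L are accumulated over its ancestors
(`L_parent += L_child/2`, processed in decreasing id order), giving
`1 + F_j = Σ_a L_ja² D_aa` in time proportional to the number of
ancestor–path segments and O(n) memory. Unknown parents enter D through
the convention `F_unknown = −1`, which folds the three D cases into one
expression. Consecutive full sibs share F and are memoized. The kernel is
JIT-compiled with numba when available (a ~20K-individual pedigree takes
well under a second); an equivalent pure-Python implementation using a
heap is the fallback, and the two are compared in tests. The tabular
diagonal minus one is the oracle.

## Recovering A from A⁻¹

`nrm_inverse_solvers` treats A⁻¹ as given (usually from `build_ainv`) and
offers: a direct sparse-LU solve of `A⁻¹A = I`; independent per-column
solves `A⁻¹x = e_i` sharing one read-only factorization (bit-identical
for any worker count, workers via joblib threads); forward/backward
substitution against the dense Cholesky factor `A⁻¹ = KK'`; inversion
via LAPACK's `dpotri` from the upper factor `A⁻¹ = U'U`; and a
hand-written preconditioned conjugate gradient.

PCG choices: the convergence criterion is the Euclidean norm of the
residual `b − A⁻¹x` below the tolerance (1e-5 by default; the right-hand
sides here are unit vectors, so absolute and relative criteria
coincide). Each column starts from `x0 = e_i` — no warm starts from
previously solved columns, preserving column independence. Three
diagonal preconditioners are provided: Jacobi `1/diag(A⁻¹)`, D, and D0.
Optional `(A + A')/2` symmetrization is off by default. Non-convergence
of a column is reported, not raised.

Colleau's indirect product computes `A·v = T(D(T'v))` through two sparse
triangular solves against T⁻¹ and costs O(nonzeros of T⁻¹); applied to
unit vectors it reproduces columns of A exactly, which the tests use.

## The pedigree simulator

The generator emulates a closed livestock population: an even-sex founder
cohort (default 200) mates randomly without selection or mortality;
afterwards each newborn dies before maturity with probability 0.03, 80%
of surviving females and 20% of surviving males are selected uniformly at
random (never on merit), females breed in a single generation while males
remain eligible one generation longer, and each selected dam is mated
`litters_per_dam` times to sires drawn uniformly with replacement, each
mating producing a full-sib litter of `litter_size`. Simulation stops
after the first generation that reaches the cumulative target (litters
are never truncated, so the final size overshoots the target). Masking
then hides sires/dams of non-base individuals with probabilities
0.20/0.10.

`litters_per_dam` defaults to 3: expected cohort growth is
`0.8·(1−0.03)·0.5·litters_per_dam·litter_size ≈ 0.388·litters_per_dam·L`,
and 3 is the smallest whole number that sustains growth at litter size 1.
With that default the generation counts needed to reach 20,000
individuals fall as litter size rises (≈17/6/4 for litter sizes 1/2/4),
and mean inbreeding among inbred individuals rises with litter size while
the maximum inbreeding coefficient stays at 0.25 — the qualitative
population patterns expected of this breeding design.

What the generator does **not** emulate: assortative or performance-based
mating, sex-specific mortality, variable litter sizes, seasonal/overlapping
female cohorts, or pedigree-recording errors. Passing tests on simulated
pedigrees therefore demonstrate algorithmic correctness on realistic
pedigree *topologies*, not calibration to any particular recorded
population.

A second generator (`random_pedigree`) produces small arbitrary acyclic
pedigrees (parents drawn from all earlier individuals, odd ids male) for
property tests; it deliberately creates structures a breeding program
would not (e.g. matings across many generations).

## Numerical and design choices

- Internal ids are 1-based (0 = unknown parent), matching the packed
  position formula `(i(i−1)/2)+j` and the field's conventions.
- Topological ordering is Kahn's algorithm with ties broken by input
  position: deterministic, and the identity for already-ordered files.
  Parents never listed as individuals are appended as founders with a
  warning; cycles are a hard error naming an individual involved.
- Factors are assembled into triplet buffers and converted to compressed
  sparse form once complete; element-wise updates of compressed formats
  are avoided throughout.
- A⁻¹ can be assembled either as the sparse triple product or from
  per-individual contributions (δ = 1/D_jj at (j,j), −δ/2 at
  (j, parent), δ/4 at parent pairs); both are exposed and tested equal.
- Dense storage for A (optionally packed): at the sizes this package
  targets in one process (up to a few tens of thousands), an n×n float64
  array is the fastest representation, and ~99.98%-sparse A⁻¹ stays in
  CSR.
- Sparsity statistics use exact zero by default (direct methods produce
  exact zeros); a `zero_tol` flag exists for solver output. RMSE over the
  lower triangle includes the diagonal. The sparsity denominator is all
  n(n−1) off-diagonal positions.
- File formats round-trip float64 losslessly: MatrixMarket coordinate
  (symmetric, 17 significant digits), triplet TSV, and a packed binary
  container (`NRMP`, version byte, little-endian uint64 n, n(n+1)/2
  float64 values).
- Degenerate inputs: single-founder pedigrees work everywhere except the
  n≥2 summary; empty row/column sets for block extraction and selfing in
  the dummy-progeny route are errors; population extinction in the
  simulator raises with advice rather than looping forever.

## Problem sizes used by the test suite and acceptance script

Exactness checks run on a 7-animal worked example with hand-derived
values (F = 0, 0, 0, 0, 0.125, 0.25, 0.28125), 50 random pedigrees of
10–500 individuals, and one simulated pedigree per litter size at a
2,000-individual target; solver accuracy uses a ≈1,000-individual
pedigree; population statistics use litter-1/2/4 simulations at a
20,000-individual target, where only sparse quantities (F, A⁻¹) are
computed. These sizes exercise every code path while keeping a full run
in the minutes range; the algorithms themselves carry no size constants.

## Known limitations

- Dense A construction is memory-bound at roughly n ≈ 30–40K per 8 GiB;
  beyond that use `nrm_block`, `a_times_vector`, or packed storage.
- No genetic groups, no multi-breed pedigrees, no dominance or genomic
  (H-matrix) relationships.
- The benchmark harness reports wall-clock times for orientation only;
  nothing in the test suite asserts timing.
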