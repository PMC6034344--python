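# Methods

## Model

Given M candidate barcodes of common length L over {A, C, G, T}, a subset
size n, and a minimum pairwise distance d, the selection is a MILP over
binary indicators x_i (barcode i selected) and continuous auxiliaries t:

**Objective.** The nucleotide-balance cost sums, for each position
l = 1..L, two laser-group deviations |n_l^{AC} − n/2|, |n_l^{GT} − n/2|
and four single-nucleotide deviations |n_l^{X} − n/4|, plus four global
deviations |N^{X} − nL/4| over the whole barcode length. All counts are
linear in x (n_l^{X} = Σ_i x_i · [seq_i[l] = X]). Each absolute value is
linearized the standard way: min |e| becomes min t with t ≥ e and t ≥ −e.
That yields 6L + 4 auxiliary variables and 12L + 8 balance inequalities —
a function of L only, never of M (for L = 8: 48 positional auxiliaries
with 96 inequalities, plus 4 global auxiliaries with 8 inequalities). The
auxiliaries are continuous; at any optimum each equals its deviation
exactly, so the MILP objective equals the cost of the selected subset.

**Constraints.** (1) The balance inequalities above. (2) One pair
exclusion x_j + x_k ≤ 1 for every candidate pair at distance < d,
enumerated by an all-pairs O(M²) screen; a feasible solution therefore
respects the distance threshold by construction. (3) The cardinality
equation Σ x_i = n, plus x_i = 1 for each barcode fixed into the solution
(augment mode).

The group terms are deliberately redundant when perfect four-way balance
exists (four-way balance implies group balance), but when n is not a
multiple of 4 they steer the optimum toward A/C vs G/T balance, which the
two-laser detection needs most. All terms are equally weighted.

**Why n ≡ 0 (mod 4) matters.** Position counts are integers summing to n,
so |n_l^{X} − n/4| can vanish for all X only when 4 | n; for odd n the
positional part of the cost is strictly positive, while the global part
can still reach zero (nucleotide usage evens out over the barcode length).

## Error-tolerance rule

A barcode code with minimum pairwise distance 2m + 1 corrects up to m
substitution errors; d = 3 (the default) tolerates one. The guarantee is
stated for Hamming distance. Levenshtein mode uses plain global edit
distance with no free end gaps; with fixed-length index reads an indel
shifts every downstream cycle, so indel distances can be optimistic about
real demultiplexing — the Hamming metric is the safer default.

## Solver backend

The structure is solver-agnostic (binaries, continuous variables, linear
constraints, linear objective, a time limit) and is exported to CPLEX LP
text via `to_lp` for debugging. The bundled backend is HiGHS through
`scipy.optimize.milp`. Mapping of outcomes:

* proved optimum → `optimal`;
* time limit (default 10 s) hit with an incumbent → `feasible_time_limited`
  and the best incumbent is returned, labeled as such everywhere;
* no subset of size n satisfies the pair constraints → `infeasible`.

HiGHS supports no branch-depth limit or RNG seed; those options are
accepted for backend portability and ignored with a warning. Extra
backend parameters pass through opaquely. Ties between equally optimal
subsets are broken by the backend; tests and callers should rely on the
objective value, not on the identity of the chosen subset.

Every solver answer is re-verified independently (`verify`): subset size,
all pairwise distances, fixed-barcode inclusion, and the cost recomputed
from the selected sequences. Reported objectives always come from that
exact recomputation, never from the solver's floating-point objective.

## Numerical choices

* Cost arithmetic uses `fractions.Fraction`, so "cost == 0" and oracle
  comparisons are exact, not within-epsilon. (The constraint right-hand
  sides n/2, n/4, nL/4 are dyadic rationals and hence exact as binary
  floats inside the solver as well.)
* A selected indicator is read off as x_i > 0.5; HiGHS returns integral
  binaries to well below that slack.
* Degenerate inputs: a pool needs ≥ 1 barcode; balance of an empty subset
  is undefined and rejected; `min_pairwise_distance` needs ≥ 2 barcodes;
  augment with zero new barcodes re-reports the fixed set.
* Duplicate sequences under distinct ids parse with a warning; any
  threshold d ≥ 1 makes them mutually exclusive via the pair constraint.
* IUPAC ambiguity codes are rejected rather than expanded: the balance
  model and laser groups are defined only over A/C/G/T.

## Design choices where the design was open

* **Check mode never runs the ILP.** Setting n = M and solving would
  declare a user's existing set "infeasible" whenever it contains a close
  pair; reporting distances, violating pairs and the cost breakdown as
  findings is strictly more useful and yields the same numbers.
* **Fixed-set conflicts fail fast.** In augment mode, two fixed barcodes
  closer than d would make the model trivially infeasible. The offending
  pair is named up front; `allow_fixed_conflicts` drops fixed–fixed pair
  constraints so a user can knowingly proceed.
* **Initial barcodes need not be candidates.** Augment matches the
  initial set to the pool by sequence and appends any that are absent.
* **Global balance targets are nL/4 each** — equal shares of the n·L
  nucleotide total, the only reading consistent with the positional
  targets.
* The 2m+1 correctability figure is reported for Hamming mode only.

## Synthetic data

`fixtures.generate` emulates a facility's candidate list: a planted
cost-zero subset (each position a random permutation of {A,C,G,T}·(n/4),
rejection-sampled until pairwise Hamming distance ≥ d, then verified, not
trusted) among decoys drawn with an A-skewed composition
(p = (1+3b, 1−b, 1−b, 1−b)/4, default bias b = 0.5) so that swapping a
decoy in worsens balance. Defaults (M = 32, L = 8, planted n = 8, d = 3)
mirror common 8-nt index pools. The generator does not emulate real
candidate screening (PCR suitability, homopolymer or GC filters,
synthesis constraints), sequencing-error processes, or index hopping — a
green test on generated pools establishes correctness of the selection
machinery, not wet-lab validity of a barcode list.

The four bundled reference sets (8/12/16/24 barcodes, L = 8) are known
optimal sets: pairwise Hamming distance ≥ 3 and perfect per-position
balance, i.e. cost exactly 0; they anchor parser, cost, distance and
solver tests.

## Limitations

* All-pairs distance screening and the MILP are intended for pools up to
  a few thousand candidates, not for exhaustive k-mer spaces (de novo
  design tools suit that better).
* Dual indexing (P5 × P7 combinations) is out of scope; compose two
  independently selected sets instead.
* Solve time grows when no perfectly balanced subset exists (the search
  must prove optimality of a nonzero optimum); the time limit then
  returns the labeled best incumbent.
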