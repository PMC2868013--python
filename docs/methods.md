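# Methods

## Model and measure

The object of study is a discrete-time, finite-state Markov chain given as a
row-stochastic transition matrix P over named states, assumed to have a
unique stationary distribution π (one recurrent class).  A partition of the
states into macro-states s₁…sₙ induces an aggregated process; in general the
aggregation introduces memory, and only special partitions ("lumpings")
leave the aggregated process Markov.

Closedness is measured as the expected conditional mutual information
between the aggregated past and future given the aggregated present.  The
stationary triple law over micro paths (y, x, z) has weight
π(y) P(y, x) P(x, z); marginalizing onto macro triples gives, for each
current macro-state sᵢ, a joint table of (previous macro, next macro), whose
mutual information I(Pᵢ; Fᵢ) is weighted by Pr(sᵢ) = Σ_{x∈sᵢ} π(x):

    ⟨I⟩ = Σᵢ Pr(sᵢ) I(Pᵢ; Fᵢ),   I = H(Pᵢ) + H(Fᵢ) − H(Pᵢ, Fᵢ).

⟨I⟩ = 0 iff the one-step aggregated process is closed.  Design choices:

* **Base 2.**  Entropies are in bits.  Only the zero-set of ⟨I⟩ matters for
  lumpability, so conclusions are base-invariant; bits are the conventional
  reporting unit.
* **Horizon one.**  Past and future are a single step each.  Longer
  horizons would detect higher-order memory but are out of scope.
* **0·log 0 ≡ 0** by continuity; exact independence can round to a tiny
  negative I, which is clipped at zero (values below −10⁻⁹ raise, as they
  would indicate a real defect rather than round-off).
* **π is the micro chain's stationary distribution** and Pr(sᵢ) its block
  sum — the only self-consistent choice for a stationary aggregated
  process.

Internally ⟨I⟩ is evaluated from the unnormalized macro triple tensor
W[j, i, k] via the identity ⟨I⟩ = S(W) − S(W_{j i}) − S(W_{i k}) + S(W_i)
with S(·) = Σ x log₂ x, avoiding per-state normalization; the tensor is
assembled in O(N n²) from B[j, x] = Σ_{y∈s_j} π_y P_{yx} and
F[x, k] = Σ_{z∈s_k} P_{xz}.  The test suite checks this against a literal
enumeration of all N³ micro triples at 10⁻¹² absolute tolerance.

## Lumping algebra

`lump` forms the macro transition matrix by π-weighted row averaging:
P_macro(I, J) = Σ_{x∈I} π(x)/π(I) Σ_{y∈J} P(x, y).  For a lumpable
partition this reproduces the macro chain exactly; in general it is the
one-step law of the stationary aggregated process.  `restrict` removes
states and renormalizes rows (used to drop stop codons and excluded
residues); renormalization is skipped for rows already within 10⁻¹³ of 1 so
restriction is an exact fixed point on its own output.  The stationary
distribution comes from the left eigenvector of the eigenvalue nearest 1;
uniqueness requires exactly one eigenvalue within 10⁻⁸ of 1.  Row-sum
validation tolerates deviations up to 10⁻⁶ by default (empirical matrices
are printed with limited precision) and renormalizes; worse rows are
rejected with the offending row reported.

## Lumpability tolerances

Two defaults for the verdict threshold τ on ⟨I⟩: 10⁻⁹ bits for exact
synthetic settings (machine-precision zero against eigensolver noise), and
10⁻³ bits for empirical matrices, which are estimated from finite counts
and never exactly lumpable.  Both are plain parameters.

## Spectral search

Right eigenvectors are used: for a lumpable partition the relevant
eigenvectors are constant within blocks ("level sets"), a right-eigenvector
property.  States are embedded with their components in selected
eigenvectors (each unit-norm, phase fixed so the largest entry is positive
real) and clustered by single linkage cut at distance ε, default
ε = 0.1/√N — scale-free given unit-norm vectors, whose element spacings
scale like 1/√N.  A selection of n eigenvectors forming exactly n clusters
is a candidate aggregation, always verified with ⟨I⟩ ≤ τ, so soundness
never depends on the clustering heuristic.

**Degenerate eigenvalues.**  Individual eigenvectors inside a repeated
eigenvalue's eigenspace are arbitrary — any basis is equally valid, and
eigensolvers may even return duplicated vectors.  Eigenvalues closer than
10⁻⁸ are therefore grouped, and each group is handled as one atomic
subspace: its coordinates are an orthonormal basis of the invariant
subspace obtained from a sorted Schur decomposition, which makes distances
between states basis-invariant.  A selection touching part of a group is
expanded to the whole group.  This matters even in the 4-state worked
example, whose kernel is two-dimensional: treating the kernel atomically
yields exactly the three aggregations the chain supports, whereas clustering
a single arbitrary kernel vector would make the outcome depend on the
eigensolver's basis choice.  Complex eigenvectors contribute their real and
imaginary parts as coordinates (a no-op for reversible chains, whose
spectra are real).

**Gap detection** maximizes the magnitude ratio |λₙ|/|λₙ₊₁| (ties toward
smaller n).  A ratio, not a difference, expresses time-scale separation
between aggregated and within-aggregate dynamics.

**Subset search.**  For each target size n the search grows a subset of the
leading max_n eigenvector groups from the stationary direction, greedily
adding the group that least increases the cluster count, backtracking on
dead ends.  Adding coordinates can only split single-linkage clusters,
never merge them, so branches whose cluster count exceeds n are pruned
exactly.  A node budget (default 2000 evaluations per target size) bounds
worst-case backtracking; on exhaustion that size is reported as not found
(optionally raised).  The search is deliberately not complete — candidates
are cheap to verify, so completeness is traded for a predictable budget.

## Agglomeration

From singletons (or any initial partition — the codon pipeline starts from
the 21-block code partition level), all k(k−1)/2 pairwise merges are
evaluated per level and the ⟨I⟩-minimizing merge applied; ties break
lexicographically on the sorted pair of block names, making traces
deterministic.  Each candidate is evaluated from scratch (the per-level B
and F arrays are reused; a merge is two row/column additions), which at
N ≤ 61 costs seconds at worst.  The full trace is always returned.

**Most significant level.**  The flagged partition is the one immediately
before the merge with the largest single-step increase in ⟨I⟩ — merging
across true groups sharply breaks closedness, merging within groups does
not.  Ties go to the latest jump; if no merge increases ⟨I⟩ at all (an
i.i.d. chain, where every partition is closed) the one-block partition is
returned.  This is a heuristic for reading the trace, not part of the
measure; users can apply their own cut to the emitted trace.  Note the
flagged level is only meaningful when the dynamics has no almost-closed
coarser aggregation of comparable quality; on randomly drawn macro chains
such near-ties do occur, and then a coarser level is — correctly — flagged.

The dendrogram export uses merge ⟨I⟩ as node height, made non-decreasing by
running maxima (greedy traces need not be monotone), so Newick branch
lengths are non-negative.

## Codon pipeline

The standard genetic code (translation table 1) is embedded with DNA
alphabet (T, not U); RNA input is transliterated, and alternative codes can
be supplied as a two-column TSV.  Stop codons are removed by restriction
with renormalization — made explicit and configurable since empirical
matrices may or may not include them.  The code partition groups sense
codons by encoded amino acid, splitting each group into connected
components of the Hamming-distance-1 graph; serine is the unique split
residue, giving 21 blocks.  Components are labeled by size then
lexicography, so S_1 is the four-codon TCN block and S_2 is {AGT, AGC}.

The amino-acid-level chain is obtained by lumping the codon chain under the
code partition with π-weights — the only construction consistent with the
closedness framework (the alternative, estimating an amino-acid matrix
separately, is out of scope).  Tryptophan is excluded by default before
agglomeration: it is the rarest, least mutable residue and otherwise
dominates the first split.  Exclusion is a flag.

## Synthetic generator

Planted chains satisfy strong lumpability (the Kemeny–Snell condition): the
row x → block J total equals P_macro(I(x), J) for every x, which guarantees
⟨I⟩ = 0 for the planted partition from any start.  Within-block allocation
mixes a block-shared composition with per-row Dirichlet noise,
alloc = (1−δ)·shared + δ·Dirichlet with δ = 1 − separation:

* `separation` (default 0.95) controls time-scale separation only —
  lumpability is exact for any value.  Near 1, the non-macro eigenvalues
  shrink like δ while the macro eigenvalues of the default diagonally
  dominant macro draw (0.7 I + 0.3 Dirichlet) stay above ≈ 0.4 in
  magnitude, so gap detection at k is well-posed with a comfortable
  (≥ 2×) margin.  At separation = 1 rows within a block are identical, and
  then every refinement of the planted partition is also exactly lumpable —
  the regime used to compare greedy agglomeration against exhaustive
  search.
* The synthetic codon chain uses the 21 code-partition blocks with a macro
  chain proportional to within_weight (50) on the diagonal and
  between_weight (1) between blocks adjacent under single point mutations,
  rows normalized, at separation 0.98.  The weight ratio keeps the smallest
  macro eigenvalue near 0.54 against within-block modes below ≈ 0.05, so
  the spectral gap falls at 21 and the leading 21 eigenvectors are
  block-constant to working precision.  This macro is a random-walk
  normalization of a symmetric weight matrix, hence reversible with a real
  spectrum, mirroring the reversibility of empirical substitution matrices.
* `perturb` mixes each row with ε of an independent Dirichlet row, modeling
  the deviation of estimated matrices from exact lumpability; ⟨I⟩ of the
  planted partition grows monotonically with ε (checked via Spearman rank
  correlation across seeds).

What the generator does *not* emulate: estimation noise correlated across
rows, codon usage bias in π beyond what the macro draw induces, and
mutation–selection structure within amino-acid blocks.  Passing tests
demonstrate that the machinery recovers planted structure under controlled
conditions, not that any particular empirical matrix is lumpable.

The worked 4-state example is constructed in closed form: states a, c jump
to b with probability p (else d); states b, d jump to a with probability q
(else c).  The aggregated {a,c}/{b,d} process flips deterministically, the
spectrum is {1, −1, 0, 0}, the second eigenvector is (1, −1, 1, −1), and
the kernel is spanned by (r, 0, p, 0) and (0, s, 0, q) with r = p(q−1)/q,
s = q(p−1)/p — verified in the tests by direct multiplication.  The chain
is reversible with π = (q, p, 1−q, 1−p)/2.

## Numerical choices and degenerate inputs

* Eigenvalue sort keys are rounded at 10⁻⁷ before ordering so exact ties
  (|1| vs |−1|) are not scrambled by last-digit noise; ties order by
  descending real part.
* Transient states (π = 0) make any block containing only them raise
  `ZeroMassBlock` rather than silently producing 0/0 tables.
* Periodic chains are handled throughout (the worked example has period
  2); only uniqueness of π is required.
* Problem sizes in the test suite and acceptance script (chains up to
  N = 61, 20-seed recovery runs, brute-force enumeration up to N = 8 and
  Bell(8) = 4140 partitions) are chosen to exercise every regime the
  methods distinguish while keeping a full run in seconds.

## Known limitations

* ⟨I⟩ tests one-step closedness only; a partition could pass while
  introducing longer-range memory.
* The spectral subset search is budgeted, not complete; it can miss
  aggregations whose eigenvectors are far down the spectrum.
* Greedy agglomeration has no optimality guarantee off the exactly
  lumpable case (where it provably attains the global minimum of zero);
  the trace is emitted precisely so that users are not bound to the greedy
  path or to the most-significant heuristic.
* Continuous-time rate matrices and estimation of matrices from alignments
  are out of scope; inputs are discrete substitution probability matrices.
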