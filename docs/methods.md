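# Methods

## The k-mer count model

For a DNA string x with k-mer counts c_t and ℓ(x) = Σ_t c_t = |x| − k + 1,
the null model is multinomial with per-k-mer frequencies q_t.  Its
log-likelihood separates into a length term, a k-mer-usage term, and
−Σ_t log c_t!, the only part that responds to *repetitiveness*.  Centring
that part by its null expectation gives

    Q(c) = Σ_t log c_t! − f(ℓ),

which tends to 0 on random strings of any length (verified by Monte Carlo:
|mean Q/ℓ| < 0.02 over 100 random 1 kb strings), and grows on repetitive
ones.  The k-mer-usage term is deliberately dropped: keeping it would
reward strings made of *rare* unique k-mers, which is not repetitiveness.
The working score adds a linear penalty,

    S(c) = Q(c) − T·ℓ,

and a string contains LC sequence iff S > 0.  All logs are natural.

### Null frequencies from GC content

Only genome-wide GC content parameterises the null: bases are i.i.d. with
P(G) = P(C) = gc/2, P(A) = P(T) = (1 − gc)/2, so q_t depends only on the
number m of G/C bases in t.  The model stores the k + 1 class frequencies
q_m = (gc/2)^m ((1−gc)/2)^{k−m} and class sizes C(k, m)·2^k (their product
sums to 1, asserted to 1e-12).  By default the CLI pools gc over all input
records (ambiguous bases excluded) and clamps it into [1e-6, 1 − 1e-6] so
degenerate inputs still run; `--gc` overrides.  Higher-order composition
(dinucleotide bias, CpG depletion) is intentionally *not* modelled.

### The scaling function f(ℓ)

Exactly, each count is marginally Binomial(ℓ, q_t), so
f(ℓ) = Σ_t Σ_n binom(n; ℓ, q_t) log n!.  The package computes the Poisson
approximation (rate ℓ q_t) as a sum over the k + 1 GC classes; the inner
series Σ_n log n! · e^{−λ} λ^n / n! is truncated once n exceeds the rate
and the current term falls below 1e-12 of the running sum (never before
n = 2, where the first non-zero term appears).  Tables cover ℓ = 0..w−k+1
and are built once per (k, gc, w); log-factorials come from an exact
cumulative-sum table (w is small, no Stirling).

The exact binomial form is also implemented (`compute_f_table_exact`) and
serves as the oracle.  Measured accuracy of the Poisson form at k = 7:
the *absolute* gap grows roughly linearly in ℓ (0.02–0.05 nats at
ℓ = 1000 for gc 0.5–0.3) because the approximation ignores an O(q)
correction per k-mer; on the per-k-mer scale that the threshold lives on
the agreement is |f_P − f_exact|/ℓ ≤ 6e-5 nats — four orders of magnitude
below T = 0.6, so the approximation never affects a masking decision.
Within the default window, max_ℓ f(ℓ)/ℓ ≈ 0.101 at gc = 0.5, so T·ℓ is
the dominant penalty.

### Defaults and what they mean

| parameter | default | meaning |
|-----------|---------|---------|
| k         | 7       | k-mer length; 4^k = 16384 ≫ w−k+1 keeps random counts mostly 0/1 |
| w         | 5000 bp | context window = longest scorable interval |
| T         | 0.6 nats/k-mer | stringency; < log 2 so a duplicated k-mer pair still gains |
| gc        | estimated | GC fraction for the null frequencies |
| X         | 20 nats | X-drop trim threshold (≈ 33 bp of random spacer) |
| ρ         | 0.5     | unique-k-mer prune fraction; 1 disables |

A useful analytic consequence (`min_detectable_copies`): with unit length
r > k, distinct unit k-mers and negligible f, the smallest exact copy
number reaching S > 0 is 3 + (k−1)/r + (3T − log 2 − log 3)/(log 4 − T) ≈
3.01 + (k−1)/r at T = 0.6 — about 3.1 copies for a 50 bp unit.  It also
bounds *detectable unit lengths for a given window*: a unit longer than
~w/3.1 cannot accumulate three copies inside the window and is invisible
(e.g. 170 bp units need w ≳ 530; they are undetectable at w = 256, which
both the engine and the brute-force oracle confirm).

## Finding good intervals

A closed interval [i, j] is **good** when S(i, j) > 0 and no proper prefix
or suffix scores *strictly* higher (ties allowed, here and in the oracle);
**perfect** when no proper substring scores higher.  Reported coordinates:
an interval starts at the first base of its first k-mer; ℓ = j − i + 1 −
(k − 1); output BED is 0-based half-open.

Scanning left to right, the incremental recurrence
U(i, j) = U(i, j−1) + log c(incoming k-mer) − T gives all prefix (and,
mirrored, suffix) scores of a window in linear time, with S = U − f(ℓ).
For each end j:

1. **Skip rule** — if the k-mer ending at j occurs once in the trailing
   window, no good interval can end at j.
2. **Backward pass** — suffix scores v = S(i, j) for all starts in the
   window, computed by one vectorised occurrence-rank + cumulative-sum
   pass.  A start survives as a candidate iff (a) v > 0 (a reported
   interval needs S > 0, and the forward pass returns exactly v on
   success, so this loses nothing and avoids forward calls on random
   sequence); (b) v ≥ every shorter suffix's score; (c) v ≥ the
   one-base-longer suffix's score; (d) the fraction of window-unique
   k-mers in the suffix is ≤ ρ (each contributes −T and cannot gain for
   any end ≤ j; ρ = 1 disables the prune for definitional comparisons).
3. **Forward pass** — for candidates in ascending start order, j* =
   argmax S(i, j′) with ties broken towards the largest j′ (favouring the
   longest interval); [i, j] is good iff j* = j.  Later candidate starts
   are contained in a reported [i, j] and are skipped, so the longest good
   interval ending at j is the one kept; base-level output is unaffected
   because contained intervals add no coverage.
4. **Full-window continuation** — once a reported interval spans the full
   window ending at j−1, it is slid to [j−w+1, j] in O(1) (incremental U
   update) provided the incoming k-mer's window count c ≥ 2, log c ≥ T
   (the interval's U does not decrease) and the slid window still scores
   positive; otherwise the verified search resumes.  This is what keeps
   megabase satellite arrays contiguous and cheap.  Slid intervals are
   flagged `extended`: they guarantee S > 0 but not prefix/suffix
   maximality — in diverged arrays a slightly higher-scoring suffix exists
   for a minority of slides, the price of skipping the verification.  All
   other reported intervals are provably good (asserted exhaustively in
   the tests).

Ambiguous bases invalidate every k-mer covering them and flush the window;
records are processed independently.  Overlapping or book-ended intervals
merge into maximal blocks (merged blocks may exceed w; individual reported
intervals never do).  The whole pipeline is deterministic.

### X-drop trimming

The good-interval definition can bridge a non-repetitive spacer flanked by
repetitive blocks that share k-mers.  Because goodness puts the score
maximum at both ends of an interval, such junk is always *internal*, and a
literal "trim the ends where U falls X below its running maximum" is a
no-op; worse, applied to the raw prefix scan it would amputate exact
tandem arrays, whose first copy always dips ≈ 0.6·r nats before any
repeat is established.  The implemented rule therefore counts a violation
only once the running maximum is *positive* (an established repetitive
peak): the left end moves past the last violating position of the prefix
scan, the right end symmetrically from the suffix scan, and when the two
trims cross inside the same valley the higher-scoring flank is kept (ties
favour the flank ending at the reported position).  X = 20 nats bridges
spacers up to ~33 bp and excises longer ones; X = ∞ disables trimming.
The effect on total masked length is small by construction.

### Strand symmetry

The per-strand search is heuristic and not exactly strand symmetric.  The
default output is the union of the forward scan and the coordinate-mapped
scan of the reverse complement, which makes the output invariant under
reverse-complementing the input *by construction* (the union of the two
per-strand results is the same set either way); the test suite asserts
bit-identical interval lists across 50 fixtures.

## The brute-force oracle

`all_good_intervals` enumerates every interval of length ≤ w and applies
the definition directly (one prefix-score pass per start, running maxima
for the prefix/suffix comparisons), in O(w²) per position; a guard
(n·w ≤ 1e7) keeps it desk-scale.  `all_perfect_intervals` adds the
substring-maximum dynamic programme (n ≤ 300).  Agreement measured over
50 seeded composite fixtures (≤ 2000 bp, w = 256; hosts with
homopolymers, STRs, 30–170 bp-unit arrays at 0–2% divergence, pure random
controls): pooled base-level Jaccard between engine and oracle = 1.0 with
pruning and trimming disabled.  The comparison disables X-drop and sets
ρ = 1 because both deliberately depart from the bare definition; their
behaviour is tested separately.

## What the generator does and does not emulate

`lodust.synth` produces i.i.d. GC-biased hosts, exact or point-mutated
tandem tilings and spliced composites — enough to exercise detection
thresholds, boundary placement, strand symmetry and spacer trimming with
exactly known ground truth.  It does not emulate indels, higher-order
repeat structure, satellite homogenisation or real genomic base
composition, so a green suite establishes correctness of the *algorithm
under its own model*, not genome-scale accuracy; the published
genome-scale evaluations are out of scope here.

## Numerical choices and degenerate inputs

* Natural logarithms throughout; T = 0.6 is meaningful relative to
  log 2 ≈ 0.693 and log 4 ≈ 1.386.
* Score-tie comparisons use ≥ with a 1e-9 slack only in tests; the engine
  itself compares exact floats computed by identical passes.
* Sequences shorter than k, all-N records and empty files yield empty
  output; estimated GC of single-letter genomes is clamped rather than
  rejected.
* The Poisson series truncation and every scan are deterministic; no
  randomness exists outside `lodust.synth`, whose PCG64 streams are fully
  seeded and integer-only.

## Known limitations

* The window caps detectable repeat periods at ~w/3 (18 kb satellite
  units would need far larger windows and a slower scan).
* Repeat units and copy numbers are not reported — the score is
  composition-based, not alignment-based.
* The per-strand search remains approximate: containment skipping can in
  principle miss a good interval that starts inside another, and the
  full-window continuation trades exactness for O(1) stepping (flagged in
  the output of the raw scan).
* GC adjustment captures composition bias only to first order; strongly
  non-i.i.d. backgrounds (isochores, CpG islands) shift f(ℓ) locally.
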