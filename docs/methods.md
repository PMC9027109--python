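# Methods

## Sample entropy

For a univariate series `u` of length `n`, template length `m` and
tolerance `r`, define `N = n − m − 1` and the two template sets
`x_i = u[i:i+m]` and `y_i = u[i:i+m+1]` for `i = 0..N−1` (0-based;
both sets deliberately contain the same `N` members, indexed by start
position, so the last sample of the series appears only as the final
component of the last length-(m+1) template).  Two templates match
when their Chebyshev distance `max_l |a_l − b_l|` is at most `r`
(closed comparison, `≤ r`).  With

- `A` = number of unordered matched pairs among the `x_i`,
- `B` = number of unordered matched pairs among the `y_i`,

the sample entropy is

```
SampEn(u, m, r) = −log(B / A)            if A > 0 and B > 0
                  −log(2 / (N(N−1)))     otherwise,
```

natural logarithm throughout.  `B/A` is the empirical conditional
probability that two windows agreeing for `m` steps also agree at the
next step.  The degenerate branch reports the largest entropy
resolvable with `N` templates (as if exactly one pair out of
`N(N−1)/2` had matched); results carry an explicit `degenerate` flag.

Two conventions here differ across published SampEn codebases and are
fixed deliberately: the `N = n − m − 1` template count (some use
`n − m`), and division by the population standard deviation *without
centering* during normalization (Chebyshev distances are
translation-invariant, so centering cannot change any count; `r` is
interpreted on the unit-SD scale, where the conventional default
`r = 0.15` is meaningful).

Exact counting sweeps all `N(N−1)/2` pairs with early abort on the
first out-of-tolerance component — `O(N²)` work, compiled with numba.
This is practical to roughly `N ≈ 2^16–2^17` on one core and is what
the package uses for ground truth in every experiment.

## The Monte-Carlo estimator

Draw a uniform random subset `s` of `N0` of the `N` template indices,
count matched pairs `Ã(s)`, `B̃(s)` at lengths `m` and `m+1` among
just those templates, repeat the experiment `N1` times independently,
and average:

```
Ā = mean_k Ã(s_k),   B̄ = mean_k B̃(s_k),   MCSampEn = −log(B̄ / Ā).
```

Cost is `N1·N0(N0−1)` template-pair distance evaluations — counted,
not assumed, by the instrumented kernel — independent of `N`.  If
either average is zero the subsample analogue of the degenerate
branch, `−log(2/(N0(N0−1)))`, is returned with the flag set.  The two
per-pair length passes are fused in the kernel (an (m+1)-match
implies an m-match of its prefix), which changes no count; the
comparison counter still reports the two-pass semantics so that the
cost invariant `N1·N0·(N0−1)` is exact.

Subsets are re-drawn independently each experiment (sampling with
replacement at the subset level); no stratification is applied.

### Moment theory

Writing `B_l` for the per-template counts (either side) and
`B = Σ B_l / 2`, the subsample pair *rate* is unbiased,

```
E[B̃ / (N0(N0−1))] = B / (N(N−1)),
```

and its variance is `C_N0 / N0` with

```
C_N0 = B/((N0−1)N(N−1))
     + (N0−2)(ΣB_l² − 2B) / ((N0−1)N(N−1)(N−2))
     + (N0−2)(N0−3)(B² − ΣB_l² + B) / ((N0−1)N(N−1)(N−2)(N−3))
     − N0·B² / (N²(N−1)²),
```

bounded by `C_N0 < 1 + 1/(2(N0−1))`.  The inline typesetting of this
expression is ambiguous in print; the grouping above is the one that
agrees *exactly* (1e−10 relative) with exhaustive subset enumeration
on every tested instance, including the frozen regression case
`B_l = (3,3,0,3,3)`, `N = 5`, `N0 = 3` where `C = 0.08` and
`Var = 2/75`.  That oracle agreement is the authoritative
disambiguation.  The formula requires `N ≥ 4`; for `N0 ∈ {2, 3}` the
third (and for `N0 = 2` the second) term has a vanishing coefficient
and the formula remains valid, so these sizes are accepted rather
than rejected.  Strict positivity of `C_N0` fails in degenerate cases
beyond `B = 0` — a full subsample (`N0 = N`) or complete matching
both force zero variance — so the zero boundary is reported with a
flag rather than treated as an error.

The theory-level convergence statement (almost-sure convergence of
order 1 in `N1`, with explicit tail constants) is not computed by
this package; the qualitative consequences — error shrinking in `N0`
and `N1` — are what the evaluation suite measures.

### Parameter strategies

- **S1** (length-independent): `N0 = 2000`, `N1 = 150`.  Constant
  cost; published accuracy studies found errors under 1e−2 from
  `N0 ≥ 1500`, `N1 = 150`, `m = 4` across a range of physiological
  signals.
- **S2** (length-adaptive): `N0 = max(1024, ⌊√N⌋)`,
  `N1 = max(1, min(⌊5 + log2 N⌋, ⌊N/N0⌋))`, total cost `O(N log N)`.
  The floor of 1024 protects accuracy on short series.  Printed
  versions of this rule are typeset-damaged (`⌊N⌋` without the
  radical, and a conflicting `max`-form for `N1` in one figure
  caption); the forms above are the ones consistent with the claimed
  `O(N log N)` complexity, with `N1` read as floor-after-sum.

## Subset sampling

The sampler must produce a uniform `N0`-subset of `{0..N−1}` in
`O(N0)` operations — `O(N)` sampling would erase the estimator's
advantage.  The package implements sequential Hidden Shuffle
sampling: a first pass simulates how many sample positions fall in
the "high" range, a second generates those as descending uniform
order statistics (collisions rerouted), and a third draws the
remaining "low" items by sequential gap sampling.  RNG draws are
bounded by a small multiple of `N0` independent of `N` (asserted in
tests by instrumented counting up to `N = 10^9`).  The raw generator
emits two monotone blocks; the public function sorts its output,
while the compiled batch kernel used inside the estimator leaves rows
unsorted (pair counting is order-invariant) and gathers the selected
templates into a contiguous buffer for cache locality.

Uniformity is not taken on faith: chi-square tests compare empirical
subset frequencies against exhaustive enumeration (e.g. all
C(6,3) = 20 subsets over 2×10^5 draws, p > 0.001) on both the Python
and compiled paths, marginal inclusion frequencies against `N0/N`,
and a partial Fisher–Yates sampler (`O(N)` memory) stands behind the
same interface as a cross-check.

Randomness handling: every stochastic function takes an explicit
integer seed or `numpy.random.Generator`; nothing seeds from the
clock.  The compiled kernels use numba's internal RNG, seeded per
call from a 31-bit integer drawn from the caller's generator; that
derived seed is recorded in the estimate's provenance.

## Synthetic benchmarks

**MIX(p)** interpolates regular → random: `x_j = α^{−1/2} sin(2πj/12)`
with `α = (1/12)Σ_{j=1..12} sin²(2πj/12) = 1/2` (so the sine has
amplitude √2 and unit variance), `y_j ~ U(−√3, √3)` (unit variance),
`z_j ~ Bernoulli(p)`, `m_j = (1−z_j)x_j + z_j y_j`.  Some printed
descriptions of this process carry typeset damage (noise support
`[−3,3]`, sine argument `12πj/12` — identically zero at integer j);
the unit-variance forms above match the process's original definition
and the printed `α`.  The literal printed variants are available
behind a `literal=True` flag for comparison only.

**1/f noise** is synthesized spectrally: complex white Gaussian
spectrum shaped by `f^{−1/2}`, DC zeroed, inverse real FFT, rescaled
to unit SD.  Tests assert a log-log periodogram slope in
[−1.2, −0.8] at `n = 2^16`.  Only its entropy statistics matter to
this package, so any standard spectral synthesis would do.

These generators emulate the *statistical* regimes the estimator is
validated on (tunable regularity, long-memory noise); they do not
emulate physiological morphology (QRS complexes, seizure spindles,
beat-to-beat artefacts) or nonstationarity of real recordings.
Passing tests therefore demonstrate correctness of the counting,
sampling and averaging machinery and the predicted error scaling —
not clinical validity on any particular signal class.  Real records
can be analyzed through the file readers and the CLI.

## Evaluation protocol

Repeated-run metrics against the exact entropy of the same
realization, 50 runs by default:

- `MeanErr = |mean(estimate − truth)|` (bias magnitude; the signed
  mean is also retained — published surfaces plot nonnegative values
  without printing the formula, and the absolute-mean reading is the
  one adopted here);
- `RMeanSqErr = sqrt(mean((estimate − truth)²))`;
- relative error `RMeanSqErr / |truth|`, undefined at zero truth.

Experiment layouts: a convergence surface over the published grids
`N0 ∈ {200i: i ≤ 20}`, `N1 ∈ {10i: i ≤ 25}` (cells with `N0 > N` are
skipped with a warning), and the relative-error-versus-p sweep with
the p-coupled schedule `N0 = round(1000+3000p)`,
`N1 = round(80+70p)`, whose published target is relative error
≤ 0.02.

### Problem sizes

The package's own experiments run at series lengths 2^12–2^16 with
exact ground truth computed by direct counting; the headline
relative-error protocol runs at `n = 2^16` (the original study used
2^20 for that experiment; the estimator's variance depends on
`(N0, N1)`, not on `N`, so the protocol transfers — this scaled-down
setting is recorded in the acceptance output's metadata).  Truncation
of very long records defaults to 10^6 samples in the CLI, matching
standard practice for these protocols.

## Numerical and design choices

- Closed tolerance `≤ r`; ties at exactly `r` count as matches.
- Natural log everywhere (the field's convention; printed sources
  leave the base unqualified).
- Counting kernels accumulate in int64; no floating summation is
  involved in `A`, `B`.
- `normalize_signal` rejects constant signals (sd = 0) rather than
  returning NaNs.
- The estimator validates `2 ≤ N0 ≤ N` and points the user to
  strategy S2 when a short series makes `N0` infeasible.
- Degenerate MC output (zero averaged counts) uses the subsample
  fallback `−log(2/(N0(N0−1)))` with `degenerate=True`; the published
  algorithm leaves this case undefined, and mirroring the exact
  definition's fallback keeps output finite.
- `MeanErr` is the absolute value of the mean signed error (see
  above).

## Known limitations

- Exact counting beyond `N ≈ 2^17` is slow on one core; the package
  does not implement kd-tree/box/bucket accelerated exact counting
  (deliberately out of scope — the Monte-Carlo estimator is the
  answer to that regime).
- No multiscale/hierarchical entropy, no parallel execution, no
  WFDB/EDF readers (convert to plain text or CSV first).
- The tail-bound constants of the almost-sure convergence theory are
  not computed (one of its thresholds is defined through a quantity
  the unbiasedness result makes identically zero, and no computable
  reading is evident); only qualitative convergence is validated.
- Sampler uniformity rests on statistical evidence (chi-square
  against enumeration) rather than a formal proof carried in this
  codebase.
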