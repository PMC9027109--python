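# mcsampen

Exact and Monte-Carlo estimation of **sample entropy** for long
univariate time series — ECG, EEG, RR-interval and other
physiological or mechanical signals where series of 10^5–10^6 samples
make the classical quadratic computation painful.

## The statistic and the estimator

For a series `u` of length `n`, template length `m` and tolerance
`r`, let `N = n − m − 1` and count unordered template pairs within
Chebyshev distance `r`: `A` pairs at length `m`, `B` pairs at length
`m + 1`.  Sample entropy is

```
SampEn(u, m, r) = −log(B / A),
```

with the fallback `−log(2/(N(N−1)))` when either count is zero.
`B/A` estimates the conditional probability that windows agreeing for
`m` steps also agree at step `m + 1`; larger values mean a less
predictable series.  Exact counting is O(N²).

**MCSampEn** replaces the full count with repeated subsampling: draw
a uniform subset of `N0` template indices (Hidden Shuffle sampling,
O(N0) per draw), count matched pairs `Ã`, `B̃` among those templates
only, repeat `N1` times, and return `−log(B̄/Ā)` from the averaged
counts.  The subsample pair rates are unbiased for the full-series
rates, their variance is `C_{N0}/N0` in closed form with
`C_{N0} < 1 + 1/(2(N0−1))`, and the total cost — exactly
`N1·N0·(N0−1)` pair comparisons — is independent of `N`.  The package
implements the exact computation, the estimator, the moment theory
with its exhaustive-enumeration oracle, the MIX(p) and 1/f synthetic
benchmarks, and the repeated-run accuracy protocol.

## Worked example

```python
from mcsampen import mcsampen, normalize_signal, sample_entropy_exact, strategy_s1
from mcsampen.signals import mix_process

# a 2^16-sample benchmark: 12-periodic sine, 30% of samples replaced
# by uniform noise, rescaled to unit SD
sig = normalize_signal(mix_process(2**16, 0.3, rng=42))

exact = sample_entropy_exact(sig, m=4, r=0.15)
s1 = strategy_s1()                       # N0=2000, N1=150
est = mcsampen(sig, m=4, r=0.15, n0=s1.n0, n1=s1.n1, rng=0)
```

Running this (`python examples/01_exact_vs_mc.py`) prints:

```
exact SampEn(m=4, r=0.15): 0.627994  (A=14789464, B=7892566)
MCSampEn (N0=2000, N1=150): 0.625766
absolute error: 0.002228
pair comparisons: mc 599,700,000 vs exact 4,294,246,430
```

The estimate agrees with the exact value to ~0.4% while performing
7× fewer pair comparisons — a gap that widens linearly with series
length, since the Monte-Carlo cost never grows.  The other scripts in
`examples/` demonstrate the unbiasedness/variance theory against
exhaustive enumeration, the error surface over `(N0, N1)`, and the
entropy-versus-randomness sweep on MIX(p).

## Command line

```sh
mcsampen --input ecg.txt                      # m=4, r=0.15, MC with S1, seed 0
mcsampen --input ecg.txt --method exact --m 5
mcsampen --input rr.csv --column rr --strategy s2 --seed 7
mcsampen --input ecg.txt --runs 50 --with-truth --output report.csv
```

Input is plain text (one value per line) or CSV with a selectable
column; records are truncated to 10^6 samples by default.  Signals
are normalized to unit SD before matching unless `--no-normalize` is
given.

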