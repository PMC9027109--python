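"""Synthetic benchmark signals: the MIX(p) process, 1/f noise, fixtures.

MIX(p) interpolates between perfect regularity and pure noise: a
deterministic 12-periodic unit-variance sine is replaced, sample by
sample under an independent Bernoulli(p) mask, with i.i.d. uniform
noise of the same variance,

    x_j = alpha^{-1/2} sin(2 pi j / 12),
    alpha = (1/12) sum_{j=1..12} sin^2(2 pi j / 12) = 1/2,
    y_j ~ U(-sqrt(3), sqrt(3))   (unit variance),
    z_j ~ Bernoulli(p),
    m_j = (1 - z_j) x_j + z_j y_j.

p = 0 gives the pure sine (amplitude sqrt(2)); p = 1 gives pure
uniform noise; the sample entropy of the process increases with p,
which makes MIX(p) the standard dial for studying how randomness
affects entropy estimators.

1/f ("pink") noise is synthesized spectrally: a white complex Gaussian
spectrum is shaped by f^{-1/2} (so power falls like 1/f), the DC term
is zeroed, and the inverse transform is rescaled to unit standard
deviation.

The fixture set bundles the tiny deterministic series used throughout
the test suite so every experiment runs without external data.
"""

from __future__ import annotations

import math

import numpy as np

from .core import Signal
from .sampling import coerce_rng

__all__ = ["mix_process", "pink_noise", "fixtures", "mix_alpha"]


def mix_alpha() -> float:
    """The sine-normalization constant alpha = mean of sin^2 over one period."""
    j = np.arange(1, 13)
    return float(np.mean(np.sin(2.0 * np.pi * j / 12.0) ** 2))


def mix_process(n: int, p: float, rng, literal: bool = False) -> Signal:
    """A length-n MIX(p) realization.

    Parameters
    ----------
    n : series length (>= 1).
    p : mixing probability in [0, 1]; the fraction of samples replaced
        by noise.
    rng : integer seed or Generator.  Two streams are consumed in
        fixed order: n uniforms (noise) then n uniforms (mask).
    literal : if True, reproduce the typeset-damaged printed variant
        (sine argument 12*pi*j/12, which vanishes at integer j, and
        noise support [-3, 3]); provided only for comparison, not for
        experiments.
    """
    if n < 1:
        raise ValueError(f"length must be >= 1, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"mixing probability must lie in [0, 1], got {p}")
    gen = coerce_rng(rng)
    j = np.arange(1, n + 1, dtype=np.float64)
    alpha = mix_alpha()
    if literal:
        x = np.sin(12.0 * np.pi * j / 12.0) / math.sqrt(alpha)
        half_width = 3.0
    else:
        x = np.sin(2.0 * np.pi * j / 12.0) / math.sqrt(alpha)
        half_width = math.sqrt(3.0)
    y = gen.uniform(-half_width, half_width, size=n)
    z = gen.random(n) < p
    return Signal(np.where(z, y, x))


def pink_noise(n: int, rng) -> Signal:
    """Unit-SD 1/f noise of length n by spectral synthesis.

    The periodogram of the output falls off with log-log slope close
    to -1 over the resolvable band (within about +/-0.2 for
    n >= 2^14).  Deterministic given the seed.
    """
    if n < 2:
        raise ValueError(f"length must be >= 2, got {n}")
    gen = coerce_rng(rng)
    nf = n // 2 + 1
    spec = gen.standard_normal(nf) + 1j * gen.standard_normal(nf)
    k = np.arange(nf, dtype=np.float64)
    k[0] = 1.0  # placeholder; DC is zeroed below
    spec *= k**-0.5
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    if sd == 0.0:  # cannot occur for n >= 2 with Gaussian spectrum
        raise RuntimeError("degenerate synthesis")
    return Signal(x / sd)


def fixtures() -> dict[str, Signal]:
    """Deterministic signals shared across the tests and examples.

    toy        : (0,0,1,0,0,1,0) — small enough for hand enumeration;
                 m=1, r=0.5 gives A=6, B=2, SampEn = log 3.
    constant   : all equal; every template matches, SampEn = 0.
    big_step   : strictly increasing with steps far beyond any usual
                 tolerance; no matches, degenerate fallback.
    mix_03     : a seeded MIX(0.3) draw of length 4096.
    """
    return {
        "toy": Signal(np.array([0.0, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0])),
        "constant": Signal(np.ones(10)),
        "big_step": Signal(np.arange(10, dtype=np.float64) * 10.0),
        "mix_03": mix_process(4096, 0.3, rng=1234),
    }
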