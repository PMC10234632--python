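"""Shared numerical helpers."""

from __future__ import annotations

import numpy as np


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Coerce a seed or Generator into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def balding_nichols(
    p: np.ndarray, f: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw allele frequencies that drifted from ancestral frequencies ``p``.

    The draw has mean ``p`` and variance ``p (1 - p) f``, i.e. the
    Balding–Nichols Beta distribution with inbreeding coefficient ``f``.
    The continuous limits are handled exactly: ``f = 0`` returns ``p``
    unchanged (no drift) and ``f = 1`` fixes each locus by a Bernoulli(p)
    coin flip.  Frequencies of exactly 0 or 1 are absorbing.
    """
    p = np.asarray(p, dtype=float)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"inbreeding coefficient f={f} outside [0, 1]")
    if f == 0.0:
        return p.copy()
    if f == 1.0:
        return (rng.random(p.shape) < p).astype(float)
    c = 1.0 / f - 1.0
    out = np.empty_like(p)
    interior = (p > 0.0) & (p < 1.0)
    out[~interior] = p[~interior]
    pi = p[interior]
    out[interior] = rng.beta(pi * c, (1.0 - pi) * c)
    return out


def uniform_p_anc_sampler(low: float = 0.01, high: float = 0.5):
    """Default ancestral allele frequency sampler: Uniform(low, high)."""

    def sampler(m: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(low, high, size=m)

    return sampler
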